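"""Telomere maintenance mechanism (TMM) calling.

Tumors maintain telomeres either canonically (CTM) through TERT activation —
MYCN amplification, TERT rearrangement, or high TERT expression — or through
alternative lengthening of telomeres (ALT), detected here as an elevated
tumor/normal telomere-length ratio estimated from the abundance of telomeric
repeat reads in WGS.  Samples meeting both sets of criteria are labeled
*Mix*; samples meeting neither are labeled *None*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"

TMM_LABELS = ("CTM", "ALT", "Mix", "None")


def _contains_repeat(seq: str, k: int, both_strands: bool = True) -> bool:
    s = seq.upper()
    if TELOMERE_MOTIF * k in s:
        return True
    return both_strands and TELOMERE_MOTIF_RC * k in s


def count_telomeric_reads(
    reads: Iterable[str],
    k: int = 7,
    both_strands: bool = True,
    scale: float = 1.0,
) -> tuple[int, int, float]:
    """Count reads containing >= ``k`` exact consecutive telomere repeats.

    A read counts if it contains ``(TTAGGG)^k`` — or, with ``both_strands``,
    ``(CCCTAA)^k`` — as an exact substring (case-insensitive).  Returns
    ``(counted, total, length_proxy)`` where the length proxy is
    ``counted / total * scale``.  The scale constant stands in for Telseq's
    GC/genome-size normalization; it cancels in tumor/normal ratios.
    """
    counted = 0
    total = 0
    for seq in reads:
        total += 1
        if _contains_repeat(seq, k, both_strands):
            counted += 1
    if total == 0:
        raise ValueError("no reads supplied")
    return counted, total, counted / total * scale


def telomere_length_ratio(l_tumor: float, l_normal: float) -> float:
    """Natural-log telomere length ratio log(L_T / L_N)."""
    if l_tumor <= 0 or l_normal <= 0:
        raise ValueError("telomere lengths must be positive")
    return float(np.log(l_tumor / l_normal))


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit of TERT expression Z scores."""

    means: tuple[float, float]  # (low, high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float

    def posterior_high(self, z: np.ndarray) -> np.ndarray:
        """Posterior probability of the higher-mean component at ``z``."""
        z = np.asarray(z, dtype=float)
        lo = self.weights[0] * stats.norm.pdf(z, self.means[0], self.sds[0])
        hi = self.weights[1] * stats.norm.pdf(z, self.means[1], self.sds[1])
        return hi / (lo + hi)


def fit_tert_threshold(
    tert_z: Sequence[float],
    posterior_cut: float = 0.95,
    seed: int = 0,
    n_init: int = 10,
    covariance_type: str = "tied",
) -> MixtureFit:
    """Fit a 2-component Gaussian mixture to TERT Z scores and locate the
    expression threshold.

    The threshold is the smallest Z at which the posterior probability of
    assignment to the stronger-expression component reaches
    ``posterior_cut``, located on a dense grid between the low-component
    mean and the far right tail.  By default the components share one
    pooled variance (``covariance_type='tied'``): with cohort-scale sample
    sizes this markedly stabilizes the threshold estimate; pass ``'full'``
    for component-specific variances.
    """
    z = np.asarray(tert_z, dtype=float)
    if len(z) < 10:
        raise ValueError(f"need >= 10 samples, got {len(z)}")
    if np.std(z) == 0:
        raise ValueError("degenerate input: zero variance")
    gm = GaussianMixture(
        n_components=2, n_init=n_init, random_state=seed, tol=1e-6, max_iter=500,
        covariance_type=covariance_type,
    ).fit(z.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge (lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    if covariance_type == "tied":
        sds = np.sqrt(np.repeat(gm.covariances_.ravel()[0], 2))
    else:
        sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    fit = MixtureFit(
        means=tuple(means[order]),
        sds=tuple(sds[order]),
        weights=tuple(weights[order]),
        threshold=np.nan,
    )
    grid = np.linspace(fit.means[0], fit.means[1] + 12 * max(fit.sds), 400_001)
    post = fit.posterior_high(grid)
    above = np.nonzero(post >= posterior_cut)[0]
    if len(above) == 0:
        raise RuntimeError("posterior never reaches the cut; components overlap")
    fit.threshold = float(grid[above[0]])
    return fit


@dataclass
class TmmFeatures:
    """Per-sample inputs to the TMM decision rule."""

    mycn_amp: bool
    tert_re: bool
    tert_z: float
    tlr: float


@dataclass
class TmmCall:
    label: str
    tert_high: bool


def classify_tmm(
    features: TmmFeatures, threshold: float, tlr_cut: float = 0.5
) -> TmmCall:
    """Assign a TMM label from molecular features.

    TERT-high requires Z above the mixture threshold in the absence of both
    MYCN amplification and TERT rearrangement.  CTM criteria: MYCN-amp or
    TERT-re or TERT-high.  ALT criterion: log telomere-length ratio above
    ``tlr_cut``.  Both -> Mix; only one -> CTM or ALT; neither -> None.
    """
    for field in ("mycn_amp", "tert_re", "tert_z", "tlr"):
        v = getattr(features, field)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise ValueError(f"missing TMM feature {field!r}")
    tert_high = (
        features.tert_z > threshold
        and not features.mycn_amp
        and not features.tert_re
    )
    ctm = features.mycn_amp or features.tert_re or tert_high
    alt = features.tlr > tlr_cut
    if ctm and alt:
        label = "Mix"
    elif ctm:
        label = "CTM"
    elif alt:
        label = "ALT"
    else:
        label = "None"
    return TmmCall(label=label, tert_high=tert_high)


def count_terra_fragments(
    read_pairs: Iterable[tuple[str, str | None]],
    total_fragments: int,
    min_repeats: int = 5,
    both_strands: bool = True,
) -> tuple[int, float]:
    """Count telomeric-repeat-containing RNA (TERRA) fragments and FPM.

    A fragment counts if either of its reads contains >= ``min_repeats``
    exact consecutive TTAGGG motifs (or the reverse complement).  FPM is
    counted fragments per million total fragments.
    """
    if total_fragments < 1:
        raise ValueError("total_fragments must be >= 1")
    counted = 0
    for pair in read_pairs:
        r1, r2 = pair
        if _contains_repeat(r1, min_repeats, both_strands) or (
            r2 is not None and _contains_repeat(r2, min_repeats, both_strands)
        ):
            counted += 1
    return counted, counted / total_fragments * 1e6


def validate_calls(
    predicted: Sequence[bool], experimental: Sequence[bool]
) -> tuple[float, float, float]:
    """Sensitivity, specificity and one-sided Fisher p of predicted calls
    against experimental labels (enrichment alternative)."""
    pred = np.asarray(predicted, dtype=bool)
    truth = np.asarray(experimental, dtype=bool)
    if len(pred) != len(truth):
        raise ValueError("length mismatch")
    if truth.all() or not truth.any():
        raise ValueError("need at least one positive and one negative label")
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    _, p = stats.fisher_exact([[tp, fn], [fp, tn]], alternative="greater")
    return sens, spec, float(p)
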