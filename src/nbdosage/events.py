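"""Structural events and region-level association scans.

Covers the targeted ATRX exon-deletion detector on binned coverage ratios,
the chromosome-resampling bootstrap around a pluggable whole-genome-doubling
(WGD) caller, Fisher enrichment of WGD across telomere-maintenance groups,
and the nested-GLM association scans: chromosome-arm DNA content vs ALT and
5 Mb-bin copy-number ratio vs mortality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests


@dataclass
class AtrxFit:
    deleted: bool
    means: tuple[float, float]
    weights: tuple[float, float]
    note: str = ""


def detect_atrx_deletion(
    signal: Sequence[float],
    mean_gap: float = 1.5,
    min_prop: float = 0.10,
    seed: int = 0,
    min_bins: int = 50,
) -> AtrxFit:
    """Detect an exon deletion from 50 bp coverage log-ratio bins over a gene.

    A two-component Gaussian mixture is fit to the per-bin signal
    ``s_i = log2(n_iT / n_iN)``; a deletion is called when the component
    means differ by at least ``mean_gap`` and the smaller cluster's weight
    is at least ``min_prop`` of the larger cluster's.
    """
    s = np.asarray(signal, dtype=float)
    s = s[np.isfinite(s)]
    if len(s) < min_bins:
        raise ValueError(f"need >= {min_bins} finite bins, got {len(s)}")
    if np.std(s) < 1e-12:
        return AtrxFit(False, (float(s[0]), float(s[0])), (1.0, 0.0), "degenerate signal")
    gm = GaussianMixture(
        n_components=2, n_init=10, tol=1e-6, max_iter=500, random_state=seed
    ).fit(s.reshape(-1, 1))
    means = tuple(gm.means_.ravel())
    weights = tuple(gm.weights_.ravel())
    gap = abs(means[0] - means[1])
    prop = min(weights) / max(weights)
    return AtrxFit(gap >= mean_gap and prop >= min_prop, means, weights)


def default_wgd_caller(profile: pd.DataFrame, genome_fraction: float = 0.5) -> bool:
    """Stand-in single-profile WGD rule: positive when at least half of the
    genome length has total copy number >= 4 with major allele count >= 2.

    Replaceable by any caller mapping a segment table to a boolean (for
    instance an evolutionary shortest-path criterion).
    """
    length = (profile["end"] - profile["start"] + 1).to_numpy(float)
    hit = (profile["cn_total"] >= 4) & (profile["n_major"] >= 2)
    return float(length[hit].sum()) / float(length.sum()) >= genome_fraction


def wgd_bootstrap(
    profile: pd.DataFrame,
    caller: Callable[[pd.DataFrame], bool] = default_wgd_caller,
    n_boot: int = 100,
    frac_cut: float = 0.05,
    seed: int = 0,
    n_chromosomes: int = 22,
) -> tuple[bool, float]:
    """Chromosome-resampling bootstrap around a WGD caller.

    ``n_boot`` resampled profiles are built by drawing ``n_chromosomes``
    chromosomes with replacement from the sample's profile; the sample is
    WGD positive when the fraction of positive bootstrap calls reaches
    ``frac_cut``.  Returns (call, bootstrap fraction).
    """
    chroms = sorted(profile["chrom"].unique())
    if len(chroms) != n_chromosomes:
        raise ValueError(f"expected {n_chromosomes} chromosomes, got {len(chroms)}")
    by_chrom = {c: g for c, g in profile.groupby("chrom")}
    rng = np.random.default_rng(seed)
    positives = 0
    for i in range(n_boot):
        draw = rng.choice(chroms, size=n_chromosomes, replace=True)
        boot = pd.concat([by_chrom[c] for c in draw], ignore_index=True)
        try:
            positives += bool(caller(boot))
        except Exception as exc:  # noqa: BLE001 - annotate bootstrap index
            raise RuntimeError(f"WGD caller failed on bootstrap {i}") from exc
    frac = positives / n_boot
    return frac >= frac_cut, frac


def fisher_wgd_enrichment(
    groups: Sequence[str], wgd: Sequence[bool], alternative: str = "two-sided"
) -> pd.DataFrame:
    """Observed vs expected WGD counts per group with Fisher exact p.

    Expected counts are ``round(n_g * total_WGD / N)``.  The p-value per
    group comes from the 2x2 table of WGD status inside vs outside the
    group (two-sided by default).
    """
    groups = np.asarray(groups)
    wgd = np.asarray(wgd, dtype=bool)
    total = int(wgd.sum())
    n = len(wgd)
    rows = []
    for g in pd.unique(groups):
        ing = groups == g
        n_g = int(ing.sum())
        if n_g == 0:
            continue
        obs = int(wgd[ing].sum())
        expected = round(n_g * total / n)
        table = [[obs, n_g - obs], [total - obs, (n - n_g) - (total - obs)]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        rows.append(
            {"group": g, "n": n_g, "observed": obs, "expected": expected, "p": float(p)}
        )
    return pd.DataFrame(rows)


def _design(covariates: pd.DataFrame) -> np.ndarray:
    parts = [np.ones(len(covariates))]
    for c in covariates.columns:
        x = pd.to_numeric(covariates[c], errors="coerce").to_numpy(float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            warnings.warn(f"dropping constant covariate {c!r}")
            continue
        parts.append(x)
    return np.column_stack(parts)


def _fit_null_probs(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fitted probabilities of the covariate-only logistic model.

    Falls back to a weakly ridge-penalized fit when maximum likelihood is
    degenerate (complete separation); the fallback is flagged.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            probs = np.asarray(res.fittedvalues)
        if np.isfinite(res.params).all() and np.abs(res.params).max() < 1e3:
            return np.clip(probs, 1e-10, 1 - 1e-10), False
    except Exception:  # noqa: BLE001 - fall through to penalized fit
        pass
    lr = LogisticRegression(C=10.0, max_iter=1000).fit(X[:, 1:], y)
    return np.clip(lr.predict_proba(X[:, 1:])[:, 1], 1e-10, 1 - 1e-10), True


def _score_stats(
    X0: np.ndarray, V: np.ndarray, y: np.ndarray, p0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rao score statistics of each region column of ``V`` added to the
    null logistic model with design ``X0`` and fitted probabilities ``p0``.

    Returns (chi-squared statistics, score numerators); vectorized over
    regions.
    """
    w = p0 * (1 - p0)
    i_inv = np.linalg.inv(X0.T @ (X0 * w[:, None]))
    u = V.T @ (y - p0)
    m = X0.T @ (V * w[:, None])
    denom = np.einsum("nm,nm->m", V * w[:, None], V) - np.einsum(
        "pm,pq,qm->m", m, i_inv, m
    )
    denom = np.maximum(denom, 1e-12)
    return u * u / denom, u


def nested_glm_scan(
    values: pd.DataFrame,
    outcome: Sequence[bool],
    covariates: pd.DataFrame,
    alpha_fwer: float = 0.05,
    n_boot: int = 199,
    seed: int = 0,
    method: str = "max_stat",
) -> pd.DataFrame:
    """Region-wise association scan between nested logistic GLMs.

    For each column of ``values`` (one region), the binary outcome is
    modeled with covariates alone versus covariates plus the region value;
    the per-region p-value is the Rao score chi-squared between the two
    models.  Family-wise error control (default ``method='max_stat'``)
    adjusts each region against the parametric-bootstrap distribution of
    the maximum score statistic across regions under the covariate-only
    null — a single-step adjustment that, unlike plain Bonferroni on the
    asymptotic p-values, stays calibrated at cohort-scale sample sizes and
    accounts for inter-region correlation.  ``method='bonferroni'`` gives
    the classical adjustment of the asymptotic p-values.

    Regions with missing values are mean-imputed for testing (missingness
    is expected to be rare); constant regions are skipped.  Returns
    ``region, coefficient, direction, p, p_adj, significant, flagged``
    with ``coefficient`` the one-step estimate of the region term.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome must have both classes")
    X0 = _design(covariates)
    regions, cols = [], []
    for region in values.columns:
        v = values[region].to_numpy(float)
        ok = np.isfinite(v)
        if not ok.any() or np.ptp(v[ok]) == 0:
            continue
        if not ok.all():
            v = np.where(ok, v, v[ok].mean())
        regions.append(region)
        cols.append(v)
    if not regions:
        return pd.DataFrame(
            columns=["region", "coefficient", "direction", "p", "p_adj",
                     "significant", "flagged"]
        )
    V = np.column_stack(cols)
    p0, flagged = _fit_null_probs(y, X0)
    z2, u = _score_stats(X0, V, y, p0)
    w = p0 * (1 - p0)
    coef = u / np.maximum(np.einsum("nm,nm->m", V * w[:, None], V), 1e-12)
    p_raw = stats.chi2.sf(z2, 1)
    if method == "bonferroni":
        reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha_fwer, method="bonferroni")
    elif method == "max_stat":
        rng = np.random.default_rng(seed)
        max_stats = np.empty(n_boot)
        for b in range(n_boot):
            yb = (rng.random(len(y)) < p0).astype(float)
            pb, fb = _fit_null_probs(yb, X0)
            flagged = flagged or fb
            z2b, _ = _score_stats(X0, V, yb, pb)
            max_stats[b] = z2b.max()
        p_adj = (1 + (max_stats[None, :] >= z2[:, None]).sum(axis=1)) / (n_boot + 1)
        p_adj = np.maximum(p_adj, p_raw)
        reject = p_adj < alpha_fwer
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {
            "region": regions,
            "coefficient": coef,
            "direction": np.where(coef > 0, "gain", "loss"),
            "p": p_raw,
            "p_adj": p_adj,
            "significant": reject,
            "flagged": flagged,
        }
    )


def arm_alt_association(
    arm_logr: pd.DataFrame,
    alt: Sequence[bool],
    covariates: pd.DataFrame,
    alpha_fwer: float = 0.05,
    **scan_kwargs,
) -> pd.DataFrame:
    """Association of chromosome-arm DNA content (LogR) with ALT status.

    ``arm_logr`` is samples x arms.  Mix samples (both CTM and ALT
    evidence) should be excluded by the caller before this test.  Covariates
    typically include MYCN amplification, ATRX alteration, age, sex,
    cohort, purity and ploidy.
    """
    return nested_glm_scan(arm_logr, alt, covariates, alpha_fwer, **scan_kwargs)


def bin_survival_association(
    bin_ratio: pd.DataFrame,
    deceased: Sequence[bool],
    covariates: pd.DataFrame,
    alpha_fwer: float = 0.05,
    bin_coords: Mapping[str, tuple] | None = None,
    **scan_kwargs,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Association of 5 Mb-bin copy-number ratio with death from disease.

    Runs the nested-GLM scan over bins and merges runs of adjacent
    significant bins (adjacency taken from ``bin_coords``:
    bin -> (chrom, start, end); defaults to column order) into candidate
    regions.  Returns (scan table, list of merged bin groups).
    """
    scan = nested_glm_scan(bin_ratio, deceased, covariates, alpha_fwer, **scan_kwargs)
    merged: list[list[str]] = []
    if len(scan) == 0:
        return scan, merged
    sig = scan.loc[scan["significant"], "region"].tolist()
    sig_set = set(sig)
    order = list(bin_ratio.columns)

    def chrom_of(b):
        return bin_coords[b][0] if bin_coords else None

    current: list[str] = []
    prev = None
    for b in order:
        if b in sig_set:
            adjacent = (
                current
                and prev in sig_set
                and (bin_coords is None or chrom_of(b) == chrom_of(prev))
            )
            if adjacent:
                current.append(b)
            else:
                if current:
                    merged.append(current)
                current = [b]
        else:
            if current:
                merged.append(current)
                current = []
        prev = b
    if current:
        merged.append(current)
    return scan, merged
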