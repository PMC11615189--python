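"""Allele-specific copy-number profiling from SNP allelic depths.

The model follows the standard two-state mixture of tumor and contaminating
normal cells.  A segment carrying ``n_A`` copies of the major and ``n_B``
copies of the minor allele in a tumor of purity ``rho`` and ploidy ``psi``
produces an expected B-allele frequency (BAF) and coverage log-ratio (LogR)

    BAF  = ((1 - rho) * 1 + rho * n_B) / ((1 - rho) * 2 + rho * (n_A + n_B))
    LogR = gamma * log2( ((1 - rho) * 2 + rho * (n_A + n_B))
                         / ((1 - rho) * 2 + rho * psi) )

Inversion of this forward model at segment level yields integer allele
counts.  Segmentation uses only the mirrored BAF signal; coverage ratios are
averaged within segments afterwards, which avoids over-segmentation from
noisy coverage tracks.

All genomic coordinates are 1-based inclusive (SEG-style tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CN_STATES = (
    "loss",
    "shallow loss",
    "neutral",
    "weak gain",
    "medium gain",
    "strong gain",
    "amplification",
)
BALANCE_STATES = ("balance", "weak imbalance", "strong imbalance", "amplification")


def forward_baf_logr(
    n_a: int, n_b: int, purity: float, ploidy: float, gamma: float = 1.0
) -> tuple[float, float]:
    """Expected (BAF, LogR) of a segment with allele counts ``(n_a, n_b)``.

    ``n_a`` is the major and ``n_b`` the minor allele count (``n_a >= n_b``).
    Raises ``ValueError`` on zero purity (the tumor signal vanishes).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    if n_b < 0 or n_a < n_b:
        raise ValueError(f"require n_a >= n_b >= 0, got ({n_a}, {n_b})")
    denom = (1 - purity) * 2 + purity * (n_a + n_b)
    if denom == 0:  # pure tumor with total copy number zero: no DNA at all
        return 0.5, -np.inf
    baf = ((1 - purity) * 1 + purity * n_b) / denom
    logr = gamma * np.log2(denom / ((1 - purity) * 2 + purity * ploidy))
    return float(baf), float(logr)


def compute_baf_logr(
    sites: pd.DataFrame,
    mean_depth_tumor: float | None = None,
    mean_depth_normal: float | None = None,
    min_depth: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Per-SNP BAF and LogR from a table of tumor/normal allelic depths.

    ``sites`` needs columns ``chrom, pos, refN, altN, refT, altT``.  Sites
    with total depth below ``min_depth`` in either tumor or normal are
    dropped.  Mean depths default to the means over retained sites.

    Returns the annotated table (added columns ``baf``, ``logr``) and the
    number of dropped sites.
    """
    d_t = sites["refT"].to_numpy(float) + sites["altT"].to_numpy(float)
    d_n = sites["refN"].to_numpy(float) + sites["altN"].to_numpy(float)
    keep = (d_t >= min_depth) & (d_n >= min_depth)
    n_dropped = int((~keep).sum())
    out = sites.loc[keep].copy()
    d_t, d_n = d_t[keep], d_n[keep]
    if len(out) == 0:
        out["baf"] = np.nan
        out["logr"] = np.nan
        return out, n_dropped
    if mean_depth_tumor is None:
        mean_depth_tumor = float(d_t.mean())
    if mean_depth_normal is None:
        mean_depth_normal = float(d_n.mean())
    if mean_depth_tumor <= 0 or mean_depth_normal <= 0:
        raise ValueError("mean depths must be positive")
    out["baf"] = out["altT"].to_numpy(float) / d_t
    out["logr"] = np.log2((d_t / d_n) / (mean_depth_tumor / mean_depth_normal))
    return out, n_dropped


def _segment_cost_gains(x: np.ndarray) -> np.ndarray:
    """SSE reduction of every split position of ``x`` (vectorized)."""
    n = len(x)
    k = np.arange(1, n)
    cs = np.cumsum(x)
    total = cs[-1]
    left = cs[:-1]
    right = total - left
    return left**2 / k + right**2 / (n - k) - total**2 / n


def _binseg(x: np.ndarray, penalty: float, min_size: int, offset: int, out: list[int]) -> None:
    n = len(x)
    if n < 2 * min_size:
        return
    gains = _segment_cost_gains(x)
    lo, hi = min_size - 1, n - min_size
    window = gains[lo:hi]
    if len(window) == 0:
        return
    k = lo + int(np.argmax(window))
    if gains[k] <= penalty:
        return
    split = k + 1  # x[:split], x[split:]
    out.append(offset + split)
    _binseg(x[:split], penalty, min_size, offset, out)
    _binseg(x[split:], penalty, min_size, offset + split, out)


def segment_baf(
    baf: np.ndarray | Sequence[float],
    penalty: float | None = None,
    min_size: int = 3,
) -> list[int]:
    """Changepoints of one chromosome's het-site BAF sequence.

    Detection runs on the mirrored signal ``|BAF - 0.5|`` by penalized
    binary segmentation.  Returned breakpoints are indices ``i`` such that
    sites ``[.., i-1]`` and ``[i, ..]`` fall in different segments.

    The default penalty is ``6 * sigma^2 * log(n)`` with ``sigma`` estimated
    robustly from first differences, which keeps spurious splits rare while
    steps of a few percent BAF remain detectable.
    """
    x = np.abs(np.asarray(baf, dtype=float) - 0.5)
    n = len(x)
    if n < 2:
        warnings.warn("fewer than 2 het sites; empty segmentation")
        return []
    if penalty is None:
        diffs = np.diff(x)
        sigma = np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2)
        sigma = max(sigma, 1e-4)
        penalty = 6.0 * sigma**2 * np.log(n)
    out: list[int] = []
    _binseg(x, penalty, min_size, 0, out)
    return sorted(out)


def estimate_allele_cn(
    baf: float,
    logr: float,
    purity: float,
    ploidy: float,
    gamma: float = 1.0,
    max_cn: int = 12,
) -> tuple[int, int]:
    """Integer (CN_major, CN_minor) minimizing squared error to the forward model.

    The observed BAF is mirrored to ``min(b, 1-b)`` so the fit is invariant
    to which allele was labeled B.  Ties break toward smaller total copy
    number, then larger minor allele count.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    b = min(baf, 1.0 - baf)
    best = None
    best_key = None
    for total in range(0, 2 * max_cn + 1):
        for n_b in range(0, total // 2 + 1):
            n_a = total - n_b
            if n_a > max_cn:
                continue
            fb, fr = forward_baf_logr(n_a, n_b, purity, ploidy, gamma)
            if not np.isfinite(fr):
                fr = -10.0  # CN 0 in a pure tumor: no coverage
            d = (b - fb) ** 2 + (logr - fr) ** 2
            key = (d, total, -n_b)
            if best_key is None or key < best_key:
                best_key = key
                best = (n_a, n_b)
    if best is None:
        raise RuntimeError("no feasible allele copy-number pair")
    return best


@dataclass
class CnStateCall:
    """Copy-number state, allelic balance state and LOH flag of one segment."""

    state: str
    balance: str | None
    loh: bool


def classify_cn_state(
    cn_major: int,
    cn_minor: int,
    ploidy: float,
    logr_seg: float = 0.0,
    logr_contig: float = 0.0,
    length: float = np.inf,
    amp_max_length: float = 10e6,
    amp_min_major: int = 5,
    amp_logr_excess: float = 0.7,
) -> CnStateCall:
    """Classify one segment into copy-number and balance states.

    Gain/loss conditions are evaluated in a fixed order with the last
    matching condition winning: weak gain (total > round(psi)), medium gain
    (> 1.5 round(psi)), strong gain (> 2.5 round(psi)), shallow loss
    (< round(psi)), loss (< 0.5 round(psi)); otherwise neutral.  Ploidy is
    rounded half-to-even.  Focal segments shorter than 10 Mb with
    CN_major >= 5 and a segment LogR exceeding the chromosome mean by > 0.7
    override both states as *amplification*.  LOH is CN_minor = 0.
    """
    if cn_minor < 0 or cn_major < cn_minor:
        raise ValueError(f"require CN_major >= CN_minor >= 0, got ({cn_major}, {cn_minor})")
    total = cn_major + cn_minor
    p = round(float(ploidy))
    state = "neutral"
    for name, cond in (
        ("weak gain", total > p),
        ("medium gain", total > 1.5 * p),
        ("strong gain", total > 2.5 * p),
        ("shallow loss", total < p),
        ("loss", total < 0.5 * p),
    ):
        if cond:
            state = name

    if cn_minor > 0 and cn_major == cn_minor:
        balance: str | None = "balance"
    elif cn_major > cn_minor:
        cn_ratio = cn_major / total
        balance = "weak imbalance" if cn_ratio <= 2 / 3 else "strong imbalance"
    else:  # (0, 0): no DNA, no balance state defined
        balance = None

    is_amp = (
        length < amp_max_length
        and cn_major >= amp_min_major
        and (logr_seg - logr_contig) > amp_logr_excess
    )
    if is_amp:
        state = "amplification"
        balance = "amplification"
    return CnStateCall(state=state, balance=balance, loh=cn_minor == 0)


def gene_amplification(state: str, logr_gene: float, logr_cut: float = 2.5) -> bool:
    """A gene is amplified if its segment state is *amplification* or its
    mean SNP LogR exceeds ``logr_cut``."""
    if not np.isfinite(logr_gene):
        raise ValueError("logr_gene is undefined (no SNPs in gene)")
    return state == "amplification" or logr_gene > logr_cut


def _overlaps(segments: pd.DataFrame, chrom, start: int, end: int) -> pd.DataFrame:
    seg = segments[segments["chrom"] == chrom]
    ov_start = np.maximum(seg["start"].to_numpy(), start)
    ov_end = np.minimum(seg["end"].to_numpy(), end)
    ov = ov_end - ov_start + 1
    seg = seg.assign(overlap=ov)
    return seg[seg["overlap"] > 0]


def summarize_region(
    segments: pd.DataFrame,
    region: tuple,
    mode: str = "weighted_mean",
    value: str = "cn_ratio",
    amp_override: bool = False,
) -> float | str | None:
    """Summarize segment values over a genomic region.

    ``region`` is ``(chrom, start, end)`` in 1-based inclusive coordinates.
    ``weighted_mean`` averages ``value`` over overlapping segments weighted
    by overlap length; ``dominant_state`` returns the state with the largest
    total overlap.  With ``amp_override`` (used for 5 Mb bins) a region
    overlapping an *amplification* segment takes that segment's value
    directly — the amplified segment of largest overlap if several.
    Returns ``None`` for a region with no overlapping segment.
    """
    chrom, start, end = region
    seg = _overlaps(segments, chrom, start, end)
    if len(seg) == 0:
        return None
    if mode == "dominant_state":
        return seg.groupby("state")["overlap"].sum().idxmax()
    if mode != "weighted_mean":
        raise ValueError(f"unknown mode {mode!r}")
    if amp_override and "state" in seg.columns:
        amp = seg[seg["state"] == "amplification"]
        if len(amp) > 0:
            return float(amp.loc[amp["overlap"].idxmax(), value])
    vals = seg[value].to_numpy(float)
    w = seg["overlap"].to_numpy(float)
    ok = np.isfinite(vals)
    if not ok.any():
        return None
    return float(np.sum(vals[ok] * w[ok]) / np.sum(w[ok]))


def call_profile(
    sites: pd.DataFrame,
    purity: float,
    ploidy: float,
    gamma: float = 1.0,
    max_cn: int = 12,
    penalty: float | None = None,
    min_depth: int = 10,
    het_only: bool = True,
) -> pd.DataFrame:
    """Full per-sample profile: BAF/LogR, segmentation, inversion, states.

    ``sites`` columns: ``chrom, pos, refN, altN, refT, altT`` and optionally
    ``genotype`` ('0|1'/'1|0' phased het calls used for segmentation).
    Returns a segment table with columns ``chrom, start, end, n_major,
    n_minor, logr_seg, baf_seg, cn_total, cn_ratio, state, balance, loh``.
    """
    annotated, _ = compute_baf_logr(sites, min_depth=min_depth)
    if het_only and "genotype" in annotated.columns:
        het = annotated[annotated["genotype"].isin(["0|1", "1|0", "0/1", "1/0"])]
    else:
        het = annotated
    rows = []
    for chrom, grp in het.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        baf = grp["baf"].to_numpy()
        logr = grp["logr"].to_numpy()
        pos = grp["pos"].to_numpy()
        if len(grp) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 het sites, skipped")
            continue
        bps = segment_baf(baf, penalty=penalty)
        bounds = [0, *bps, len(grp)]
        logr_contig = float(np.nanmean(logr))
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            baf_seg = float(np.nanmean(np.abs(baf[lo:hi] - 0.5)) + 0.5)
            logr_seg = float(np.nanmean(logr[lo:hi]))
            n_a, n_b = estimate_allele_cn(baf_seg, logr_seg, purity, ploidy, gamma, max_cn)
            start, end = int(pos[lo]), int(pos[hi - 1])
            call = classify_cn_state(
                n_a, n_b, ploidy, logr_seg, logr_contig, length=end - start + 1
            )
            total = n_a + n_b
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_major": n_a,
                    "n_minor": n_b,
                    "baf_seg": baf_seg,
                    "logr_seg": logr_seg,
                    "cn_total": total,
                    "cn_ratio": n_a / total if total else np.nan,
                    "state": call.state,
                    "balance": call.balance,
                    "loh": call.loh,
                }
            )
    return pd.DataFrame(rows)
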