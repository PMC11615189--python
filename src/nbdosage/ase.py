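"""Allele-specific expression (ASE) and allelic expression imbalance (AEI).

RNA read counts at exonic heterozygous SNPs are filtered, checked for
bi-allelic signal against the per-sample sequencing noise rate, aggregated
to phased haplotype counts per gene, and tested for imbalance with an exact
two-sided binomial test against a 1:1 null.  The ASE ratio of a gene is
``max(A, B) / (A + B)`` over its haplotype counts, so it lives in
``[0.5, 1]`` and is invariant to haplotype relabeling.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def filter_sites(
    sites: pd.DataFrame,
    min_total: int = 8,
    min_allelic: int = 2,
    allelic_rule: str = "each",
) -> tuple[pd.DataFrame, int]:
    """Drop low-coverage ASE sites.

    Keeps sites with ``ref + alt >= min_total`` and, under the default
    ``allelic_rule='each'``, ``min(ref, alt) >= min_allelic`` (the stricter
    reading of "less than 2 allelic reads"); ``'either'`` requires only
    ``max(ref, alt) >= min_allelic``.  Returns (retained sites, n dropped).
    """
    ref = sites["ref_count"].to_numpy(float)
    alt = sites["alt_count"].to_numpy(float)
    keep = (ref + alt) >= min_total
    if allelic_rule == "each":
        keep &= np.minimum(ref, alt) >= min_allelic
    elif allelic_rule == "either":
        keep &= np.maximum(ref, alt) >= min_allelic
    else:
        raise ValueError(f"unknown allelic_rule {allelic_rule!r}")
    return sites.loc[keep].copy(), int((~keep).sum())


def noise_rate(sites: pd.DataFrame, floor: float = 1e-4) -> float:
    """Per-sample sequencing noise rate: total non-ref/non-alt reads over
    total raw depth.  Zero estimates are replaced by ``floor``."""
    p0 = sites["other_count"].sum() / sites["raw_depth"].sum()
    if p0 <= 0:
        warnings.warn(f"noise rate is zero; substituting floor {floor}")
        return floor
    return float(p0)


def biallelic_test(
    sites: pd.DataFrame, p0: float | None = None, alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """Flag sites whose minimum allele count exceeds the noise expectation.

    Upper-tail exact binomial test of ``min(ref, alt)`` successes in
    ``ref + alt`` trials at success probability ``p0`` (the sample noise
    rate), Benjamini-Hochberg adjusted across sites; sites rejected at
    ``alpha_fdr`` are classified bi-allelic.
    """
    out = sites.copy()
    if p0 is None:
        p0 = noise_rate(sites)
    kmin = np.minimum(out["ref_count"], out["alt_count"]).to_numpy(int)
    n = (out["ref_count"] + out["alt_count"]).to_numpy(int)
    # P(X >= kmin) under Binomial(n, p0)
    p = stats.binom.sf(kmin - 1, n, p0)
    reject, q, _, _ = multipletests(p, alpha=alpha_fdr, method="fdr_bh")
    out["p_biallelic"] = p
    out["q_biallelic"] = q
    out["biallelic"] = reject
    return out


def estimate_ref_bias(sites: pd.DataFrame) -> float:
    """Mean reference allele fraction over ASE sites in copy-balanced
    regions of a sample (0.5 = no mapping bias)."""
    if len(sites) == 0:
        warnings.warn("no qualifying sites for reference-bias estimate")
        return np.nan
    frac = sites["ref_count"] / (sites["ref_count"] + sites["alt_count"])
    return float(frac.mean())


def aggregate_haplotypes(
    sites: pd.DataFrame, min_counts: int = 10
) -> tuple[int, int] | None:
    """Sum phased allelic counts of one gene into haplotype counts (A, B).

    Each site's ``hap_a_allele`` column says which allele ('ref' or 'alt')
    lies on haplotype A.  Unphased sites are excluded with a warning.
    Returns ``None`` when the gene has fewer than ``min_counts`` total
    haplotype counts.
    """
    a = b = 0
    for row in sites.itertuples(index=False):
        which = getattr(row, "hap_a_allele", None)
        if which == "ref":
            a += row.ref_count
            b += row.alt_count
        elif which == "alt":
            a += row.alt_count
            b += row.ref_count
        else:
            warnings.warn("unphased site excluded from haplotype aggregation")
    if a + b < min_counts:
        return None
    return int(a), int(b)


def aei_test_single(a: int, b: int) -> float:
    """Exact two-sided binomial p for haplotype counts (A, B) at null 0.5.

    Two-sidedness follows the minimum-likelihood convention: the sum of all
    outcome probabilities no larger than the observed outcome's.
    """
    return stats.binomtest(a, a + b, 0.5, alternative="two-sided").pvalue


def aei_test(
    counts: pd.DataFrame, alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """AEI calls for a table of gene x sample haplotype counts ``A``, ``B``.

    Adds ``ase_ratio``, raw ``p``, BH-adjusted ``q`` (pooled across all
    observations in the table) and the ``aei`` flag at ``alpha_fdr``.
    """
    out = counts.copy()
    a = out["A"].to_numpy(int)
    b = out["B"].to_numpy(int)
    n = a + b
    if (n < 10).any():
        raise ValueError("all observations need A + B >= 10")
    out["ase_ratio"] = np.maximum(a, b) / n
    out["p"] = [aei_test_single(ai, bi) for ai, bi in zip(a, b)]
    reject, q, _, _ = multipletests(out["p"], alpha=alpha_fdr, method="fdr_bh")
    out["q"] = q
    out["aei"] = reject
    return out


def gene_ase_summary(
    gene_table: pd.DataFrame, imprinted_genes: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict | None]:
    """Per-gene AEI frequency and mean ASE ratio across samples, with an
    optional imprinting enrichment test.

    ``gene_table`` needs columns ``gene, aei, ase_ratio`` (one row per
    informative gene x sample observation).  Enrichment compares annotated
    imprinted genes against the rest on both statistics with one-sided
    Wilcoxon rank-sum tests (imprinted greater).
    """
    summary = (
        gene_table.groupby("gene")
        .agg(
            n_informative=("aei", "size"),
            aei_frequency=("aei", "mean"),
            mean_ase_ratio=("ase_ratio", "mean"),
        )
        .reset_index()
    )
    enrichment = None
    if imprinted_genes:
        mask = summary["gene"].isin(set(imprinted_genes))
        if mask.any() and (~mask).any():
            enrichment = {}
            for col in ("mean_ase_ratio", "aei_frequency"):
                res = stats.mannwhitneyu(
                    summary.loc[mask, col],
                    summary.loc[~mask, col],
                    alternative="greater",
                )
                enrichment[col] = float(res.pvalue)
    return summary, enrichment
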