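"""Genetic effects on gene expression and allele-specific expression.

Per gene, expression (or the ASE ratio) is modeled by ordinary least squares
on local genetic effects — lead cis-eQTL genotype, copy number, structural
variant breakpoints, somatic SNV burdens — plus covariates.  The variance
explained by each effect is its sequential (Type I) ANOVA sum of squares as
a fraction of the total sum of squares, computed in the fixed predictor
order listed below; significance per effect comes from the F statistic with
Bonferroni adjustment across genes (an FDR switch is provided).

The module also provides the cohort residualization used as the expression
measure throughout, the allelic-dosage (ASE-vs-expression) gene test, and
the ALT differential-expression scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXPRESSION_EFFECTS = ["eqtl_gt", "cn_logr", "sv", "snv_promoter", "snv_gene"]
EXPRESSION_COVARIATES = ["purity", "mycn_amp"]
ASE_EFFECTS = ["eqtl_het", "cn_ratio", "sv", "snv_promoter", "snv_gene"]
ASE_COVARIATES = ["purity", "mycn_amp", "log_coverage"]


def normalize_expression(
    counts: pd.DataFrame, cohort: Sequence[str]
) -> pd.DataFrame:
    """Cohort-residualized expression from a genes x samples count matrix.

    Counts are library-size scaled (counts per million), log1p transformed
    as a variance-stabilizing step, then regressed per gene on cohort
    membership; the residuals are the expression measure.  Genes with zero
    counts everywhere are dropped.
    """
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("sample with zero library size")
    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} genes with zero counts everywhere")
    cpm = counts.loc[nonzero] / libsize * 1e6
    logx = np.log1p(cpm)
    cohort = pd.Series(list(cohort), index=counts.columns)
    resid = logx.copy()
    for level in cohort.unique():
        cols = cohort.index[cohort == level]
        resid[cols] = logx[cols].sub(logx[cols].mean(axis=1), axis=0)
    return resid


@dataclass
class EffectDecomposition:
    """Sequential ANOVA variance fractions for one gene."""

    gene: str
    fractions: dict[str, float]  # effect -> SS_effect / SS_total
    residual_fraction: float
    pvalues: dict[str, float]
    n_obs: int
    skipped: dict[str, str] = field(default_factory=dict)


def _sequential_anova(
    y: np.ndarray, X: np.ndarray, names: list[str]
) -> tuple[dict[str, float], float, dict[str, float]]:
    """Type I sums of squares of ``y`` on columns of ``X`` added in order.

    Returns (fractions, residual fraction, F-test p-values).  Fractions and
    the residual fraction sum to 1 by construction.
    """
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("constant response")
    ones = np.ones((n, 1))
    rss_prev = ss_total
    design = ones
    ss = {}
    for j, name in enumerate(names):
        design = np.hstack([design, X[:, j : j + 1]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        ss[name] = max(rss_prev - rss, 0.0)
        rss_prev = rss
    rss_full = rss_prev
    rank_full = np.linalg.matrix_rank(design)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid
    pvals = {}
    for name in names:
        if ms_resid == 0:
            pvals[name] = 0.0 if ss[name] > 0 else 1.0
        else:
            f = ss[name] / 1.0 / ms_resid
            pvals[name] = float(stats.f.sf(f, 1, df_resid))
    fractions = {k: v / ss_total for k, v in ss.items()}
    return fractions, rss_full / ss_total, pvals


def _decompose(
    data: pd.DataFrame,
    response: str,
    effects: list[str],
    covariates: list[str],
    gene: str,
    min_obs: int,
) -> EffectDecomposition | None:
    cols = effects + covariates
    sub = data[[response] + cols].dropna()
    if len(sub) < min_obs:
        return None
    y = sub[response].to_numpy(float)
    names, columns, skipped = [], [], {}
    for c in cols:
        x = sub[c].to_numpy(float)
        if np.ptp(x) == 0:
            skipped[c] = "constant column"
            continue
        names.append(c)
        columns.append(x)
    X = np.column_stack(columns)
    fractions, resid_frac, pvals = _sequential_anova(y, X, names)
    return EffectDecomposition(
        gene=gene,
        fractions=fractions,
        residual_fraction=resid_frac,
        pvalues=pvals,
        n_obs=len(sub),
        skipped=skipped,
    )


def decompose_expression(
    data: pd.DataFrame, gene: str = "", min_obs: int = 20
) -> EffectDecomposition | None:
    """Variance decomposition of total expression for one gene.

    ``data`` holds one row per sample with columns ``expression`` plus the
    effects ``eqtl_gt, cn_logr, sv, snv_promoter, snv_gene`` and covariates
    ``purity, mycn_amp``.  Genes with fewer than ``min_obs`` complete
    observations return ``None``.
    """
    return _decompose(
        data, "expression", EXPRESSION_EFFECTS, EXPRESSION_COVARIATES, gene, min_obs
    )


def decompose_ase(
    data: pd.DataFrame, gene: str = "", min_obs: int = 20
) -> EffectDecomposition | None:
    """Variance decomposition of the ASE ratio for one gene.

    Effects are ``eqtl_het`` (heterozygosity of the lead eQTL), ``cn_ratio``,
    SV and SNV flags; covariates additionally include the log total allelic
    coverage at the ASE SNPs.
    """
    return _decompose(data, "ase_ratio", ASE_EFFECTS, ASE_COVARIATES, gene, min_obs)


def adjust_effect_pvalues(
    decompositions: Sequence[EffectDecomposition],
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Multiple-testing adjustment per effect across genes.

    Returns a long table ``gene, effect, ss_fraction, p, p_adj,
    significant``.  ``method`` is 'bonferroni' (default) or 'fdr_bh'.
    """
    rows = []
    for d in decompositions:
        for eff, frac in d.fractions.items():
            rows.append(
                {"gene": d.gene, "effect": eff, "ss_fraction": frac, "p": d.pvalues[eff]}
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    table["significant"] = False
    for eff, idx in table.groupby("effect").groups.items():
        reject, p_adj, _, _ = multipletests(
            table.loc[idx, "p"], alpha=alpha, method=method
        )
        table.loc[idx, "p_adj"] = p_adj
        table.loc[idx, "significant"] = reject
    return table


def _ftest_term(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> tuple[float, float]:
    """F-test p-value for the terms in ``X_full`` absent from ``X_reduced``."""
    n = len(y)
    coef_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_f = float(np.sum((y - X_full @ coef_f) ** 2))
    coef_r, _, _, _ = np.linalg.lstsq(X_reduced, y, rcond=None)
    rss_r = float(np.sum((y - X_reduced @ coef_r) ** 2))
    df_num = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    df_den = n - np.linalg.matrix_rank(X_full)
    if df_num <= 0 or df_den <= 0 or rss_f <= 0:
        return np.nan, np.nan
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return f, float(stats.f.sf(f, df_num, df_den))


def ad_gene_test(
    data: pd.DataFrame,
    covariate_cols: Sequence[str] = ("purity", "log_coverage", "normal_dna_ratio"),
    cohort_col: str | None = "cohort",
    min_obs: int = 10,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Allelic-dosage test: per-gene association of ASE ratio with expression.

    ``data`` holds rows (gene x sample) with ``gene, ase_ratio, expression``
    plus covariates.  Per gene with >= ``min_obs`` informative samples the
    ASE ratio is regressed on expression and covariates; the expression term
    is tested by F-test and BH-adjusted across genes.  A negative
    coefficient means bi-allelic activation raises expression (imprinting
    loss pattern); mono-allelic amplification gives a positive one.
    """
    rows = []
    for gene, grp in data.groupby("gene"):
        cols = ["ase_ratio", "expression", *covariate_cols]
        if cohort_col and cohort_col in grp.columns:
            cols.append(cohort_col)
        sub = grp[cols].dropna()
        if len(sub) < min_obs or sub["expression"].nunique() < 2:
            continue
        y = sub["ase_ratio"].to_numpy(float)
        parts = [np.ones(len(sub)), sub["expression"].to_numpy(float)]
        for c in covariate_cols:
            x = sub[c].to_numpy(float)
            if np.ptp(x) > 0:
                parts.append(x)
        if cohort_col and cohort_col in sub.columns:
            dummies = pd.get_dummies(sub[cohort_col], drop_first=True)
            for c in dummies.columns:
                parts.append(dummies[c].to_numpy(float))
        X_full = np.column_stack(parts)
        X_red = np.delete(X_full, 1, axis=1)
        coef, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
        _, p = _ftest_term(y, X_full, X_red)
        rows.append({"gene": gene, "coefficient": float(coef[1]), "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    ok = out["p"].notna()
    out["q"] = np.nan
    out["ad_gene"] = False
    if ok.any():
        reject, q, _, _ = multipletests(out.loc[ok, "p"], alpha=alpha_fdr, method="fdr_bh")
        out.loc[ok, "q"] = q
        out.loc[ok, "ad_gene"] = reject
    return out


def alt_de_scan(
    expression: pd.DataFrame,
    alt: Sequence[bool],
    covariates: pd.DataFrame,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential expression between ALT and non-ALT tumors.

    Per gene (rows of ``expression``), a linear model of expression on ALT
    status plus covariates is compared to the covariate-only model by a
    chi-squared ANOVA (likelihood ratio); p-values are BH-adjusted across
    genes.  Constant covariates are dropped with a warning.  Returns
    ``gene, coefficient, p, q, significant``.
    """
    alt = np.asarray(alt, dtype=float)
    if alt.min() == alt.max():
        raise ValueError("both ALT and non-ALT samples required")
    n = expression.shape[1]
    parts = [np.ones(n)]
    for c in covariates.columns:
        x = pd.to_numeric(covariates[c], errors="coerce").to_numpy(float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            warnings.warn(f"dropping constant covariate {c!r}")
            continue
        parts.append(x)
    X_red = np.column_stack(parts)
    X_full = np.column_stack([X_red[:, :1], alt, X_red[:, 1:]])
    rows = []
    for gene, y in expression.iterrows():
        y = y.to_numpy(float)
        if np.ptp(y) == 0:
            continue
        coef_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
        rss_f = float(np.sum((y - X_full @ coef_f) ** 2))
        coef_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_r = float(np.sum((y - X_red @ coef_r) ** 2))
        if rss_f <= 0:
            continue
        lr = n * np.log(rss_r / rss_f)
        p = float(stats.chi2.sf(lr, 1))
        rows.append({"gene": gene, "coefficient": float(coef_f[1]), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        reject, q, _, _ = multipletests(out["p"], alpha=alpha_fdr, method="fdr_bh")
        out["q"] = q
        out["significant"] = reject
    return out
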