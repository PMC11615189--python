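"""Synthetic tumor cohort generator with planted ground truth.

Emulates every input the analysis consumes — per-SNP allelic depths for
tumor and matched normal, phased genotypes, allele-specific copy-number
segments under purity/ploidy mixing, allelic RNA counts driven by allelic
copy ratio plus eQTL and imprinting effects, a bimodal TERT expression
signal, telomere-repeat-bearing WGS reads, TERRA read pairs, binned ATRX
coverage with exon deletions, and clinical/survival labels — so the whole
pipeline is testable against known truth without any sequencing data.

The genome is abstract: chromosomes are integer-indexed with a common
configurable length and no reference sequence.  Reads are fixed 150 bp;
telomeric reads are exact repeat concatenations plus random flanks.  All
randomness flows from the single config seed through named substreams, so
identical configs produce identical output files byte for byte.

Default parameters mirror the study conditions of a 115-tumor neuroblastoma
cohort: purity at least 0.6, 38% whole-genome doubled, telomere-maintenance
class frequencies CTM 43 : ALT 20 : Mix 1 : None 51, two RNA-library
cohorts of 52 and 63 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnprofile import forward_baf_logr  # generative counterpart, re-exported
from .errors import ConfigError
from .tmm import MixtureFit, TELOMERE_MOTIF, TELOMERE_MOTIF_RC

__all__ = [
    "SimConfig", "SimTruth", "SimBundle", "simulate_cohort",
    "simulate_gene_ase", "simulate_effect_gene", "ase_probability",
    "analytic_tert_threshold", "forward_baf_logr",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_samples: int = 115
    n_chromosomes: int = 22
    chrom_length: int = 100_000_000
    snps_per_chrom: int = 300
    genes_per_chrom: int = 20
    purity_range: tuple[float, float] = (0.6, 1.0)
    ploidy_options: tuple[float, float] = (2.0, 4.0)  # (non-WGD, WGD) baseline
    wgd_fraction: float = 44 / 115
    segment_rate: float = 1.5  # expected breakpoints per chromosome
    noise_sd_baf: float = 0.02
    noise_sd_logr: float = 0.15
    depth_mean: float = 30.0  # mean WGS depth at SNPs (even: exact noise-free ratios)
    rna_depth_mean: float = 60.0
    ase_sites_per_gene: int = 3
    # two-component TERT expression Z mixture: (means, sds, weights)
    tmm_mixture: dict = field(
        default_factory=lambda: {
            "means": (-0.5, 1.5),
            "sds": (0.5, 0.5),
            "weights": (0.75, 0.25),
        }
    )
    tmm_proportions: dict = field(
        default_factory=lambda: {
            "CTM": 43 / 115,
            "ALT": 20 / 115,
            "Mix": 1 / 115,
            "None": 51 / 115,
        }
    )
    imprinted_fraction: float = 0.05
    eqtl_fraction: float = 0.30
    beta_binomial_rho: float = 0.0  # allelic-count overdispersion, off by default
    telomere_reads_total: int = 4000
    read_length: int = 150
    atrx_bins: int = 400
    terra_fragments: int = 400
    seed: int = 0

    def validate(self) -> None:
        def _prop(name):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

        for name in ("wgd_fraction", "imprinted_fraction", "eqtl_fraction",
                     "beta_binomial_rho"):
            _prop(name)
        lo, hi = self.purity_range
        if not (0.3 <= lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must be within [0.3, 1.0], got {self.purity_range}")
        for name in ("n_samples", "n_chromosomes", "snps_per_chrom",
                     "genes_per_chrom", "telomere_reads_total", "atrx_bins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        w = self.tmm_mixture["weights"]
        if abs(sum(w) - 1) > 1e-9:
            raise ConfigError(f"tmm_mixture weights must sum to 1, got {w}")
        p = self.tmm_proportions
        if abs(sum(p.values()) - 1) > 1e-9:
            raise ConfigError(f"tmm_proportions must sum to 1, got {p}")
        if self.segment_rate < 0:
            raise ConfigError("segment_rate must be >= 0")
        if self.noise_sd_baf < 0 or self.noise_sd_logr < 0:
            raise ConfigError("noise standard deviations must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth: every emitted observation traces back here."""

    samples: pd.DataFrame  # per-sample purity, ploidy, WGD, TMM, flags, tlr, ...
    segments: pd.DataFrame  # per sample x segment true (CN_major, CN_minor)
    genes: pd.DataFrame  # per-gene eQTL effect, imprinting, dosage coefficient
    tert_threshold: float  # analytic posterior crossing of the true mixture


@dataclass
class SimBundle:
    """All synthetic input tables and read sets, keyed like real inputs."""

    clinical: pd.DataFrame
    snps: pd.DataFrame  # long table over samples
    segments_truth: pd.DataFrame
    ase_sites: pd.DataFrame
    gene_counts: pd.DataFrame  # per gene x sample haplotype counts A, B
    expression: pd.DataFrame  # genes x samples raw counts
    gene_inputs: pd.DataFrame  # per gene x sample effect predictors
    atrx_bins: pd.DataFrame
    fastq: dict  # sample -> {"tumor": [seq...], "normal": [seq...]}
    terra: dict  # sample -> {"pairs": [(r1, r2)...], "total_fragments": int}
    vcf_records: pd.DataFrame  # phased genotypes, one row per site x sample


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "samples", "segments", "snps", "genes", "expression",
        "ase", "fastq", "atrx", "terra", "clinical",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def analytic_tert_threshold(mixture: dict, posterior_cut: float = 0.95) -> float:
    """Posterior crossing of the true TERT mixture on a dense grid."""
    fit = MixtureFit(
        means=tuple(mixture["means"]),
        sds=tuple(mixture["sds"]),
        weights=tuple(mixture["weights"]),
        threshold=np.nan,
    )
    grid = np.linspace(fit.means[0], fit.means[1] + 12 * max(fit.sds), 400_001)
    post = fit.posterior_high(grid)
    return float(grid[np.nonzero(post >= posterior_cut)[0][0]])


def _truncated_normal(rng, mean, sd, size, lower=-np.inf, upper=np.inf):
    out = np.empty(size)
    todo = np.arange(size)
    while len(todo):
        draw = rng.normal(mean, sd, size=len(todo))
        ok = (draw > lower) & (draw < upper)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _simulate_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    labels = rng.choice(
        list(cfg.tmm_proportions), size=n, p=list(cfg.tmm_proportions.values())
    )
    mu_lo, mu_hi = cfg.tmm_mixture["means"]
    sd_lo, sd_hi = cfg.tmm_mixture["sds"]
    thr = analytic_tert_threshold(cfg.tmm_mixture)

    mycn = np.zeros(n, bool)
    tert_re = np.zeros(n, bool)
    tert_high = np.zeros(n, bool)
    tert_z = np.empty(n)
    tlr = np.empty(n)
    for i, lab in enumerate(labels):
        ctm_like = lab in ("CTM", "Mix")
        if ctm_like:
            mech = rng.choice(["mycn", "tert_re", "tert_high"], p=[0.53, 0.37, 0.10])
            if lab == "Mix":  # mixed phenotype arises with a TERT rearrangement
                mech = "tert_re"
            mycn[i] = mech == "mycn"
            tert_re[i] = mech == "tert_re"
            tert_high[i] = mech == "tert_high"
        if ctm_like and tert_high[i]:
            # truth label requires Z beyond the analytic threshold
            tert_z[i] = _truncated_normal(rng, mu_hi, sd_hi, 1, lower=thr)[0]
        elif ctm_like:
            tert_z[i] = rng.normal(mu_hi, sd_hi)
        else:
            tert_z[i] = _truncated_normal(rng, mu_lo, sd_lo, 1, upper=thr)[0]
        if lab in ("ALT", "Mix"):
            tlr[i] = _truncated_normal(rng, 1.2, 0.25, 1, lower=0.7)[0]
        else:
            tlr[i] = _truncated_normal(rng, 0.0, 0.12, 1, upper=0.35)[0]

    wgd = rng.random(n) < cfg.wgd_fraction
    purity = rng.uniform(*cfg.purity_range, size=n)
    atrx = np.where(
        labels == "ALT", rng.random(n) < 0.45, rng.random(n) < 0.02
    )
    l_normal = rng.uniform(5.0, 9.0, size=n)  # telomere length proxy, kb
    risk = np.where(
        (labels != "None") | (rng.random(n) < 0.15), "high",
        np.where(rng.random(n) < 0.1, "medium", "low"),
    )
    p_dead = 1 / (1 + np.exp(-(-1.8 + 1.2 * mycn + 1.0 * (labels != "None"))))
    deceased = rng.random(n) < p_dead
    return pd.DataFrame(
        {
            "sample": [f"S{i:03d}" for i in range(n)],
            "cohort": np.where(np.arange(n) < round(n * 52 / 115), "A", "B"),
            "purity": purity,
            "wgd": wgd,
            "tmm_label": labels,
            "mycn_amp": mycn,
            "tert_re": tert_re,
            "tert_high_true": tert_high,
            "tert_z_true": tert_z,
            "tlr_true": tlr,
            "atrx_deleted": atrx,
            "l_normal": l_normal,
            "l_tumor": l_normal * np.exp(tlr),
            "risk": risk,
            "age": rng.lognormal(0.0, 0.9, size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "stage4": rng.random(n) < 0.4,
            "deceased": deceased,
        }
    )


def _simulate_segments(
    cfg: SimConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    half = cfg.chrom_length // 2
    for s in samples.itertuples(index=False):
        base = (2, 2) if s.wgd else (1, 1)
        is_alt = s.tmm_label in ("ALT", "Mix")
        for chrom in range(1, cfg.n_chromosomes + 1):
            n_bp = rng.poisson(cfg.segment_rate)
            bps = np.sort(rng.integers(2, cfg.chrom_length, size=n_bp))
            bounds = [1, *bps.tolist(), cfg.chrom_length]
            for j in range(len(bounds) - 1):
                start, end = bounds[j], bounds[j + 1]
                if j > 0:
                    start += 1
                major, minor = base
                if rng.random() < 0.40:
                    ev = rng.choice(
                        ["gain1", "gain_both", "loss1", "loh", "gain2"],
                        p=[0.35, 0.10, 0.30, 0.15, 0.10],
                    )
                    if ev == "gain1":
                        major += 1
                    elif ev == "gain_both":
                        major += 1
                        minor += 1
                    elif ev == "loss1":
                        minor = max(minor - 1, 0)
                    elif ev == "loh":
                        minor = 0
                    elif ev == "gain2":
                        major += rng.integers(2, 4)
                # ALT-linked arm lesions: 11q loss and 17q gain
                if is_alt and start > half:
                    if chrom == 11 and rng.random() < 0.9:
                        minor = max(min(minor, base[1] - 1), 0)
                    if chrom == 17 and rng.random() < 0.9:
                        major = max(major, base[0] + 1)
                rows.append(
                    {
                        "sample": s.sample,
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "n_major": int(major),
                        "n_minor": int(minor),
                        "major_hap": "A" if rng.random() < 0.5 else "B",
                    }
                )
        # occasional focal amplification on a random chromosome
        if rng.random() < 0.25:
            chrom = int(rng.integers(1, cfg.n_chromosomes + 1))
            start = int(rng.integers(1, cfg.chrom_length - 2_000_000))
            rows.append(
                {
                    "sample": s.sample,
                    "chrom": chrom,
                    "start": start,
                    "end": start + 2_000_000,
                    "n_major": int(rng.integers(6, 11)),
                    "n_minor": 1,
                    "major_hap": "A",
                }
            )
    seg = pd.DataFrame(rows)
    seg["cn_total"] = seg["n_major"] + seg["n_minor"]
    return seg


def _sample_ploidy(segments: pd.DataFrame) -> pd.Series:
    length = segments["end"] - segments["start"] + 1
    w = segments.assign(w=length * segments["cn_total"], length=length)
    g = w.groupby("sample")
    return g["w"].sum() / g["length"].sum()


def _segment_lookup(segments: pd.DataFrame):
    """sample -> chrom -> (starts, ends, majors, minors, major_haps)."""
    table: dict = {}
    for (smp, chrom), grp in segments.groupby(["sample", "chrom"]):
        grp = grp.sort_values("start")
        table.setdefault(smp, {})[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["n_major"].to_numpy(),
            grp["n_minor"].to_numpy(),
            grp["major_hap"].to_numpy(),
        )
    return table


def _locate(lookup_chrom, pos: np.ndarray):
    starts, ends, majors, minors, haps = lookup_chrom
    idx = np.searchsorted(starts, pos, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    return majors[idx], minors[idx], haps[idx]


def _simulate_snps(
    cfg: SimConfig,
    samples: pd.DataFrame,
    lookup,
    ploidy: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-SNP allelic depth tables for tumor and normal, all samples."""
    panel = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        pos = np.sort(
            rng.choice(cfg.chrom_length - 2, size=cfg.snps_per_chrom, replace=False) + 1
        )
        ref = rng.choice(BASES, size=cfg.snps_per_chrom)
        alt = np.array(
            [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
        )
        panel.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}))
    panel = pd.concat(panel, ignore_index=True)

    deterministic = cfg.noise_sd_baf == 0 and cfg.noise_sd_logr == 0
    per_copy = cfg.depth_mean / 2
    frames = []
    for s in samples.itertuples(index=False):
        rho = s.purity
        psi = ploidy[s.sample]
        gts = rng.choice(["0/0", "0|1", "1|0", "1/1"], size=len(panel),
                         p=[0.3, 0.25, 0.25, 0.2])
        major = np.empty(len(panel), int)
        minor = np.empty(len(panel), int)
        hapA_major = np.empty(len(panel), bool)
        for chrom, grp in panel.groupby("chrom"):
            m, mi, hp = _locate(lookup[s.sample][chrom], grp["pos"].to_numpy())
            major[grp.index] = m
            minor[grp.index] = mi
            hapA_major[grp.index] = hp == "A"
        total = major + minor
        # number of copies carrying the alt allele
        alt_on_a = np.isin(gts, ["1|0", "1/1"])  # '1|0': alt on haplotype A
        n_alt = np.where(
            np.isin(gts, ["0/0"]), 0,
            np.where(
                np.isin(gts, ["1/1"]), total,
                np.where(alt_on_a == hapA_major, major, minor),
            ),
        )
        mix_total = (1 - rho) * 2 + rho * total
        # germline copies of the alt allele in the admixed normal cells
        germ_alt = np.where(
            np.isin(gts, ["0/0"]), 0, np.where(np.isin(gts, ["1/1"]), 2, 1)
        )
        baf_exp = np.where(
            mix_total > 0,
            ((1 - rho) * germ_alt / 2 * 2 + rho * n_alt) / np.maximum(mix_total, 1e-12),
            0.5,
        )
        if deterministic:
            d_n = np.full(len(panel), int(cfg.depth_mean))
            alt_n = np.round(d_n * germ_alt / 2).astype(int)
            d_t = np.round(per_copy * mix_total).astype(int)
            alt_t = np.round(d_t * baf_exp).astype(int)
        else:
            d_n = rng.poisson(cfg.depth_mean, size=len(panel))
            alt_n = rng.binomial(d_n, germ_alt / 2)
            eps = rng.normal(0, cfg.noise_sd_logr, size=len(panel))
            d_t = rng.poisson(per_copy * mix_total * 2**eps)
            p = np.clip(baf_exp + rng.normal(0, cfg.noise_sd_baf, size=len(panel)), 0, 1)
            alt_t = rng.binomial(d_t, p)
        frames.append(
            pd.DataFrame(
                {
                    "sample": s.sample,
                    "chrom": panel["chrom"],
                    "pos": panel["pos"],
                    "ref": panel["ref"],
                    "alt": panel["alt"],
                    "refN": d_n - alt_n,
                    "altN": alt_n,
                    "refT": d_t - alt_t,
                    "altT": alt_t,
                    "genotype": gts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _simulate_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        pos = np.sort(rng.integers(1, cfg.chrom_length, size=cfg.genes_per_chrom))
        for j, p in enumerate(pos):
            rows.append(
                {
                    "gene": f"G{chrom:02d}_{j:03d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "is_eqtl": rng.random() < cfg.eqtl_fraction,
                    "eqtl_beta": rng.normal(0, 0.4),
                    "maf": rng.uniform(0.1, 0.5),
                    "imprinted": rng.random() < cfg.imprinted_fraction,
                    "dosage_coef": rng.uniform(0.5, 1.5),
                    "base_expr": rng.uniform(3.5, 6.0),  # log scale
                }
            )
    genes = pd.DataFrame(rows)
    genes.loc[~genes["is_eqtl"], "eqtl_beta"] = 0.0
    return genes


def simulate_gene_ase(
    p_hap_a: float,
    depth: int,
    rng: np.random.Generator,
    overdispersion: float = 0.0,
) -> tuple[int, int]:
    """Draw haplotype counts (A, B) for one gene x sample observation.

    Counts are binomial at success probability ``p_hap_a`` (the allelic copy
    ratio of haplotype A modulated by planted eQTL/imprinting effects), or
    beta-binomial when ``overdispersion`` (the intraclass rho) is positive.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if overdispersion > 0:
        conc = (1 - overdispersion) / overdispersion
        p = rng.beta(p_hap_a * conc, (1 - p_hap_a) * conc)
    else:
        p = p_hap_a
    a = int(rng.binomial(depth, p))
    return a, depth - a


def ase_probability(
    cn_a: float,
    cn_b: float,
    purity: float,
    eqtl_logodds: float = 0.0,
    imprinted_to_a: bool | None = None,
    imprint_ratio: float = 0.95,
) -> float:
    """Expected haplotype-A RNA fraction from allelic copy ratio + effects."""
    mix_a = (1 - purity) * 1 + purity * cn_a
    mix_b = (1 - purity) * 1 + purity * cn_b
    p = mix_a / (mix_a + mix_b) if (mix_a + mix_b) > 0 else 0.5
    if eqtl_logodds:
        odds = p / (1 - p) * np.exp(eqtl_logodds) if p < 1 else np.inf
        p = odds / (1 + odds) if np.isfinite(odds) else 1.0
    if imprinted_to_a is not None:
        p = imprint_ratio if imprinted_to_a else 1 - imprint_ratio
    return float(np.clip(p, 1e-6, 1 - 1e-6))


def _multinomial_split(rng, counts: np.ndarray, k: int) -> np.ndarray:
    """Split each count uniformly into ``k`` cells by binomial thinning."""
    remaining = counts.copy()
    parts = []
    for j in range(k, 1, -1):
        drawn = rng.binomial(remaining, 1.0 / j)
        parts.append(drawn)
        remaining = remaining - drawn
    parts.append(remaining)
    return np.column_stack(parts)


def _simulate_rna(
    cfg: SimConfig,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    lookup,
    rng: np.random.Generator,
):
    """Expression counts, gene x sample haplotype counts, ASE site table,
    per-gene effect-predictor table (vectorized over samples per gene)."""
    n = len(samples)
    k = cfg.ase_sites_per_gene
    sample_ids = samples["sample"].to_numpy()
    purity = samples["purity"].to_numpy()
    cohort_b = (samples["cohort"] == "B").to_numpy()
    expr = np.zeros((len(genes), n))
    gene_frames, ase_frames, input_frames = [], [], []

    for gi, g in enumerate(genes.itertuples(index=False)):
        geno = rng.binomial(2, g.maf, size=n)
        sv = rng.random(n) < 0.02
        snv_prom = rng.random(n) < 0.01
        snv_gene = rng.random(n) < 0.03
        imprint_a = rng.random(n) < 0.5

        major = np.empty(n, int)
        minor = np.empty(n, int)
        hap_a_is_major = np.empty(n, bool)
        pos_arr = np.array([g.pos])
        for si, smp in enumerate(sample_ids):
            m, mi, hp = _locate(lookup[smp][g.chrom], pos_arr)
            major[si], minor[si], hap_a_is_major[si] = m[0], mi[0], hp[0] == "A"
        cn_a = np.where(hap_a_is_major, major, minor)
        cn_b = np.where(hap_a_is_major, minor, major)
        mix_a = (1 - purity) + purity * cn_a
        mix_b = (1 - purity) + purity * cn_b
        p_a = np.where(mix_a + mix_b > 0, mix_a / np.maximum(mix_a + mix_b, 1e-12), 0.5)
        het = geno == 1
        if g.eqtl_beta:
            odds = p_a / np.clip(1 - p_a, 1e-12, None) * np.exp(g.eqtl_beta)
            p_a = np.where(het, odds / (1 + odds), p_a)
        if g.imprinted:
            p_a = np.where(imprint_a, 0.95, 0.05)
        p_a = np.clip(p_a, 1e-6, 1 - 1e-6)

        depth = np.maximum(rng.poisson(cfg.rna_depth_mean, size=n), 1)
        if cfg.beta_binomial_rho > 0:
            conc = (1 - cfg.beta_binomial_rho) / cfg.beta_binomial_rho
            p_draw = rng.beta(p_a * conc, (1 - p_a) * conc)
        else:
            p_draw = p_a
        a = rng.binomial(depth, p_draw)
        b = depth - a

        total = major + minor
        mix_total = (1 - purity) * 2 + purity * total
        logr_true = np.log2(mix_total / 2)
        mu = g.base_expr + g.dosage_coef * logr_true + g.eqtl_beta * 0.5 * geno + 0.3 * cohort_b
        expr[gi] = rng.poisson(np.exp(mu))

        gene_frames.append(
            pd.DataFrame({"sample": sample_ids, "gene": g.gene, "A": a, "B": b})
        )
        input_frames.append(
            pd.DataFrame(
                {
                    "sample": sample_ids,
                    "gene": g.gene,
                    "eqtl_gt": geno,
                    "eqtl_het": het.astype(int),
                    "cn_logr": logr_true,
                    "cn_ratio": np.where(total > 0, major / np.maximum(total, 1), np.nan),
                    "sv": sv.astype(int),
                    "snv_promoter": snv_prom.astype(int),
                    "snv_gene": snv_gene.astype(int),
                }
            )
        )
        # distribute haplotype counts over k exonic het SNP sites
        a_split = _multinomial_split(rng, a, k)
        b_split = _multinomial_split(rng, b, k)
        hap_ref = rng.random((n, k)) < 0.5  # site's haplotype-A allele is ref
        ref_c = np.where(hap_ref, a_split, b_split)
        alt_c = np.where(hap_ref, b_split, a_split)
        other = rng.binomial(ref_c + alt_c, 0.005)
        ase_frames.append(
            pd.DataFrame(
                {
                    "sample": np.repeat(sample_ids, k),
                    "gene": g.gene,
                    "chrom": g.chrom,
                    "pos": np.tile(g.pos + np.arange(k) * 100, n),
                    "ref_count": ref_c.ravel(),
                    "alt_count": alt_c.ravel(),
                    "other_count": other.ravel(),
                    "raw_depth": (ref_c + alt_c + other).ravel(),
                    "hap_a_allele": np.where(hap_ref.ravel(), "ref", "alt"),
                }
            )
        )
    # TERT expression row encoding the planted Z mixture
    tert = np.exp(5.0 + 0.8 * samples["tert_z_true"].to_numpy())
    expr_df = pd.DataFrame(expr, index=genes["gene"], columns=samples["sample"])
    expr_df.loc["TERT"] = rng.poisson(tert)
    return (
        expr_df,
        pd.concat(gene_frames, ignore_index=True),
        pd.concat(ase_frames, ignore_index=True),
        pd.concat(input_frames, ignore_index=True),
    )


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seqs(rng, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    arr = _BASE_BYTES[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode() for row in arr]


def _random_seq(rng, length: int) -> str:
    return _random_seqs(rng, 1, length)[0]


def _telomeric_read(rng, length: int) -> str:
    """Exact repeat concatenation plus a random flank, either strand."""
    motif = TELOMERE_MOTIF if rng.random() < 0.5 else TELOMERE_MOTIF_RC
    n_rep = int(rng.integers(10, length // 6 + 1))
    core = motif * n_rep
    flank = _random_seq(rng, length - len(core))
    return (core + flank)[:length]


def _simulate_fastq(cfg: SimConfig, samples: pd.DataFrame, rng) -> dict:
    out = {}
    for s in samples.itertuples(index=False):
        reads = {}
        for tissue, L in (("tumor", s.l_tumor), ("normal", s.l_normal)):
            frac = min(0.01 * L, 0.5)
            n_tel = rng.binomial(cfg.telomere_reads_total, frac)
            seqs = [_telomeric_read(rng, cfg.read_length) for _ in range(n_tel)]
            seqs += _random_seqs(rng, cfg.telomere_reads_total - n_tel, cfg.read_length)
            order = rng.permutation(len(seqs))
            reads[tissue] = [seqs[i] for i in order]
        out[s.sample] = reads
    return out


def _simulate_terra(cfg: SimConfig, samples: pd.DataFrame, rng) -> dict:
    out = {}
    for s in samples.itertuples(index=False):
        rate = 30e-6 if s.tmm_label in ("ALT", "Mix") else 8e-6
        total = 1_000_000
        n_tel = rng.poisson(rate * total)
        mates = _random_seqs(rng, n_tel, cfg.read_length)
        pairs = [
            (_telomeric_read(rng, cfg.read_length), mate) for mate in mates
        ]
        n_fill = max(cfg.terra_fragments - len(pairs), 0)
        fill = _random_seqs(rng, 2 * n_fill, cfg.read_length)
        pairs += list(zip(fill[:n_fill], fill[n_fill:]))
        out[s.sample] = {"pairs": pairs, "total_fragments": total}
    return out


def _simulate_atrx(cfg: SimConfig, samples: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for s in samples.itertuples(index=False):
        sig = rng.normal(0.0, 0.2, size=cfg.atrx_bins)
        if s.atrx_deleted:
            frac = rng.uniform(0.3, 0.5)
            width = int(frac * cfg.atrx_bins)
            start = int(rng.integers(0, cfg.atrx_bins - width))
            sig[start : start + width] += -2.0
        n_n = np.full(cfg.atrx_bins, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "sample": s.sample,
                    "bin_start": np.arange(cfg.atrx_bins) * 50 + 1,
                    "tumor_norm": 2.0**sig,
                    "normal_norm": n_n,
                    "signal": sig,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: SimConfig) -> tuple[SimTruth, SimBundle]:
    """Generate the full synthetic cohort with planted truth.

    Identical configs (including the seed) produce identical outputs.
    """
    config.validate()
    st = _streams(config.seed)
    samples = _simulate_samples(config, st["samples"])
    segments = _simulate_segments(config, samples, st["segments"])
    ploidy = _sample_ploidy(segments)
    samples["ploidy"] = samples["sample"].map(ploidy)
    lookup = _segment_lookup(segments)
    snps = _simulate_snps(config, samples, lookup, ploidy, st["snps"])
    genes = _simulate_genes(config, st["genes"])
    expression, gene_counts, ase_sites, gene_inputs = _simulate_rna(
        config, samples, genes, lookup, st["expression"]
    )
    fastq = _simulate_fastq(config, samples, st["fastq"])
    terra = _simulate_terra(config, samples, st["terra"])
    atrx_bins = _simulate_atrx(config, samples, st["atrx"])

    clinical = samples[
        [
            "sample", "cohort", "purity", "ploidy", "mycn_amp", "tert_re",
            "risk", "age", "sex", "stage4", "deceased",
        ]
    ].copy()
    vcf_records = snps.loc[
        :, ["sample", "chrom", "pos", "ref", "alt", "genotype"]
    ].copy()

    truth = SimTruth(
        samples=samples,
        segments=segments,
        genes=genes,
        tert_threshold=analytic_tert_threshold(config.tmm_mixture),
    )
    bundle = SimBundle(
        clinical=clinical,
        snps=snps,
        segments_truth=segments,
        ase_sites=ase_sites,
        gene_counts=gene_counts,
        expression=expression,
        gene_inputs=gene_inputs,
        atrx_bins=atrx_bins,
        fastq=fastq,
        terra=terra,
        vcf_records=vcf_records,
    )
    return truth, bundle


def simulate_effect_gene(
    n: int,
    cn_fraction: float,
    rng: np.random.Generator,
    response: str = "expression",
) -> pd.DataFrame:
    """One gene's per-sample table with a planted copy-number variance share.

    The copy-number predictor is standard normal and its coefficient is
    chosen so that it contributes ``cn_fraction`` of the response variance;
    remaining predictors and covariates are independent noise.
    """
    if not 0 <= cn_fraction < 1:
        raise ValueError("cn_fraction must be in [0, 1)")
    b = np.sqrt(cn_fraction / (1 - cn_fraction))
    cn = rng.normal(size=n)
    y = b * cn + rng.normal(size=n)
    df = pd.DataFrame(
        {
            "eqtl_gt": rng.binomial(2, 0.3, size=n),
            "eqtl_het": rng.binomial(1, 0.4, size=n),
            "cn_logr": cn,
            "cn_ratio": cn,
            "sv": rng.binomial(1, 0.05, size=n),
            "snv_promoter": rng.binomial(1, 0.03, size=n),
            "snv_gene": rng.binomial(1, 0.05, size=n),
            "purity": rng.uniform(0.6, 1.0, size=n),
            "mycn_amp": rng.binomial(1, 0.2, size=n),
            "log_coverage": rng.normal(4, 0.5, size=n),
        }
    )
    df[response] = y
    return df
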