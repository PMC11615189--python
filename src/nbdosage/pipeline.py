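"""End-to-end cohort analysis: simulate -> cn -> tmm -> ase -> effects -> assoc.

Each stage consumes tables produced by the previous one, writes TSV outputs
plus a machine-readable JSON summary, and is individually re-runnable.  All
randomness flows from the single run seed through named substreams, so a
re-run with the same configuration reproduces outputs byte-identically.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import cnprofile, events, geneffects, io, synthdata, tmm as tmm_mod
from .errors import ConfigError, InputError

STAGES = ("simulate", "cn", "tmm", "ase", "effects", "assoc")


@dataclass
class RunConfig:
    outdir: str = "nbdosage_run"
    seed: int = 0
    stages: tuple = STAGES
    sim: synthdata.SimConfig | None = None
    cn_penalty: float | None = None
    tlr_cut: float = 0.5
    posterior_cut: float = 0.95
    alpha_fdr: float = 0.05
    alpha_fwer: float = 0.05
    bin_size: int = 5_000_000


def summarize_bins(
    segments: pd.DataFrame,
    chrom_length: int,
    bin_size: int = 5_000_000,
    value: str = "cn_ratio",
) -> pd.Series:
    """Overlap-weighted mean of ``value`` in non-overlapping genomic bins.

    Bins overlapping an *amplification* segment take that segment's value
    directly (largest overlap wins), preserving focal amplification signal
    inside large bins.
    """
    n_bins = int(np.ceil(chrom_length / bin_size))
    out = {}
    for chrom, grp in segments.groupby("chrom"):
        wsum = np.zeros(n_bins)
        vsum = np.zeros(n_bins)
        amp_val = np.full(n_bins, np.nan)
        amp_ov = np.zeros(n_bins)
        for row in grp.itertuples(index=False):
            v = getattr(row, value)
            if not np.isfinite(v):
                continue
            b0 = (row.start - 1) // bin_size
            b1 = (row.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(row.start, b * bin_size + 1)
                hi = min(row.end, (b + 1) * bin_size)
                ov = hi - lo + 1
                wsum[b] += ov
                vsum[b] += ov * v
                if getattr(row, "state", None) == "amplification" and ov > amp_ov[b]:
                    amp_ov[b] = ov
                    amp_val[b] = v
        for b in range(n_bins):
            key = f"chr{chrom}:{b * bin_size + 1}-{min((b + 1) * bin_size, chrom_length)}"
            if amp_ov[b] > 0:
                out[key] = amp_val[b]
            elif wsum[b] > 0:
                out[key] = vsum[b] / wsum[b]
    return pd.Series(out)


def summarize_arms(
    segments: pd.DataFrame, chrom_length: int, value: str = "logr_seg"
) -> pd.Series:
    """Overlap-weighted mean of ``value`` per chromosome arm (p = first
    half, q = second half of the abstract chromosome)."""
    half = chrom_length // 2
    out = {}
    for chrom in sorted(segments["chrom"].unique()):
        for arm, (lo, hi) in (("p", (1, half)), ("q", (half + 1, chrom_length))):
            v = cnprofile.summarize_region(segments, (chrom, lo, hi), "weighted_mean", value)
            if v is not None:
                out[f"{chrom}{arm}"] = v
    return pd.Series(out)


def stage_cn(bundle: synthdata.SimBundle, cfg: RunConfig) -> dict:
    """Allele-specific copy-number calling for every sample."""
    clin = bundle.clinical.set_index("sample")
    chrom_length = int(
        bundle.segments_truth["end"].max()
        if bundle.segments_truth is not None
        else bundle.snps["pos"].max()
    )
    seg_frames, arm_rows, bin_rows = [], {}, {}
    for sample, sites in bundle.snps.groupby("sample"):
        prof = cnprofile.call_profile(
            sites,
            purity=float(clin.loc[sample, "purity"]),
            ploidy=float(clin.loc[sample, "ploidy"]),
            penalty=cfg.cn_penalty,
        )
        prof.insert(0, "sample", sample)
        seg_frames.append(prof)
        arm_rows[sample] = summarize_arms(prof, chrom_length, "logr_seg")
        bin_rows[sample] = summarize_bins(prof, chrom_length, cfg.bin_size, "cn_ratio")
    segments = pd.concat(seg_frames, ignore_index=True)
    return {
        "segments": segments,
        "arm_logr": pd.DataFrame(arm_rows).T,
        "bin_ratio": pd.DataFrame(bin_rows).T,
        "chrom_length": chrom_length,
    }


def stage_tmm(bundle: synthdata.SimBundle, cfg: RunConfig, seed: int) -> dict:
    """Telomere-length ratios, TERT threshold and TMM labels."""
    clin = bundle.clinical.set_index("sample")
    expr = geneffects.normalize_expression(bundle.expression, clin["cohort"])
    tert = expr.loc["TERT"]
    tert_z = (tert - tert.mean()) / tert.std()
    fit = tmm_mod.fit_tert_threshold(tert_z, posterior_cut=cfg.posterior_cut, seed=seed)
    rows = []
    for sample in clin.index:
        reads = bundle.fastq[sample]
        _, _, lt = tmm_mod.count_telomeric_reads(reads["tumor"])
        _, _, ln = tmm_mod.count_telomeric_reads(reads["normal"])
        tlr = tmm_mod.telomere_length_ratio(lt, ln) if lt > 0 and ln > 0 else np.nan
        feats = tmm_mod.TmmFeatures(
            mycn_amp=bool(clin.loc[sample, "mycn_amp"]),
            tert_re=bool(clin.loc[sample, "tert_re"]),
            tert_z=float(tert_z[sample]),
            tlr=float(tlr),
        )
        call = tmm_mod.classify_tmm(feats, fit.threshold, cfg.tlr_cut)
        rows.append(
            {
                "sample": sample,
                "mycn_amp": feats.mycn_amp,
                "tert_re": feats.tert_re,
                "tert_z": feats.tert_z,
                "tlr": feats.tlr,
                "tert_high": call.tert_high,
                "tmm_label": call.label,
            }
        )
    calls = pd.DataFrame(rows)
    return {"tmm_calls": calls, "tert_threshold": fit.threshold, "expression_resid": expr}


def stage_ase(bundle: synthdata.SimBundle, cfg: RunConfig) -> dict:
    """Site filtering, bi-allelic check, haplotype aggregation, AEI calls."""
    gene_rows = []
    n_dropped_total = 0
    for sample, sites in bundle.ase_sites.groupby("sample"):
        kept, n_dropped = ase_mod.filter_sites(sites)
        n_dropped_total += n_dropped
        if len(kept) == 0:
            continue
        kept = ase_mod.biallelic_test(kept, alpha_fdr=cfg.alpha_fdr)
        kept = kept[kept["biallelic"]]
        for gene, gsites in kept.groupby("gene"):
            agg = ase_mod.aggregate_haplotypes(gsites)
            if agg is None:
                continue
            a, b = agg
            gene_rows.append({"sample": sample, "gene": gene, "A": a, "B": b})
    counts = pd.DataFrame(gene_rows)
    table = ase_mod.aei_test(counts, alpha_fdr=cfg.alpha_fdr)
    summary, _ = ase_mod.gene_ase_summary(table)
    return {"gene_ase": table, "ase_summary": summary, "sites_dropped": n_dropped_total}


def stage_effects(
    bundle: synthdata.SimBundle,
    expr_resid: pd.DataFrame,
    gene_ase: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Per-gene variance decomposition of expression and ASE ratio."""
    clin = bundle.clinical.set_index("sample")
    inputs = bundle.gene_inputs.merge(
        clin[["purity", "mycn_amp"]].reset_index(), on="sample"
    )
    inputs["mycn_amp"] = inputs["mycn_amp"].astype(int)
    ase = gene_ase.copy()
    ase["log_coverage"] = np.log(ase["A"] + ase["B"])
    inputs = inputs.merge(
        ase[["sample", "gene", "ase_ratio", "log_coverage"]],
        on=["sample", "gene"], how="left",
    )
    expr_long = expr_resid.stack().rename("expression").reset_index()
    expr_long.columns = ["gene", "sample", "expression"]
    inputs = inputs.merge(expr_long, on=["sample", "gene"], how="left")
    expr_decomp, ase_decomp = [], []
    for gene, grp in inputs.groupby("gene"):
        d = geneffects.decompose_expression(grp, gene=gene)
        if d is not None:
            expr_decomp.append(d)
        d = geneffects.decompose_ase(grp, gene=gene)
        if d is not None:
            ase_decomp.append(d)
    return {
        "expr_effects": geneffects.adjust_effect_pvalues(expr_decomp),
        "ase_effects": geneffects.adjust_effect_pvalues(ase_decomp),
    }


def stage_assoc(
    bundle: synthdata.SimBundle,
    cn_out: dict,
    tmm_calls: pd.DataFrame,
    cfg: RunConfig,
    seed: int,
) -> dict:
    """ATRX deletions, WGD bootstrap + enrichment, arm and bin scans."""
    clin = bundle.clinical.set_index("sample")
    # ATRX exon deletions
    atrx_rows = []
    for sample, grp in bundle.atrx_bins.groupby("sample"):
        fit = events.detect_atrx_deletion(grp["signal"], seed=seed)
        atrx_rows.append({"sample": sample, "atrx_deleted": fit.deleted})
    atrx = pd.DataFrame(atrx_rows).set_index("sample")

    # WGD bootstrap per sample
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    wgd_rows = []
    for sample, prof in cn_out["segments"].groupby("sample"):
        call, frac = events.wgd_bootstrap(
            prof, seed=int(rng.integers(2**31)),
            n_chromosomes=prof["chrom"].nunique(),
        )
        wgd_rows.append({"sample": sample, "wgd": call, "wgd_boot_frac": frac})
    wgd = pd.DataFrame(wgd_rows).set_index("sample")

    calls = tmm_calls.set_index("sample")
    enrich = events.fisher_wgd_enrichment(
        calls["tmm_label"], wgd.loc[calls.index, "wgd"]
    )

    # arm-level ALT association (Mix excluded)
    keep = calls.index[calls["tmm_label"] != "Mix"]
    covars = pd.DataFrame(
        {
            "mycn_amp": clin.loc[keep, "mycn_amp"].astype(int),
            "atrx": atrx.loc[keep, "atrx_deleted"].astype(int),
            "age": clin.loc[keep, "age"],
            "sex": (clin.loc[keep, "sex"] == "M").astype(int),
            "cohort": (clin.loc[keep, "cohort"] == "B").astype(int),
            "purity": clin.loc[keep, "purity"],
            "ploidy": clin.loc[keep, "ploidy"],
        }
    )
    arm_scan = events.arm_alt_association(
        cn_out["arm_logr"].loc[keep],
        (calls.loc[keep, "tmm_label"] == "ALT").to_numpy(),
        covars,
        cfg.alpha_fwer,
    )

    # 5 Mb bin survival association
    surv_covars = pd.DataFrame(
        {
            "mycn_amp": clin["mycn_amp"].astype(int),
            "age": clin["age"],
            "stage4": clin["stage4"].astype(int),
            "sex": (clin["sex"] == "M").astype(int),
            "purity": clin["purity"],
            "ploidy": clin["ploidy"],
        }
    )
    bins = cn_out["bin_ratio"].loc[clin.index]
    coords = {}
    for b in bins.columns:
        chrom, rng_part = b[3:].split(":")
        lo, hi = rng_part.split("-")
        coords[b] = (chrom, int(lo), int(hi))
    bin_scan, merged = events.bin_survival_association(
        bins, clin["deceased"].astype(bool).to_numpy(), surv_covars,
        cfg.alpha_fwer, bin_coords=coords,
    )
    return {
        "atrx": atrx.reset_index(),
        "wgd": wgd.reset_index(),
        "wgd_enrichment": enrich,
        "arm_scan": arm_scan,
        "bin_scan": bin_scan,
        "merged_bins": merged,
    }


def run_pipeline(config: RunConfig, bundle=None, truth=None) -> dict:
    """Execute the requested stages; write tables and a JSON report.

    With no pre-supplied bundle the cohort is simulated from
    ``config.sim`` (seeded from ``config.seed`` unless set explicitly).
    Outputs land in ``config.outdir`` only after all stages succeed.
    """
    for s in config.stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    if bundle is None:
        sim = config.sim or synthdata.SimConfig(seed=config.seed)
        truth, bundle = synthdata.simulate_cohort(sim)

    results: dict = {"truth": truth, "bundle": bundle}
    report: dict = {"n_samples": int(len(bundle.clinical)), "stages": list(config.stages)}

    if "cn" in config.stages:
        results["cn"] = stage_cn(bundle, config)
        report["n_segments"] = int(len(results["cn"]["segments"]))
    if "tmm" in config.stages:
        results["tmm"] = stage_tmm(bundle, config, config.seed)
        tally = results["tmm"]["tmm_calls"]["tmm_label"].value_counts().to_dict()
        report["tmm_tally"] = {k: int(v) for k, v in tally.items()}
        report["tert_threshold"] = float(results["tmm"]["tert_threshold"])
    if "ase" in config.stages:
        results["ase"] = stage_ase(bundle, config)
        report["n_aei"] = int(results["ase"]["gene_ase"]["aei"].sum())
        report["ase_sites_dropped"] = int(results["ase"]["sites_dropped"])
    if "effects" in config.stages:
        if "tmm" not in results or "ase" not in results:
            raise ConfigError("effects stage requires tmm and ase stages")
        results["effects"] = stage_effects(
            bundle, results["tmm"]["expression_resid"], results["ase"]["gene_ase"], config
        )
        sig = results["effects"]["expr_effects"]
        report["n_significant_expr_effects"] = int(sig["significant"].sum())
    if "assoc" in config.stages:
        if "cn" not in results or "tmm" not in results:
            raise ConfigError("assoc stage requires cn and tmm stages")
        results["assoc"] = stage_assoc(
            bundle, results["cn"], results["tmm"]["tmm_calls"], config, config.seed
        )
        report["n_wgd"] = int(results["assoc"]["wgd"]["wgd"].sum())
        report["significant_arms"] = results["assoc"]["arm_scan"].loc[
            lambda d: d["significant"], "region"
        ].tolist()
        report["merged_survival_bins"] = results["assoc"]["merged_bins"]

    results["report"] = report
    if config.outdir:
        _write_outputs(config, results)
    return results


def _write_outputs(config: RunConfig, results: dict) -> None:
    """Write all stage outputs atomically: staged to a temp dir, then moved."""
    final = Path(config.outdir)
    tmp = Path(tempfile.mkdtemp(prefix="nbdosage_"))
    try:
        if "cn" in results:
            io.write_table(results["cn"]["segments"], tmp / "segments.tsv")
            io.write_table(results["cn"]["arm_logr"], tmp / "arm_logr.tsv", index=True)
            io.write_table(results["cn"]["bin_ratio"], tmp / "bin_ratio.tsv", index=True)
        if "tmm" in results:
            io.write_table(results["tmm"]["tmm_calls"], tmp / "tmm_calls.tsv")
        if "ase" in results:
            io.write_table(results["ase"]["gene_ase"], tmp / "gene_ase.tsv")
            io.write_table(results["ase"]["ase_summary"], tmp / "ase_summary.tsv")
        if "effects" in results:
            io.write_table(results["effects"]["expr_effects"], tmp / "expr_effects.tsv")
            io.write_table(results["effects"]["ase_effects"], tmp / "ase_effects.tsv")
        if "assoc" in results:
            for key in ("atrx", "wgd", "wgd_enrichment", "arm_scan", "bin_scan"):
                io.write_table(results["assoc"][key], tmp / f"{key}.tsv")
        with open(tmp / "report.json", "w") as fh:
            json.dump(results["report"], fh, indent=2, sort_keys=True)
        final.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            shutil.move(str(f), final / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
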