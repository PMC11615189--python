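"""Copy-number model: forward BAF/LogR, segmentation, inversion, states."""

import numpy as np
import pandas as pd
import pytest

from nbdosage import cnprofile
from nbdosage.cnprofile import (
    CnStateCall,
    classify_cn_state,
    compute_baf_logr,
    estimate_allele_cn,
    forward_baf_logr,
    segment_baf,
    summarize_region,
)


class TestForwardModel:
    @pytest.mark.parametrize(
        "n_a,n_b,rho,psi,exp_baf,exp_logr",
        [
            (1, 1, 1.0, 2.0, 0.5, 0.0),
            (2, 0, 0.5, 2.0, 0.25, 0.0),
            (2, 1, 1.0, 2.0, 1 / 3, np.log2(1.5)),
        ],
    )
    def test_known_values(self, n_a, n_b, rho, psi, exp_baf, exp_logr):
        baf, logr = forward_baf_logr(n_a, n_b, rho, psi)
        assert baf == pytest.approx(exp_baf, abs=1e-12)
        assert logr == pytest.approx(exp_logr, abs=1e-12)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            forward_baf_logr(1, 1, 0.0, 2.0)

    def test_invalid_allele_order_rejected(self):
        with pytest.raises(ValueError):
            forward_baf_logr(1, 2, 0.5, 2.0)


class TestComputeBafLogr:
    def _table(self, refT, altT, refN=15, altN=15):
        return pd.DataFrame(
            {"chrom": [1], "pos": [100], "refN": [refN], "altN": [altN],
             "refT": [refT], "altT": [altT]}
        )

    def test_balanced_site(self):
        out, dropped = compute_baf_logr(
            self._table(15, 15), mean_depth_tumor=30, mean_depth_normal=30
        )
        assert dropped == 0
        assert out["baf"].iloc[0] == pytest.approx(0.5)
        assert out["logr"].iloc[0] == pytest.approx(0.0)

    def test_doubled_tumor_depth_gives_logr_one(self):
        out, _ = compute_baf_logr(
            self._table(30, 30), mean_depth_tumor=30, mean_depth_normal=30
        )
        assert out["logr"].iloc[0] == pytest.approx(1.0)

    def test_baf_is_alt_fraction(self):
        out, _ = compute_baf_logr(
            self._table(21, 9), mean_depth_tumor=30, mean_depth_normal=30
        )
        assert out["baf"].iloc[0] == pytest.approx(0.3)

    def test_low_depth_sites_dropped_and_counted(self):
        df = pd.DataFrame(
            {"chrom": [1, 1], "pos": [1, 2], "refN": [15, 2], "altN": [15, 2],
             "refT": [15, 15], "altT": [15, 15]}
        )
        out, dropped = compute_baf_logr(df)
        assert dropped == 1 and len(out) == 1


class TestSegmentation:
    def test_constant_baf_no_breakpoints(self, rng):
        baf = 0.5 + rng.normal(0, 0.02, size=1000)
        assert segment_baf(baf) == []

    def test_single_planted_step_localized(self, rng):
        baf = np.concatenate(
            [0.5 + rng.normal(0, 0.02, 500), 0.25 + rng.normal(0, 0.02, 500)]
        )
        bps = segment_baf(baf)
        assert len(bps) == 1
        assert abs(bps[0] - 500) <= 2

    def test_two_planted_steps_recovered_without_spurious(self, rng):
        baf = np.concatenate(
            [0.5 + rng.normal(0, 0.02, 300),
             0.33 + rng.normal(0, 0.02, 300),
             0.5 + rng.normal(0, 0.02, 300)]
        )
        bps = segment_baf(baf)
        assert len(bps) == 2
        assert abs(bps[0] - 300) <= 2 and abs(bps[1] - 600) <= 2

    def test_recall_precision_at_default_noise(self, rng):
        """Breakpoint recall >= 0.95, precision >= 0.9 on planted profiles."""
        tp = fp = fn = 0
        levels = [0.5, 0.333, 0.25, 0.4]
        for _ in range(60):
            n_seg = rng.integers(2, 4)
            cuts = np.sort(rng.choice(np.arange(40, 260), size=n_seg - 1, replace=False))
            bounds = [0, *cuts.tolist(), 300]
            lv = rng.permutation(levels)[:n_seg]
            baf = np.concatenate(
                [lv[i] + rng.normal(0, 0.02, bounds[i + 1] - bounds[i])
                 for i in range(n_seg)]
            )
            found = segment_baf(baf)
            truth = list(cuts)
            matched = set()
            for t in truth:
                hit = [b for b in found if abs(b - t) <= 3 and b not in matched]
                if hit:
                    matched.add(hit[0])
                    tp += 1
                else:
                    fn += 1
            fp += len([b for b in found if b not in matched])
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.9


class TestAlleleCnInversion:
    @pytest.mark.parametrize(
        "baf,logr,rho,psi,expected",
        [
            (0.5, 0.0, 1.0, 2.0, (1, 1)),
            (1 / 3, np.log2(1.5), 1.0, 2.0, (2, 1)),
            (0.25, 0.0, 0.5, 2.0, (2, 0)),
        ],
    )
    def test_known_inversions(self, baf, logr, rho, psi, expected):
        assert estimate_allele_cn(baf, logr, rho, psi) == expected

    def test_exact_round_trip_over_grid(self):
        """Inversion recovers every (n_A, n_B) pair exactly at zero noise."""
        for rho in (0.4, 0.6, 0.8, 1.0):
            for psi in (2.0, 4.0):
                for n_a in range(0, 9):
                    for n_b in range(0, n_a + 1):
                        baf, logr = forward_baf_logr(n_a, n_b, rho, psi)
                        if not np.isfinite(logr):
                            continue
                        assert estimate_allele_cn(baf, logr, rho, psi) == (n_a, n_b)

    def test_mirrored_baf_equivalent(self):
        a = estimate_allele_cn(1 / 3, np.log2(1.5), 1.0, 2.0)
        b = estimate_allele_cn(2 / 3, np.log2(1.5), 1.0, 2.0)
        assert a == b == (2, 1)


def brute_force_state(cn_major, cn_minor, ploidy):
    """Independent re-application of the printed classification rules."""
    total = cn_major + cn_minor
    p = round(ploidy)
    state = "neutral"
    if total > p:
        state = "weak gain"
    if total > 1.5 * p:
        state = "medium gain"
    if total > 2.5 * p:
        state = "strong gain"
    if total < p:
        state = "shallow loss"
    if total < 0.5 * p:
        state = "loss"
    if cn_minor > 0 and cn_major == cn_minor:
        balance = "balance"
    elif cn_major > cn_minor:
        balance = "weak imbalance" if cn_major / total <= 2 / 3 else "strong imbalance"
    else:
        balance = None
    return state, balance, cn_minor == 0


class TestStateClassification:
    def test_exhaustive_rule_agreement(self):
        """Classifier matches brute-force rules for all CN_total <= 10."""
        for psi in (2, 3, 4):
            for total in range(0, 11):
                for n_b in range(0, total // 2 + 1):
                    n_a = total - n_b
                    call = classify_cn_state(n_a, n_b, psi)
                    assert (call.state, call.balance, call.loh) == brute_force_state(
                        n_a, n_b, psi
                    ), (n_a, n_b, psi)

    @pytest.mark.parametrize(
        "cn,psi,state,balance,loh",
        [
            ((3, 2), 2, "medium gain", "weak imbalance", False),
            ((1, 1), 2, "neutral", "balance", False),
            ((2, 0), 2, "neutral", "strong imbalance", True),
        ],
    )
    def test_printed_examples(self, cn, psi, state, balance, loh):
        call = classify_cn_state(*cn, psi)
        assert (call.state, call.balance, call.loh) == (state, balance, loh)

    def test_focal_amplification_override(self):
        call = classify_cn_state(
            6, 1, 2, logr_seg=1.0, logr_contig=0.0, length=5_000_000
        )
        assert call.state == "amplification" and call.balance == "amplification"

    def test_long_segment_not_amplification(self):
        call = classify_cn_state(
            6, 1, 2, logr_seg=1.0, logr_contig=0.0, length=20_000_000
        )
        assert call.state != "amplification"


class TestGeneAmplification:
    @pytest.mark.parametrize(
        "state,logr,expected",
        [("amplification", 1.0, True), ("neutral", 2.6, True), ("weak gain", 0.4, False)],
    )
    def test_rule(self, state, logr, expected):
        assert cnprofile.gene_amplification(state, logr) is expected

    def test_undefined_logr_rejected(self):
        with pytest.raises(ValueError):
            cnprofile.gene_amplification("neutral", np.nan)


class TestSummarizeRegion:
    def _segments(self):
        return pd.DataFrame(
            {
                "chrom": [1, 1],
                "start": [1, 3_000_001],
                "end": [3_000_000, 5_000_000],
                "cn_ratio": [1.0, 0.5],
                "logr_seg": [0.5, 0.0],
                "state": ["neutral", "neutral"],
            }
        )

    def test_weighted_mean(self):
        v = summarize_region(self._segments(), (1, 1, 5_000_000), value="cn_ratio")
        assert v == pytest.approx(0.8)

    def test_amplification_override(self):
        seg = pd.DataFrame(
            {
                "chrom": [1, 1],
                "start": [1, 1_000_001],
                "end": [1_000_000, 5_000_000],
                "logr_seg": [3.0, 0.0],
                "state": ["amplification", "neutral"],
            }
        )
        v = summarize_region(
            seg, (1, 1, 5_000_000), value="logr_seg", amp_override=True
        )
        assert v == pytest.approx(3.0)

    def test_single_segment_identity(self):
        seg = self._segments().iloc[:1]
        v = summarize_region(seg, (1, 1, 3_000_000), value="cn_ratio")
        assert v == pytest.approx(1.0)

    def test_no_overlap_returns_none(self):
        assert summarize_region(self._segments(), (2, 1, 100), value="cn_ratio") is None

    def test_split_invariance(self, rng):
        """Splitting a segment into contiguous halves leaves summaries unchanged."""
        for _ in range(20):
            start, end = 1, int(rng.integers(2_000_000, 9_000_000))
            val = float(rng.uniform(0, 1))
            whole = pd.DataFrame(
                {"chrom": [1], "start": [start], "end": [end],
                 "cn_ratio": [val], "state": ["neutral"]}
            )
            mid = int(rng.integers(start + 1, end))
            halves = pd.DataFrame(
                {"chrom": [1, 1], "start": [start, mid + 1], "end": [mid, end],
                 "cn_ratio": [val, val], "state": ["neutral", "neutral"]}
            )
            region = (1, 1, 10_000_000)
            assert summarize_region(whole, region, value="cn_ratio") == pytest.approx(
                summarize_region(halves, region, value="cn_ratio")
            )

    def test_dominant_state(self):
        seg = self._segments()
        seg.loc[0, "state"] = "weak gain"
        assert summarize_region(seg, (1, 1, 5_000_000), mode="dominant_state") == "weak gain"
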