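"""Expression normalization and per-gene variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from nbdosage import geneffects, synthdata


class TestNormalizeExpression:
    def _counts(self, rng, n_genes=30, n_samples=20):
        return pd.DataFrame(
            rng.poisson(100, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_cohort_residual_means_zero(self, rng):
        counts = self._counts(rng)
        cohort = ["A"] * 10 + ["B"] * 10
        counts.iloc[:, 10:] += 50  # batch shift
        resid = geneffects.normalize_expression(counts, cohort)
        assert np.allclose(resid.iloc[:, :10].mean(axis=1), 0, atol=1e-10)
        assert np.allclose(resid.iloc[:, 10:].mean(axis=1), 0, atol=1e-10)

    def test_library_size_invariance(self, rng):
        counts = self._counts(rng)
        cohort = ["A"] * 10 + ["B"] * 10
        r1 = geneffects.normalize_expression(counts, cohort)
        r2 = geneffects.normalize_expression(counts * 2, cohort)
        assert np.allclose(r1, r2, atol=1e-9)

    def test_batch_shift_removed(self, rng):
        """Post-hoc cohort F-test nonsignificant on batch-shifted null genes."""
        from scipy import stats

        counts = self._counts(rng, n_genes=100)
        counts.iloc[:, 10:] = rng.poisson(300, size=(100, 10))
        cohort = ["A"] * 10 + ["B"] * 10
        resid = geneffects.normalize_expression(counts, cohort)
        pvals = [
            stats.f_oneway(row[:10], row[10:]).pvalue for row in resid.to_numpy()
        ]
        assert np.mean(np.asarray(pvals) < 0.05) < 0.1

    def test_zero_genes_dropped(self, rng):
        counts = self._counts(rng)
        counts.iloc[0] = 0
        with pytest.warns(UserWarning):
            resid = geneffects.normalize_expression(counts, ["A"] * 10 + ["B"] * 10)
        assert "g0" not in resid.index


def random_gene_data(rng, n=60):
    df = synthdata.simulate_effect_gene(n, 0.3, rng)
    df["expression"] = rng.normal(size=n) + 0.5 * df["cn_logr"]
    df["ase_ratio"] = rng.uniform(0.5, 1.0, size=n)
    return df


class TestDecomposition:
    def test_noise_free_cn_effect(self, rng):
        df = synthdata.simulate_effect_gene(100, 0.0, rng)
        df["expression"] = 2.0 * df["cn_logr"]
        d = geneffects.decompose_expression(df)
        assert d.fractions["cn_logr"] > 0.95
        assert d.residual_fraction < 0.01

    def test_fractions_sum_to_one(self, rng):
        for _ in range(20):
            df = random_gene_data(rng)
            d = geneffects.decompose_expression(df)
            total = sum(d.fractions.values()) + d.residual_fraction
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_affine_response_invariance(self, rng):
        df = random_gene_data(rng)
        d1 = geneffects.decompose_expression(df)
        df2 = df.assign(expression=3.0 * df["expression"] + 7.0)
        d2 = geneffects.decompose_expression(df2)
        for k in d1.fractions:
            assert d1.fractions[k] == pytest.approx(d2.fractions[k], abs=1e-9)
            assert d1.pvalues[k] == pytest.approx(d2.pvalues[k], abs=1e-9)

    def test_agrees_with_statsmodels_anova(self, rng):
        """Sequential SS and F p-values match statsmodels anova_lm (Type I)."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = random_gene_data(rng)
        d = geneffects.decompose_expression(df)
        formula = "expression ~ " + " + ".join(
            geneffects.EXPRESSION_EFFECTS + geneffects.EXPRESSION_COVARIATES
        )
        tab = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=1)
        ss_total = tab["sum_sq"].sum()
        for eff in geneffects.EXPRESSION_EFFECTS:
            assert d.fractions[eff] == pytest.approx(
                tab.loc[eff, "sum_sq"] / ss_total, abs=1e-9
            )
            assert d.pvalues[eff] == pytest.approx(tab.loc[eff, "PR(>F)"], abs=1e-9)

    def test_min_observations_enforced(self, rng):
        df = random_gene_data(rng, n=15)
        assert geneffects.decompose_expression(df) is None

    def test_ase_identity_response(self, rng):
        df = synthdata.simulate_effect_gene(80, 0.0, rng, response="ase_ratio")
        df["ase_ratio"] = df["cn_ratio"]
        d = geneffects.decompose_ase(df)
        assert d.fractions["cn_ratio"] > 0.95

    def test_planted_fraction_recovery(self, rng):
        """Mean estimated CN fraction within 3 points of the planted 30%."""
        fracs = []
        for _ in range(300):
            df = synthdata.simulate_effect_gene(115, 0.30, rng)
            d = geneffects.decompose_expression(df)
            fracs.append(d.fractions["cn_logr"])
        assert np.mean(fracs) == pytest.approx(0.30, abs=0.03)

    def test_null_gene_rarely_significant(self, rng):
        """Pure-noise genes: no Bonferroni-significant effects in >=95% of runs."""
        decomps = []
        for i in range(200):
            df = synthdata.simulate_effect_gene(60, 0.0, rng)
            df["expression"] = rng.normal(size=60)
            decomps.append(geneffects.decompose_expression(df, gene=f"g{i}"))
        table = geneffects.adjust_effect_pvalues(decomps)
        frac_genes_hit = (
            table[table["significant"]]["gene"].nunique() / 200
        )
        assert frac_genes_hit <= 0.05


class TestAdGeneTest:
    def _cohort(self, rng, slope, n=40):
        x = rng.normal(size=n)
        return pd.DataFrame(
            {
                "gene": "g",
                "expression": x,
                "ase_ratio": np.clip(0.75 + slope * 0.1 * x + rng.normal(0, 0.02, n), 0.5, 1),
                "purity": rng.uniform(0.6, 1, n),
                "log_coverage": rng.normal(4, 0.5, n),
                "normal_dna_ratio": rng.uniform(0.5, 0.6, n),
                "cohort": rng.choice(["A", "B"], n),
            }
        )

    def test_imprinting_loss_pattern_negative(self, rng):
        out = geneffects.ad_gene_test(self._cohort(rng, slope=-1))
        assert out["coefficient"].iloc[0] < 0
        assert out["q"].iloc[0] < 0.05

    def test_amplification_pattern_positive(self, rng):
        out = geneffects.ad_gene_test(self._cohort(rng, slope=+1))
        assert out["coefficient"].iloc[0] > 0
        assert out["q"].iloc[0] < 0.05

    def test_null_false_positive_control(self, rng):
        frames = []
        for g in range(300):
            df = self._cohort(rng, slope=0)
            df["ase_ratio"] = np.clip(0.75 + rng.normal(0, 0.05, len(df)), 0.5, 1)
            df["gene"] = f"g{g}"
            frames.append(df)
        out = geneffects.ad_gene_test(pd.concat(frames))
        assert out["ad_gene"].mean() <= 0.05

    def test_min_informative_samples(self, rng):
        out = geneffects.ad_gene_test(self._cohort(rng, slope=1, n=5))
        assert len(out) == 0


class TestAltDeScan:
    def _data(self, rng, n=80, n_genes=50, planted=5, effect=2.0):
        alt = rng.random(n) < 0.25
        cov = pd.DataFrame(
            {
                "mycn": rng.binomial(1, 0.2, n),
                "age": rng.lognormal(0, 0.8, n),
                "sex": rng.binomial(1, 0.5, n),
                "purity": rng.uniform(0.6, 1, n),
            }
        )
        expr = pd.DataFrame(
            rng.normal(size=(n_genes, n)), index=[f"g{i}" for i in range(n_genes)]
        )
        expr.iloc[:planted] += effect * alt
        return expr, alt, cov

    def test_planted_upregulation_recovered(self, rng):
        expr, alt, cov = self._data(rng)
        out = geneffects.alt_de_scan(expr, alt, cov).set_index("gene")
        for g in ["g0", "g1", "g2", "g3", "g4"]:
            assert out.loc[g, "significant"]
            assert out.loc[g, "coefficient"] > 0

    def test_null_fdr_controlled(self, rng):
        """Average false-discovery proportion stays near the nominal level."""
        fdps = []
        for _ in range(8):
            expr, alt, cov = self._data(rng, n_genes=400, planted=40, effect=2.5)
            out = geneffects.alt_de_scan(expr, alt, cov)
            hits = out[out["significant"]]
            if len(hits):
                fdps.append((hits["gene"].str.slice(1).astype(int) >= 40).mean())
        assert np.mean(fdps) <= 0.07

    def test_confounded_gene_not_significant(self, rng):
        n = 100
        mycn = rng.binomial(1, 0.3, n).astype(bool)
        alt = np.where(mycn, False, rng.random(n) < 0.35)  # ALT avoids MYCN
        expr = pd.DataFrame(
            [3.0 * mycn + rng.normal(0, 1, n)], index=["g_mycn"]
        )
        cov = pd.DataFrame({"mycn": mycn.astype(int), "purity": rng.uniform(0.6, 1, n)})
        out = geneffects.alt_de_scan(expr, alt, cov)
        assert not out["significant"].iloc[0]

    def test_single_class_rejected(self, rng):
        expr, alt, cov = self._data(rng)
        with pytest.raises(ValueError):
            geneffects.alt_de_scan(expr, np.zeros(len(alt), bool), cov)
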