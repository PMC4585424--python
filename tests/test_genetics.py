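import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenopipe.genetics import (
    allele_group_bootstrap,
    heritability,
    line_anova_pvalue,
    permutation_threshold,
    single_marker_scan,
    variance_components,
)
from phenopipe.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="module")
def geno150():
    cfg = SimulationConfig(seed=0, n_lines=150)
    g, _ = simulate_genotypes(cfg, np.random.default_rng(0))
    return g


def line_table(rng, n_lines=150, reps=2, s_g=1.0, s_e=1.0):
    lines = [f"L{i:03d}" for i in range(n_lines)]
    g = rng.normal(0, s_g, n_lines)
    rows = [(ln, g[i] + rng.normal(0, s_e))
            for i, ln in enumerate(lines) for _ in range(reps)]
    return pd.DataFrame(rows, columns=["line_id", "value"])


class TestVarianceComponents:
    def test_recovers_planted_variances(self):
        """sigma2_G = sigma2_e = 1, 150 lines x 2 reps: median estimates
        within 25% across seeds."""
        ests = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            s2g, s2e = variance_components(line_table(rng))
            ests.append((s2g, s2e))
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(1.0, rel=0.25)
        assert med[1] == pytest.approx(1.0, rel=0.25)

    def test_pure_noise_floored_near_zero(self):
        small = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s2g, _ = variance_components(line_table(rng, s_g=0.0))
            small.append(s2g)
        assert np.median(small) < 0.1

    def test_single_replicate_everywhere_rejected(self):
        df = pd.DataFrame({"line_id": ["a", "b", "c"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            variance_components(df)


class TestHeritability:
    def test_zero_genetic_variance(self):
        assert heritability(0.0, 1.0, 2) == 0.0

    def test_hand_computed_line_mean_basis(self):
        # 100 * 1 / (1 + 1/2)
        assert heritability(1.0, 1.0, 2) == pytest.approx(66.667, rel=1e-4)

    def test_no_residual_noise_gives_full_heritability(self):
        assert heritability(2.5, 0.0, 2) == pytest.approx(100.0)

    def test_both_zero_undefined(self):
        assert np.isnan(heritability(0.0, 0.0, 2))

    def test_span_matches_platform_range(self, result_noisy):
        """On the simulated platform, trait heritabilities fall in the
        low-to-moderate band reported for image-derived traits."""
        h2 = result_noisy.summary["h2"].dropna()
        assert (h2 >= 0).all() and (h2 <= 100).all()
        assert h2.min() < 54 and h2.max() > 10


class TestSingleMarkerScan:
    def test_parent_label_flip_negates_effects(self, geno150):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
        s1 = single_marker_scan(y, geno150, threshold=np.inf)
        s2 = single_marker_scan(y, -geno150, threshold=np.inf)
        np.testing.assert_allclose(s1.table["effect"], -s2.table["effect"],
                                   rtol=1e-10)
        np.testing.assert_allclose(s1.table["F"], s2.table["F"], rtol=1e-10)

    def test_statistic_invariant_to_affine_trait_transform(self, geno150):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
        s1 = single_marker_scan(y, geno150, threshold=np.inf)
        s2 = single_marker_scan(3.0 * y + 11.0, geno150, threshold=np.inf)
        np.testing.assert_allclose(s1.table["F"], s2.table["F"], rtol=1e-8)

    def test_monomorphic_marker_skipped(self, geno150):
        g = geno150.copy()
        g["mono"] = 1.0
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=len(g)), index=g.index)
        res = single_marker_scan(y, g, threshold=np.inf)
        row = res.table.set_index("marker").loc["mono"]
        assert row["skipped_monomorphic"]
        assert np.isnan(row["F"])

    def test_marginal_null_pvalues_uniform(self, geno150):
        """Under the null, a fixed marker's p-value is uniform across
        trait realizations (KS at 1%)."""
        ps = []
        for seed in range(150):
            rng = np.random.default_rng(1000 + seed)
            y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
            res = single_marker_scan(y, geno150, threshold=np.inf)
            ps.append(res.table["p"].iloc[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_covariates_absorb_their_effect(self, geno150):
        """A trait driven by one 'phenology' marker: with that marker as
        covariate its linked region drops out of the scan."""
        rng = np.random.default_rng(8)
        causal = geno150["chr5_m08"].fillna(0.0)
        y = pd.Series(2.0 * causal.to_numpy() + rng.normal(size=len(geno150)),
                      index=geno150.index)
        plain = single_marker_scan(y, geno150, threshold=np.inf)
        adj = single_marker_scan(
            y, geno150.drop(columns=["chr5_m08"]),
            covariates=geno150[["chr5_m08"]].fillna(0.0), threshold=np.inf)
        f_plain = plain.table.set_index("marker")["F"]
        f_adj = adj.table.set_index("marker")["F"]
        assert f_plain["chr5_m07"] > 30           # linked marker lights up
        assert f_adj["chr5_m07"] < f_plain["chr5_m07"] / 5


class TestPermutationThreshold:
    def test_threshold_decreases_with_alpha(self, geno150):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
        t05 = permutation_threshold(y, geno150, n_perm=200, alpha=0.05, seed=1)
        t20 = permutation_threshold(y, geno150, n_perm=200, alpha=0.20, seed=1)
        assert t20 < t05

    def test_bitwise_reproducible_given_seed(self, geno150):
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
        a = permutation_threshold(y, geno150, n_perm=150, seed=42)
        b = permutation_threshold(y, geno150, n_perm=150, seed=42)
        assert a == b

    def test_minimum_permutations_enforced(self, geno150):
        y = pd.Series(np.zeros(len(geno150)), index=geno150.index)
        with pytest.raises(ValueError):
            permutation_threshold(y, geno150, n_perm=50)

    def test_threshold_distribution_stable_across_seeds(self, geno150):
        """Permuting an already-exchangeable trait leaves the threshold
        essentially unchanged between two seeds."""
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=len(geno150)), index=geno150.index)
        t1 = permutation_threshold(y, geno150, n_perm=500, seed=1)
        t2 = permutation_threshold(
            y.sample(frac=1, random_state=0).set_axis(y.index), geno150,
            n_perm=500, seed=2)
        assert t1 == pytest.approx(t2, rel=0.15)


class TestAlleleGroupBootstrap:
    def make_fits(self, rng, n=30, spread=0.0):
        idx = [f"L{i:03d}" for i in range(n)]
        return pd.DataFrame({
            "V_final": 10 + spread * rng.normal(size=n),
            "K": np.full(n, 0.14),
            "t0": np.full(n, 45.0),
        }, index=pd.Index(idx, name="line_id"))

    def make_calls(self, n=30):
        idx = [f"L{i:03d}" for i in range(n)]
        return pd.Series([1] * (n // 2) + [-1] * (n - n // 2), index=idx)

    def test_identical_curves_zero_envelope(self, rng):
        fits = self.make_fits(rng, spread=0.0)
        out = allele_group_bootstrap(fits, self.make_calls(), np.linspace(20, 60, 5),
                                     n_boot=100, seed=0)
        assert np.allclose(out["sd"], 0.0)

    def test_envelope_shrinks_with_class_size(self):
        rng = np.random.default_rng(0)
        grid = np.array([45.0])
        widths = {}
        for n in (20, 80):
            fits = self.make_fits(rng, n=n, spread=2.0)
            calls = pd.Series(np.ones(n, dtype=int), index=fits.index)
            calls.iloc[: n // 2] = 1
            calls.iloc[n // 2:] = -1
            out = allele_group_bootstrap(fits, calls, grid, n_boot=400, seed=1)
            widths[n] = out[out.allele == "A"]["sd"].iloc[0]
        # sd of a mean scales ~1/sqrt(n): quadrupling n roughly halves it
        assert widths[80] < 0.75 * widths[20]

    def test_small_class_rejected(self, rng):
        fits = self.make_fits(rng, n=12)
        calls = self.make_calls(12)  # 6 per class, below the minimum of 10
        with pytest.raises(ValueError, match="class"):
            allele_group_bootstrap(fits, calls, np.array([40.0]), n_boot=10)

    def test_planted_effect_separates_classes(self, geno150):
        """Lines carrying the + allele at a size QTL show a higher mean
        fitted curve."""
        rng = np.random.default_rng(3)
        calls = geno150["chr1_m10"].dropna()
        fits = pd.DataFrame({
            "V_final": 10 + 1.5 * calls + rng.normal(0, 0.5, len(calls)),
            "K": np.full(len(calls), 0.14),
            "t0": np.full(len(calls), 45.0),
        }, index=calls.index)
        out = allele_group_bootstrap(fits, calls, np.array([60.0]),
                                     n_boot=300, seed=4)
        mean_a = out[out.allele == "A"]["mean"].iloc[0]
        mean_b = out[out.allele == "B"]["mean"].iloc[0]
        assert mean_a > mean_b


class TestLineAnova:
    def test_strong_line_effect_detected(self):
        rng = np.random.default_rng(1)
        df = line_table(rng, s_g=3.0, s_e=0.5)
        assert line_anova_pvalue(df) < 1e-6

    def test_requires_two_lines(self):
        df = pd.DataFrame({"line_id": ["a", "a"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            line_anova_pvalue(df)
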