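"""NB differential expression: size factors, dispersion, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tdmdscreen.containers import WT
from tdmdscreen.diffexpr import (
    NBDEModel,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)


def frame(rows, prefix="lib"):
    rows = np.asarray(rows)
    return pd.DataFrame(rows, index=[f"f{i}" for i in range(rows.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(rows.shape[1])])


def groups_for(counts, pattern=("WT", "mutant")):
    n = counts.shape[1]
    half = n // 2
    return pd.Series([pattern[0]] * half + [pattern[1]] * (n - half),
                     index=counts.columns)


def simulate_nb(rng, mu_wt, mu_mut, alpha, n_rep=2):
    """Plain numpy NB simulator (oracle-side, independent of simkit)."""
    def draw(mu):
        if alpha == 0:
            return rng.poisson(mu)
        n = 1 / alpha
        return rng.negative_binomial(n, n / (n + mu))

    cols = [draw(mu_wt) for _ in range(n_rep)] + [draw(mu_mut) for _ in range(n_rep)]
    return frame(np.column_stack(cols))


class TestSizeFactors:
    def test_identical_libraries_unit_factors(self):
        counts = frame([[5, 5], [9, 9]])
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_library_hand_oracle(self):
        # features [[2,4],[10,20]]: ratios to geometric means are
        # (1/sqrt 2, sqrt 2) in both rows, so s = (0.7071, 1.4142) ~ (1, 2)
        s = size_factors(frame([[2, 4], [10, 20]]))
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0)

    def test_feature_permutation_invariance(self):
        counts = frame([[2, 4], [10, 20], [7, 7]])
        s1 = size_factors(counts)
        s2 = size_factors(counts.iloc[[2, 0, 1]])
        assert np.allclose(s1, s2)

    def test_geometric_mean_is_one(self):
        s = size_factors(frame([[3, 9, 27], [10, 10, 10]]))
        assert np.exp(np.log(s).mean()) == pytest.approx(1.0)

    def test_no_common_feature_errors_without_fallback(self):
        counts = frame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        s = size_factors(counts, pseudo_reference=True)
        assert (s > 0).all()


class TestDispersion:
    def test_poisson_counts_give_small_alpha(self):
        rng = np.random.default_rng(0)
        counts = simulate_nb(rng, np.full(500, 500.0), np.full(500, 500.0),
                             alpha=0.0, n_rep=25)
        g = groups_for(counts)
        disp = estimate_dispersion(counts, size_factors(counts), g)
        assert disp.median() < 0.01

    def test_nb_alpha_recovered_with_many_replicates(self):
        rng = np.random.default_rng(1)
        counts = simulate_nb(rng, np.full(300, 500.0), np.full(300, 500.0),
                             alpha=0.1, n_rep=50)
        g = groups_for(counts)
        disp = estimate_dispersion(counts, size_factors(counts), g)
        assert 0.05 <= disp.median() <= 0.2

    def test_single_replicate_rejected(self):
        counts = frame([[5, 6], [7, 8]])
        g = pd.Series(["WT", "mutant"], index=counts.columns)
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(counts, size_factors(counts), g)

    def test_variance_below_mean_hits_floor_side(self):
        # identical replicate counts: var 0 < mean, raw estimate negative
        counts = frame([[50, 50, 50, 50]])
        g = groups_for(counts)
        disp = estimate_dispersion(counts, size_factors(counts), g)
        assert (disp <= 1e-6).all()


class TestWaldTest:
    def test_null_large_counts_calibrated(self):
        """Identical group means: small log2FC and mostly p > 0.05."""
        rng = np.random.default_rng(2)
        mu = np.full(200, 10_000.0)
        counts = simulate_nb(rng, mu, mu, alpha=1e-4, n_rep=4)
        g = groups_for(counts)
        sf = size_factors(counts)
        disp = pd.Series(1e-4, index=counts.index)
        t = nb_wald_test(counts, sf, disp, g)
        assert (t.log2fc.abs() < 0.1).mean() >= 0.95
        assert (t.pvalue > 0.05).mean() >= 0.90

    def test_planted_eightfold_recovered(self):
        # 8-fold change on 40 features over a null background (the nulls
        # anchor the median-of-ratios normalisation)
        rng = np.random.default_rng(3)
        n, n_hit = 240, 40
        mu_wt = np.full(n, 500.0)
        mu_mut = mu_wt.copy()
        mu_mut[:n_hit] *= 8
        counts = simulate_nb(rng, mu_wt, mu_mut, alpha=0.01, n_rep=2)
        g = groups_for(counts)
        t = nb_wald_test(counts, size_factors(counts),
                         pd.Series(0.01, index=counts.index), g).iloc[:n_hit]
        ok = (t.log2fc.between(2.5, 3.5)) & (t.pvalue < 1e-4)
        assert ok.mean() >= 0.90

    def test_all_zero_flagged(self):
        counts = frame([[0, 0, 0, 0], [5, 6, 7, 8]])
        g = groups_for(counts)
        t = nb_wald_test(counts, size_factors(counts),
                         pd.Series(0.05, index=counts.index), g)
        assert t.loc["f0", "status"] == "all-zero"
        assert np.isnan(t.loc["f0", "pvalue"])

    def test_group_zero_flagged_low_count(self):
        counts = frame([[5, 6, 0, 0], [50, 60, 70, 80]])
        g = groups_for(counts)
        t = nb_wald_test(counts, size_factors(counts),
                         pd.Series(0.05, index=counts.index), g)
        assert t.loc["f0", "status"] == "low-count"

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(4)
        counts = simulate_nb(rng, np.full(50, 300.0), np.full(50, 900.0),
                             alpha=0.02, n_rep=2)
        g = groups_for(counts)
        sf = size_factors(counts)
        disp = pd.Series(0.02, index=counts.index)
        t1 = nb_wald_test(counts, sf, disp, g, reference=WT)
        t2 = nb_wald_test(counts, sf, disp, g, reference="mutant")
        assert np.allclose(t1.log2fc, -t2.log2fc)
        assert np.allclose(t1.pvalue, t2.pvalue)

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(5)
        counts = simulate_nb(rng, np.full(100, 2000.0), np.full(100, 6000.0),
                             alpha=0.01, n_rep=2)
        g = groups_for(counts)
        disp = pd.Series(0.01, index=counts.index)
        t1 = nb_wald_test(counts, size_factors(counts), disp, g)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        s1 = size_factors(counts)
        s2 = size_factors(scaled)
        t2 = nb_wald_test(scaled, s2, disp, g)
        # relative factor of the scaled library grows by the scaling constant
        assert (s2.iloc[0] / s2.iloc[1]) / (s1.iloc[0] / s1.iloc[1]) == pytest.approx(
            3.0, rel=0.05
        )
        assert np.allclose(t1.log2fc, t2.log2fc, atol=0.05)

    def test_one_group_empty_rejected(self):
        counts = frame([[1, 2]])
        g = pd.Series(["WT", "WT"], index=counts.columns)
        with pytest.raises(ValueError, match="two groups"):
            nb_wald_test(counts, size_factors(counts),
                         pd.Series(0.05, index=counts.index), g)

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: statsmodels NB GLM on the same design."""
        rng = np.random.default_rng(6)
        counts = simulate_nb(rng, np.full(5, 400.0), np.full(5, 1600.0),
                             alpha=0.05, n_rep=3)
        g = groups_for(counts)
        sf = size_factors(counts)
        alpha = 0.05
        t = nb_wald_test(counts, sf, pd.Series(alpha, index=counts.index), g)
        X = np.column_stack([np.ones(6), (g == "mutant").astype(float)])
        for feat in counts.index:
            y = counts.loc[feat].to_numpy()
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf.to_numpy()),
            ).fit()
            assert t.loc[feat, "log2fc"] == pytest.approx(
                glm.params[1] / np.log(2), abs=1e-4
            )
            assert t.loc[feat, "se"] == pytest.approx(
                glm.bse[1] / np.log(2), rel=0.02
            )


class TestBH:
    def test_hand_oracle(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_empty_vector(self):
        assert bh_adjust(np.array([])).size == 0

    def test_padj_dominates_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestModelSurface:
    def test_fit_returns_results_with_summary(self, screen_data):
        res = NBDEModel(screen_data["counts"], stage="L1").fit()
        text = res.summary()
        assert "Wald" in text and "size factors" in text
        assert {"baseMean", "log2fc", "se", "pvalue", "padj", "status"} <= set(
            res.table.columns
        )

    def test_padj_ge_p_on_tested(self, screen_data):
        res = NBDEModel(screen_data["counts"], stage="L1").fit()
        t = res.table[res.table.status == "tested"]
        assert (t.padj >= t.pvalue - 1e-12).all()
        assert ((t.pvalue > 0) & (t.pvalue <= 1)).all()
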