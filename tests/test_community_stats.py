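"""PERMANOVA, BIOENV and the predator-prey size regression."""

import numpy as np
import pandas as pd
import pytest

import sagitta as sg
from sagitta import community_stats as cs


def balanced_design(n_per_cell=4):
    a = np.repeat(["summer", "fall", "winter"], 2 * n_per_cell)
    b = np.tile(np.repeat(["neritic", "oceanic"], n_per_cell), 3)
    return a, b


class TestEuclideanDistanceMatrix:
    def test_identical_samples_zero(self):
        dm = sg.euclidean_distance_matrix([1.0, 1.0, 1.0])
        assert np.all(dm.data == 0)

    def test_univariate_absolute_differences(self):
        dm = sg.euclidean_distance_matrix([0.0, 3.0, 4.0])
        assert dm.data[0, 1] == 3.0
        assert dm.data[0, 2] == 4.0
        assert dm.data[1, 2] == 1.0

    def test_triangle_inequality_random(self, rng):
        x = rng.normal(size=(15, 3))
        d = sg.euclidean_distance_matrix(x).data
        for i in range(15):
            for j in range(15):
                for k in range(15):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            sg.euclidean_distance_matrix([1.0, np.nan])


class TestPermanovaTwoWay:
    def test_univariate_equals_classical_anova(self, rng):
        """On a balanced crossed design with Euclidean distances the
        sequential pseudo-F of every term equals the classical two-way
        ANOVA F to 1e-10."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        a, b = balanced_design(4)
        y = rng.normal(size=a.size) + 0.8 * (a == "summer") + 0.5 * (b == "neritic")
        tab = sg.permanova_two_way(
            sg.euclidean_distance_matrix(y), a, b, n_perm=99, seed=0,
            factor_names=("season", "zone"),
        )
        fit = smf.ols("y ~ C(a) * C(b)", data=pd.DataFrame({"y": y, "a": a, "b": b})).fit()
        anova = anova_lm(fit, typ=1)
        assert tab.pseudo_f["season"] == pytest.approx(anova["F"]["C(a)"], abs=1e-10)
        assert tab.pseudo_f["zone"] == pytest.approx(anova["F"]["C(b)"], abs=1e-10)
        assert tab.pseudo_f["interaction"] == pytest.approx(anova["F"]["C(a):C(b)"], abs=1e-10)
        assert tab.ss["season"] == pytest.approx(anova["sum_sq"]["C(a)"], rel=1e-10)

    def test_ss_decomposition_sums_to_total(self, rng):
        a, b = balanced_design(3)
        y = rng.normal(size=(a.size, 4))
        tab = sg.permanova_two_way(sg.euclidean_distance_matrix(y), a, b, n_perm=49, seed=1)
        parts = sum(tab.ss[t] for t in (*tab.terms, "residual"))
        assert parts == pytest.approx(tab.ss["total"], rel=1e-8)
        assert tab.df["total"] == a.size - 1
        assert sum(tab.df[t] for t in (*tab.terms, "residual")) == tab.df["total"]

    def test_p_values_respect_add_one_convention(self, rng):
        a, b = balanced_design(3)
        y = rng.normal(size=a.size)
        tab = sg.permanova_two_way(sg.euclidean_distance_matrix(y), a, b, n_perm=99, seed=2)
        for t in tab.terms:
            assert 1 / 100 <= tab.p_perm[t] <= 1.0

    def test_relabeling_invariance(self, rng):
        a, b = balanced_design(3)
        y = rng.normal(size=a.size) + (a == "fall")
        perm = rng.permutation(a.size)
        t1 = sg.permanova_two_way(sg.euclidean_distance_matrix(y), a, b, n_perm=99, seed=3)
        t2 = sg.permanova_two_way(
            sg.euclidean_distance_matrix(y[perm]), a[perm], b[perm], n_perm=99, seed=3
        )
        for t in t1.terms:
            assert t1.pseudo_f[t] == pytest.approx(t2.pseudo_f[t], rel=1e-9)
            assert t1.ss[t] == pytest.approx(t2.ss[t], rel=1e-9)

    def test_seed_determinism_and_unique_permutation_count(self, rng):
        a, b = balanced_design(3)
        y = rng.normal(size=a.size)
        dm = sg.euclidean_distance_matrix(y)
        t1 = sg.permanova_two_way(dm, a, b, n_perm=199, seed=9)
        t2 = sg.permanova_two_way(dm, a, b, n_perm=199, seed=9)
        assert t1.p_perm == t2.p_perm
        assert 0 < t1.n_unique_permutations <= 199

    def test_empty_cell_named_in_error(self):
        a = ["summer"] * 4 + ["winter"] * 4
        b = ["neritic"] * 4 + ["neritic"] * 2 + ["oceanic"] * 2
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="empty cell.*summer.*oceanic"):
            sg.permanova_two_way(sg.euclidean_distance_matrix(y), a, b, n_perm=9)

    def test_single_level_factor_rejected(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="levels"):
            sg.permanova_two_way(
                sg.euclidean_distance_matrix(y), ["s"] * 6, ["n", "o"] * 3, n_perm=9
            )


class TestBioenv:
    def test_generating_variable_attains_perfect_rho(self, rng):
        env = pd.DataFrame(rng.normal(size=(20, 3)), columns=["temp", "sal", "chl"])
        dm = sg.euclidean_distance_matrix(
            ((env["temp"] - env["temp"].mean()) / env["temp"].std(ddof=1)).to_numpy()
        )
        res = sg.bioenv(env, dm)
        assert res.best_vars == ("temp",)
        assert res.rho == pytest.approx(1.0)

    def test_rank_invariance_to_monotone_transform(self, rng):
        env = pd.DataFrame(rng.normal(size=(15, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=15)
        d = sg.euclidean_distance_matrix(y).data
        res1 = sg.bioenv(env, d)
        res2 = sg.bioenv(env, np.sqrt(d))  # monotone transform of distances
        assert res1.best_vars == res2.best_vars
        assert res1.rho == pytest.approx(res2.rho, abs=1e-12)

    def test_exclusion_honored(self, rng):
        env = pd.DataFrame(rng.normal(size=(15, 3)), columns=["a", "b", "cop"])
        res = sg.bioenv(env, sg.euclidean_distance_matrix(rng.normal(size=15)), exclude=["cop"])
        assert all("cop" not in subset for subset in res.trace["subset"])

    def test_constant_variable_dropped_with_warning(self, rng, caplog):
        env = pd.DataFrame({"a": rng.normal(size=12), "flat": np.ones(12)})
        with caplog.at_level("WARNING", logger="sagitta"):
            res = sg.bioenv(env, sg.euclidean_distance_matrix(rng.normal(size=12)))
        assert "flat" in caplog.text
        assert all(s == ("a",) for s in res.trace["subset"])

    def test_agrees_with_reference_implementation(self, rng):
        """Cross-check rho per subset against scikit-bio's BIOENV on the same
        data (independent implementation of the same procedure)."""
        from skbio.stats.distance import bioenv as skbio_bioenv

        env = pd.DataFrame(rng.normal(size=(18, 3)), columns=["t", "s", "c"])
        y = env["t"].to_numpy() + 0.5 * rng.normal(size=18)
        ids = [f"st{i}" for i in range(18)]
        dm = sg.euclidean_distance_matrix(y, ids=ids)
        res = sg.bioenv(env, dm)
        ref = skbio_bioenv(dm, env.set_axis(ids, axis=0))
        # skbio reports the best subset per size; compare the per-size maxima
        ours = res.trace.groupby("size")["rho"].max()
        for k in (1, 2, 3):
            assert ours[k] == pytest.approx(ref["correlation"].iloc[k - 1], abs=1e-9)


class TestSizeRegression:
    def test_exact_linear_relation(self):
        pred = np.linspace(10, 20, 12)
        res = sg.size_regression(pred, 0.1 * pred)
        assert res.slope == pytest.approx(0.1, abs=1e-12)
        assert res.p_value < 1e-10

    def test_intercept_shift_leaves_slope(self, rng):
        pred = rng.uniform(8, 22, size=30)
        prey = 0.05 * pred + rng.normal(0, 0.1, size=30)
        r1 = sg.size_regression(pred, prey)
        r2 = sg.size_regression(pred, prey + 5.0)
        assert r1.slope == pytest.approx(r2.slope, rel=1e-12)
        assert r1.t_statistic == pytest.approx(r2.t_statistic, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sg.size_regression([1, 2], [1, 2])
        with pytest.raises(ValueError):
            sg.size_regression([2, 2, 2], [1, 2, 3])
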