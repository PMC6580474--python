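import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from forkscan import forks, synth
from forkscan.forks import Triplet, enumerate_triplets, fork_fit, ratio_series, screen_forks
from forkscan.matrix_io import CONTROL, TREATMENT
from forkscan.synth import ForkSpec, SyntheticSpec

from conftest import make_matrix


def triplet_matrix(a, b, c, n_control):
    n = len(a)
    conditions = [CONTROL] * n_control + [TREATMENT] * (n - n_control)
    return make_matrix([a, b, c], feature_ids=["A", "B", "C"], conditions=conditions)


def random_triplet_matrix(rng, n_control=12, n_treatment=11, slope_diff=0.0, noise_sd=0.5):
    n = n_control + n_treatment
    cond = np.array([0.0] * n_control + [1.0] * n_treatment)
    b = np.exp(rng.normal(1, 0.3, n))
    c = np.exp(rng.normal(1, 0.3, n))
    slope = 2.0 + slope_diff * cond
    a = 8 * noise_sd + slope * (b / c) + rng.normal(0, noise_sd, n)
    return triplet_matrix(a, b, c, n_control)


class TestEnumerate:
    def test_three_candidates_give_six_ordered_triplets(self):
        ts = enumerate_triplets({"x", "y", "z"}, {"x", "y", "z"}, {"x", "y", "z"})
        assert len(ts) == 6
        assert all(len({t.A_id, t.B_id, t.C_id}) == 3 for t in ts)

    def test_disjoint_two_each_give_eight(self):
        ts = enumerate_triplets({"a1", "a2"}, {"b1", "b2"}, {"c1", "c2"})
        assert len(ts) == 8

    def test_empty_role_errors(self):
        with pytest.raises(ValueError, match="role B"):
            enumerate_triplets({"x"}, set(), {"y"})

    def test_deterministic_sorted_order(self):
        ts1 = enumerate_triplets(["y", "x"], ["x", "y"], ["z"])
        ts2 = enumerate_triplets(["x", "y"], ["y", "x"], ["z"])
        assert ts1 == ts2
        assert ts1 == sorted(ts1, key=lambda t: t.as_tuple())

    def test_repeated_id_rejected_in_triplet(self):
        with pytest.raises(ValueError, match="distinct"):
            Triplet("a", "a", "b")


class TestRatioSeries:
    def test_equal_numerator_denominator(self):
        m = triplet_matrix([1, 1, 1, 1], [3, 4, 5, 6], [3, 4, 5, 6], 2)
        assert np.allclose(ratio_series(m, "B", "C"), 1.0)

    def test_arithmetic(self):
        m = triplet_matrix([1, 1], [2, 6], [1, 3], 1)
        assert ratio_series(m, "B", "C").tolist() == [2.0, 2.0]

    def test_zero_denominator_flags_degenerate(self):
        m = triplet_matrix([1, 2, 1, 3, 1, 2], [2, 3, 2, 4, 2, 3], [1, 0, 1, 2, 1, 2], 3)
        with pytest.raises(ValueError, match="degenerate-denominator"):
            ratio_series(m, "B", "C")
        fit = fork_fit(m, Triplet("A", "B", "C"))
        assert "degenerate-denominator" in fit.flags


class TestForkFit:
    def test_noiseless_unequal_slopes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 23
        cond = np.array([0.0] * 12 + [1.0] * 11)
        b = np.exp(rng.normal(1, 0.3, n))
        c = np.exp(rng.normal(1, 0.3, n))
        a = (2.0 + 3.0 * cond) * (b / c)
        fit = fork_fit(triplet_matrix(a, b, c, 12), Triplet("A", "B", "C"))
        assert fit.slope_control == pytest.approx(2.0, abs=1e-8)
        assert fit.slope_treatment == pytest.approx(5.0, abs=1e-8)
        assert fit.interaction_estimate == pytest.approx(3.0, abs=1e-8)
        assert "saturated" in fit.flags and math.isnan(fit.interaction_p)

    def test_interaction_is_slope_difference(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fit = fork_fit(random_triplet_matrix(rng, slope_diff=1.5), Triplet("A", "B", "C"))
            assert fit.interaction_estimate == pytest.approx(
                fit.slope_treatment - fit.slope_control, abs=1e-10
            )

    def test_matches_independent_ols_oracle(self):
        # independent route: statsmodels OLS on the same design
        rng = np.random.default_rng(2)
        for _ in range(100):
            m = random_triplet_matrix(rng, slope_diff=rng.normal(0, 2))
            fit = fork_fit(m, Triplet("A", "B", "C"))
            ratio = (m.values.loc["B"] / m.values.loc["C"]).to_numpy()
            cond = (m.condition == TREATMENT).astype(float).to_numpy()
            X = sm.add_constant(np.column_stack([ratio, cond, ratio * cond]))
            res = sm.OLS(m.values.loc["A"].to_numpy(), X).fit()
            assert fit.interaction_estimate == pytest.approx(res.params[3], abs=1e-8)
            assert fit.interaction_se == pytest.approx(res.bse[3], abs=1e-8)
            assert fit.interaction_p == pytest.approx(res.pvalues[3], abs=1e-8)
            assert fit.slope_control == pytest.approx(res.params[1], abs=1e-8)

    def test_equivariance_under_scaling_A(self):
        rng = np.random.default_rng(3)
        m = random_triplet_matrix(rng, slope_diff=1.0)
        fit = fork_fit(m, Triplet("A", "B", "C"))
        m2 = make_matrix(
            np.vstack([m.values.loc["A"] * 3.5, m.values.loc["B"], m.values.loc["C"]]),
            feature_ids=["A", "B", "C"],
            conditions=list(m.condition),
        )
        fit2 = fork_fit(m2, Triplet("A", "B", "C"))
        assert fit2.slope_control == pytest.approx(3.5 * fit.slope_control)
        assert fit2.interaction_estimate == pytest.approx(3.5 * fit.interaction_estimate)
        assert fit2.interaction_p == pytest.approx(fit.interaction_p, abs=1e-12)
        assert fit2.cor_overall == pytest.approx(fit.cor_overall, abs=1e-12)

    def test_invariance_under_common_scaling_of_B_and_C(self):
        rng = np.random.default_rng(4)
        m = random_triplet_matrix(rng, slope_diff=1.0)
        fit = fork_fit(m, Triplet("A", "B", "C"))
        m2 = make_matrix(
            np.vstack([m.values.loc["A"], m.values.loc["B"] * 7, m.values.loc["C"] * 7]),
            feature_ids=["A", "B", "C"],
            conditions=list(m.condition),
        )
        fit2 = fork_fit(m2, Triplet("A", "B", "C"))
        assert fit2.interaction_estimate == pytest.approx(fit.interaction_estimate, rel=1e-10)
        assert fit2.interaction_p == pytest.approx(fit.interaction_p, abs=1e-12)

    def test_collinear_design_flagged(self):
        m = triplet_matrix([1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2], [1, 1, 1, 1, 1, 1], 3)
        fit = fork_fit(m, Triplet("A", "B", "C"))  # constant ratio => collinear
        assert "collinear" in fit.flags


class TestScreen:
    def test_alpha_zero_empty_significant_set(self):
        rng = np.random.default_rng(5)
        m = random_triplet_matrix(rng, slope_diff=3)
        fits = screen_forks(m, [Triplet("A", "B", "C")])
        assert forks.significant_forks(fits, alpha=0.0) == []

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            m = random_triplet_matrix(rng, slope_diff=0.0)
            fit = fork_fit(m, Triplet("A", "B", "C"))
            rej += fit.interaction_p < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_differential_fork_ranks_first_among_equal_slope_forks(self):
        # one slope-difference-3 fork against a dozen equal-slope (null) fork
        # triplets drawn from the same generative model
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n_genes=0, n_metabolites=39, n_enriched_genes=0, n_discriminative=0,
                missing_rate=0,
                fork_specs=[ForkSpec(2, 5, 0.5)] + [ForkSpec(2, 2, 0.5)] * 12,
                rng_seed=seed,
            )
            m, truth = synth.generate_cohort(spec)
            planted = Triplet(*truth.fork_triplets[0][:3])
            triplets = [Triplet(*t[:3]) for t in truth.fork_triplets]
            fits = screen_forks(m, triplets)
            wins += fits[0].triplet == planted
        assert wins >= 18

    def test_bh_adjusted_p_attached_and_monotone(self):
        rng = np.random.default_rng(7)
        ms = [random_triplet_matrix(rng, slope_diff=d) for d in (0, 0, 3)]
        fits = []
        for m in ms:
            fits.extend(screen_forks(m, [Triplet("A", "B", "C")]))
        # combined screen over a shared matrix for a genuine multi-test case
        big = make_matrix(
            np.vstack([m.values for m in ms]),
            feature_ids=[f"{x}{i}" for i in range(3) for x in "ABC"],
            conditions=list(ms[0].condition),
        )
        trips = [Triplet(f"A{i}", f"B{i}", f"C{i}") for i in range(3)]
        out = screen_forks(big, trips, adjust="benjamini-hochberg")
        ps = [f.interaction_p for f in out]
        qs = [f.adjusted_p for f in out]
        assert all(q >= p - 1e-15 for p, q in zip(ps, qs))
        assert ps == sorted(ps)

    def test_fork_table_columns(self, tmp_path):
        rng = np.random.default_rng(8)
        m = random_triplet_matrix(rng, slope_diff=2)
        fits = screen_forks(m, [Triplet("A", "B", "C")])
        forks.write_fork_table(fits, tmp_path / "forks.csv")
        df = pd.read_csv(tmp_path / "forks.csv")
        assert {"A", "B", "C", "interaction_p", "adjusted_p", "cor_control"} <= set(df.columns)
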