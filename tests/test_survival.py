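"""Module-based survival analysis: orientation, sigma statistic, log-rank."""

import numpy as np
import pandas as pd
import pytest

from clam.containers import CLAMError, ModuleSet
from clam.simulate import SimulationConfig, generate
from clam.survival import (
    ModuleSurvival,
    coexpression_sd,
    logrank_split,
    orient_genes,
    survival_screen,
)
from tests.conftest import make_expression


def logrank_oracle(time_a, event_a, time_b, event_b):
    """Hand-tabulated two-group log-rank chi-square.

    At each distinct event time: n at risk and deaths per group; the
    statistic is (sum(O_a - E_a))^2 / sum(V) with the hypergeometric
    variance at every event time.
    """
    times = sorted(
        set([t for t, e in zip(time_a, event_a) if e] + [t for t, e in zip(time_b, event_b) if e])
    )
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n_a = sum(1 for x in time_a if x >= t)
        n_b = sum(1 for x in time_b if x >= t)
        d_a = sum(1 for x, e in zip(time_a, event_a) if x == t and e)
        d_b = sum(1 for x, e in zip(time_b, event_b) if x == t and e)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        E_a = d * n_a / n
        O_minus_E += d_a - E_a
        V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return O_minus_E ** 2 / V


def clinical_frame(samples, times, events):
    return pd.DataFrame({"sample_id": samples, "time": times, "event": events})


class TestOrientation:
    def test_all_positive_correlations_keep_plus_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = pd.DataFrame(
            [base, base * 2 + 1, base + 0.1], index=["g1", "g2", "g3"]
        )
        signs = orient_genes(expr)
        assert (signs == 1.0).all()

    def test_exact_negative_gets_minus_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 8.0])
        expr = pd.DataFrame([base, base * 1.5, -base], index=["g1", "g2", "g3"])
        signs = orient_genes(expr)
        assert signs["g3"] == -1.0
        assert signs["g1"] == 1.0

    def test_flipped_matrix_consensus_nonnegative(self, rng):
        base = rng.standard_normal(12)
        rows = [
            base + 0.3 * rng.standard_normal(12),
            -base + 0.3 * rng.standard_normal(12),
            base + 0.3 * rng.standard_normal(12),
            -2 * base + 0.3 * rng.standard_normal(12),
        ]
        expr = pd.DataFrame(rows, index=["g1", "g2", "g3", "g4"])
        signs = orient_genes(expr)
        flipped = expr.mul(signs, axis=0)
        corr = flipped.T.corr()
        reference = signs.index[signs == 1.0][0]
        assert (corr[reference] >= -1e-12).all()


class TestCoexpressionSD:
    def test_identical_zscores_give_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expression([base, base * 3.0 - 1.0])
        sigma = coexpression_sd(["g1", "g2"], expr)
        assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_two_point_population_sd(self):
        # build profiles whose z-scores in sample s1 are +1 and -1
        expr = make_expression([[1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]])
        # both genes perfectly anticorrelated: orientation flips g2, so the
        # aligned z-scores coincide and sigma is 0 everywhere
        sigma = coexpression_sd(["g1", "g2"], expr)
        assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_matches_hand_computation(self, rng):
        values = rng.standard_normal((3, 6))
        expr = make_expression(values)
        sigma = coexpression_sd(["g1", "g2", "g3"], expr)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        signs = orient_genes(
            pd.DataFrame(z, index=["g1", "g2", "g3"], columns=expr.samples)
        ).to_numpy()
        aligned = z * signs[:, None]
        expected = aligned.std(axis=0)
        np.testing.assert_allclose(sigma.to_numpy(), expected, atol=1e-12)

    def test_flip_invariance(self, rng):
        values = rng.standard_normal((4, 8))
        expr = make_expression(values)
        flipped = values.copy()
        flipped[2] = -flipped[2]
        expr_flipped = make_expression(flipped)
        s1 = coexpression_sd(list(expr.data.index), expr)
        s2 = coexpression_sd(list(expr.data.index), expr_flipped)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_zero_variance_gene_dropped(self):
        values = np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [2, 4, 6, 9]])
        sigma = coexpression_sd(["g1", "g2", "g3"], make_expression(values))
        assert len(sigma) == 4  # computed from the two usable genes

    def test_module_below_two_genes_is_error(self):
        values = np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]])
        with pytest.raises(CLAMError):
            coexpression_sd(["g1", "g2"], make_expression(values))


class TestLogrank:
    def test_six_patient_worked_example_exact(self):
        # group A (stat > median): events at t = 1, 3, 5
        # group B: event at t = 2, censored at 4 and 6
        stat = pd.Series(
            {"p1": 1.0, "p2": 1.0, "p3": 1.0, "p4": 0.0, "p5": 0.0, "p6": 0.0}
        )
        clin = clinical_frame(
            ["p1", "p2", "p3", "p4", "p5", "p6"],
            [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
            [1, 1, 1, 1, 0, 0],
        )
        result = logrank_split(stat, clin)
        expected = logrank_oracle(
            [1.0, 3.0, 5.0], [1, 1, 1], [2.0, 4.0, 6.0], [1, 0, 0]
        )
        assert result.chi_square == pytest.approx(expected, abs=1e-10)
        assert result.group_sizes == {"high": 3, "low": 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_small_cohorts(self, seed):
        gen = np.random.default_rng(seed)
        n = 10
        stat = pd.Series(gen.standard_normal(n), index=[f"p{i}" for i in range(n)])
        times = np.round(gen.exponential(5, n), 1) + 0.1
        events = gen.integers(0, 2, n)
        clin = clinical_frame(list(stat.index), times, events)
        if events.sum() == 0:
            return
        result = logrank_split(stat, clin)
        med = np.median(stat)
        high = stat > med
        expected = logrank_oracle(
            times[high.to_numpy()], events[high.to_numpy()],
            times[~high.to_numpy()], events[~high.to_numpy()],
        )
        assert result.chi_square == pytest.approx(expected, abs=1e-8)

    def test_identical_curves_null(self):
        stat = pd.Series(
            [1.0, 1.0, 0.0, 0.0], index=["p1", "p2", "p3", "p4"]
        )
        clin = clinical_frame(["p1", "p2", "p3", "p4"], [2.0, 4.0, 2.0, 4.0], [1, 1, 1, 1])
        result = logrank_split(stat, clin)
        assert result.chi_square == pytest.approx(0.0, abs=1e-10)
        assert result.p_value == pytest.approx(1.0)

    def test_constant_statistic_degenerate(self):
        stat = pd.Series([0.5] * 5, index=[f"p{i}" for i in range(5)])
        clin = clinical_frame(list(stat.index), [1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        result = logrank_split(stat, clin)
        assert result.degenerate
        assert result.p_value == 1.0
        assert result.group_sizes["high"] == 0  # ties all go to "low"

    def test_median_ties_go_to_low_group(self):
        stat = pd.Series([1.0, 2.0, 2.0, 3.0], index=["p1", "p2", "p3", "p4"])
        clin = clinical_frame(["p1", "p2", "p3", "p4"], [1, 2, 3, 4], [1, 1, 1, 1])
        result = logrank_split(stat, clin)
        assert result.groups["p2"] == "low"
        assert result.groups["p3"] == "low"
        assert result.groups["p4"] == "high"


class TestScreen:
    def test_single_module_three_modes(self, rng):
        values = rng.standard_normal((4, 20))
        expr = make_expression(values, samples=[f"p{i}" for i in range(20)])
        clin = clinical_frame(
            [f"p{i}" for i in range(20)],
            rng.exponential(5, 20),
            rng.integers(0, 2, 20),
        )
        modules = ModuleSet.from_dict({"m1": {"g1", "g2", "g3", "g4"}})
        table = survival_screen(modules, expr, clin)
        assert len(table) == 3
        assert set(table["mode"]) == {"sd", "mean", "single_gene"}
        assert (table["p_adj"] >= table["p"] - 1e-12).all()

    def test_sd_mode_beats_mean_mode_for_causal_module(self):
        study = generate(SimulationConfig(seed=2))
        table = survival_screen(study.truth, study.datasets[0], study.clinical)
        causal = study.causal_module
        p_sd = table.loc[(table["module"] == causal) & (table["mode"] == "sd"), "p"].iloc[0]
        p_mean = table.loc[(table["module"] == causal) & (table["mode"] == "mean"), "p"].iloc[0]
        assert p_sd < p_mean
        assert p_sd < 0.05

    def test_km_coordinates_emitted(self, rng):
        values = rng.standard_normal((3, 16))
        expr = make_expression(values, samples=[f"p{i}" for i in range(16)])
        clin = clinical_frame(
            [f"p{i}" for i in range(16)],
            rng.exponential(5, 16) + 0.1,
            np.ones(16, dtype=int),
        )
        modules = ModuleSet.from_dict({"m1": {"g1", "g2", "g3"}})
        results = ModuleSurvival(modules, expr, clin).fit(modes=("sd",))
        km = results.table["result"].iloc[0].km_coordinates(clin)
        assert set(km) == {"low", "high"}
        for frame in km.values():
            assert (frame["survival"].diff().dropna() <= 1e-12).all()
        assert "Module-based survival screen" in results.summary()
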