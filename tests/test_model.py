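"""The psychometric model: prediction, likelihood, fitting, trading ratio."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from cuetrade import (
    PsychometricParams,
    ResponseTable,
    StimulusCondition,
    UndefinedTITRError,
    UnidentifiableDesignError,
    cancellation_itd,
    compute_titr,
    fit_psychometric,
    neg_log_likelihood,
    predict_p_right,
    residual_diagnostics,
    solve_cancellation_itd,
)
from cuetrade.model import FitResult, _p_right

from conftest import make_binomial_table


def params_strategy(zero_bias=False):
    def build(a_ild, a_itd, beta, gamma, dfrac):
        if zero_bias:
            beta, dfrac = 0.0, 0.0
        return PsychometricParams(a_ild, a_itd, beta, gamma, gamma / 2 * dfrac)

    return st.builds(
        build,
        st.floats(-1, 1),
        st.floats(-0.1, 0.1),
        st.floats(-3, 3),
        st.floats(0, 0.9),
        st.floats(-1, 1),
    )


conditions = st.tuples(st.floats(-500, 500), st.floats(-10, 10))


class TestPredict:
    def test_neutral_stimulus_is_midline(self):
        p = PsychometricParams(0.3, 0.02)
        assert predict_p_right(p, StimulusCondition(0, 0)) == pytest.approx(0.5)

    def test_pure_lapse_limit(self):
        p = PsychometricParams(0.3, 0.02, beta=1.5, gamma=1 - 1e-12)
        for itd, ild in [(-80, -4), (80, 4), (0, 1)]:
            assert predict_p_right(p, StimulusCondition(itd, ild)) == pytest.approx(
                0.5, abs=1e-9
            )

    def test_cue_cancellation_at_20us_per_db(self):
        # an 80 µs ITD exactly offsets a -4 dB ILD at a 20 µs/dB trading ratio
        p = PsychometricParams(alpha_ild=0.25, alpha_itd=0.0125)
        assert predict_p_right(p, StimulusCondition(80, -4)) == pytest.approx(0.5)

    def test_against_numerical_integration_of_normal_density(self):
        # Phi(1) from quadrature of the density, not from the package's CDF
        phi1 = quad(lambda x: np.exp(-x * x / 2) / np.sqrt(2 * np.pi), -np.inf, 1.0)[0]
        p = PsychometricParams(1.0, 0.0, beta=0.0, gamma=0.1, delta=0.02)
        expected = phi1 * 0.9 + 0.05 + 0.02
        assert predict_p_right(p, StimulusCondition(0, 1)) == pytest.approx(
            expected, abs=1e-10
        )

    @given(params_strategy(), conditions)
    def test_bounds_invariant(self, params, cell):
        """p is confined to [γ/2+δ, 1−γ/2+δ] ⊆ [0,1] with no post-hoc clamp."""
        p = float(_p_right(params, cell[0], cell[1]))
        lo = params.gamma / 2 + params.delta
        hi = 1 - params.gamma / 2 + params.delta
        assert lo - 1e-12 <= p <= hi + 1e-12
        assert -1e-12 <= p <= 1 + 1e-12

    @given(
        st.floats(0, 1),
        st.floats(0, 0.1),
        st.floats(-3, 3),
        st.floats(0, 0.9),
        st.floats(-400, 400),
        st.floats(0, 100),
        st.floats(-8, 8),
        st.floats(0, 2),
    )
    def test_monotone_in_both_cues(self, a_ild, a_itd, beta, gamma, itd, ditd, ild, dild):
        params = PsychometricParams(a_ild, a_itd, beta, gamma, 0.0)
        base = float(_p_right(params, itd, ild))
        assert float(_p_right(params, itd + ditd, ild)) >= base - 1e-12
        assert float(_p_right(params, itd, ild + dild)) >= base - 1e-12

    @given(params_strategy(zero_bias=True), conditions)
    def test_point_symmetry_at_zero_biases(self, params, cell):
        itd, ild = cell
        total = float(_p_right(params, itd, ild)) + float(_p_right(params, -itd, -ild))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestNegLogLikelihood:
    def test_single_cell_coin_flip(self):
        table = ResponseTable(animal_id="o", counts={(60.0, 0.0): (1, 2)})
        params = PsychometricParams(0.0, 0.0)  # p = 0.5 everywhere
        assert neg_log_likelihood(params, table) == pytest.approx(2 * np.log(2))

    def test_equals_per_trial_bernoulli_sum(self):
        params = PsychometricParams(0.2, 0.01, 0.1, 0.12, 0.03)
        table = make_binomial_table(params, n_per_cell=40, seed=5)
        expected = 0.0
        for (itd, ild), (k, n) in table.counts.items():
            p = float(_p_right(params, itd, ild))
            expected -= k * np.log(p) + (n - k) * np.log(1 - p)
        assert neg_log_likelihood(params, table) == pytest.approx(expected, rel=1e-12)

    def test_epsilon_guard_keeps_value_finite_and_warns(self):
        params = PsychometricParams(5.0, 0.5, beta=10.0)  # p == 1.0 at (80, 4)
        table = ResponseTable(animal_id="o", counts={(80.0, 4.0): (3, 4)})
        with pytest.warns(RuntimeWarning, match="epsilon guard"):
            val = neg_log_likelihood(params, table)
        assert np.isfinite(val) and val > 20  # ~ -ln(1e-12)

    def test_nonnegative(self):
        params = PsychometricParams(0.3, 0.015, 0.0, 0.1, 0.0)
        table = make_binomial_table(params, n_per_cell=30, seed=9)
        assert neg_log_likelihood(params, table) >= 0


class TestTITR:
    def test_definition(self):
        assert compute_titr(PsychometricParams(0.2, 0.01)) == pytest.approx(20.0)

    def test_ild_blind_observer(self):
        assert compute_titr(PsychometricParams(0.0, 0.01)) == 0.0

    def test_undefined_without_itd_sensitivity(self):
        with pytest.raises(UndefinedTITRError):
            compute_titr(PsychometricParams(0.2, 0.0))

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_invariant_under_joint_rescaling(self, c):
        base = PsychometricParams(0.2, 0.01, beta=0.3, gamma=0.1, delta=0.02)
        scaled = dataclasses.replace(
            base, alpha_ild=c * 0.2, alpha_itd=c * 0.01, beta=c * 0.3
        )
        assert compute_titr(scaled) == pytest.approx(compute_titr(base))


class TestCancellation:
    @pytest.mark.parametrize(
        "titr, ild, expected",
        [(20.0, 4.0, 80.0), (18.7, 1.0, 18.7), (20.0, -4.0, 80.0), (33.0, 0.0, 0.0)],
    )
    def test_closed_form(self, titr, ild, expected):
        assert cancellation_itd(titr, ild) == pytest.approx(expected)

    @pytest.mark.parametrize("gamma", [0.0, 0.2])
    def test_numeric_solution_matches_closed_form(self, gamma):
        params = PsychometricParams(0.25, 0.0125, gamma=gamma)
        itd = solve_cancellation_itd(params, -4.0)
        assert itd == pytest.approx(80.0, abs=1e-6)
        assert abs(itd) == pytest.approx(cancellation_itd(20.0, -4.0), abs=1e-6)
        # canceling ITD points opposite to the ILD
        assert np.sign(itd) == -np.sign(-4.0)


class TestFit:
    gen = PsychometricParams(0.28, 0.015, beta=-0.05, gamma=0.1, delta=0.02)

    def test_ml_dominance_over_generating_params(self):
        table = make_binomial_table(self.gen, n_per_cell=170, seed=3)  # ~4080 trials
        fit = fit_psychometric(table)
        assert fit.converged
        assert fit.neg_log_lik <= neg_log_likelihood(self.gen, table) + 1e-9

    def test_recovers_parameters_at_scale(self):
        table = make_binomial_table(self.gen, n_per_cell=170, seed=3)
        fit = fit_psychometric(table)
        assert fit.titr_us_per_db == pytest.approx(
            compute_titr(self.gen), rel=0.15
        )
        assert fit.params.gamma == pytest.approx(self.gen.gamma, abs=0.06)
        assert fit.identifiable

    def test_residuals_shrink_with_expected_counts(self):
        # counts set to their expectations: the MLE sits at the generator and
        # residuals reduce to rounding noise
        n = 200000
        counts = {}
        for ild in (-4.0, -1.0, 0.0, 1.0, 4.0):
            for itd in (-80.0, -60.0, 0.0, 60.0, 80.0):
                if itd == 0 and ild == 0:
                    continue
                p = float(_p_right(self.gen, itd, ild))
                counts[(itd, ild)] = (round(n * p), n)
        table = ResponseTable(animal_id="o", counts=counts)
        fit = fit_psychometric(table)
        assert max(abs(r) for r in fit.residuals.values()) < 1e-3

    def test_residual_diagnostics_match_independent_recount(self):
        table = make_binomial_table(self.gen, n_per_cell=60, seed=21)
        fit = fit_psychometric(table)
        residuals, summary = residual_diagnostics(fit, table)
        for (itd, ild), (k, n) in table.counts.items():
            expected = k / n - float(_p_right(fit.params, itd, ild))
            assert residuals[(itd, ild)] == pytest.approx(expected, abs=1e-12)
        assert summary["max_abs_residual"] == pytest.approx(
            max(abs(r) for r in residuals.values())
        )
        assert residuals == pytest.approx(fit.residuals)

    def test_single_ild_level_is_unidentifiable(self):
        counts = {(itd, 1.0): (5, 10) for itd in (-80.0, -60.0, 60.0, 80.0)}
        with pytest.raises(UnidentifiableDesignError, match="ILD"):
            fit_psychometric(ResponseTable(animal_id="o", counts=counts))

    def test_guessing_observer_flagged_unidentifiable(self):
        guesser = PsychometricParams(0.0, 0.0, gamma=0.95)
        table = make_binomial_table(guesser, n_per_cell=25, seed=14)
        fit = fit_psychometric(table)
        assert "titr_unidentifiable" in fit.identifiability_flags
        assert not fit.identifiable

    def test_one_sided_responses_flagged_as_separation(self):
        counts = {
            (itd, ild): (12, 12)
            for itd in (-80.0, 80.0)
            for ild in (-4.0, 4.0)
        }
        fit = fit_psychometric(ResponseTable(animal_id="o", counts=counts))
        assert "separation" in fit.identifiability_flags
        assert not fit.identifiable
        assert np.isfinite(fit.neg_log_lik)

    def test_report_text_round_trip(self):
        table = make_binomial_table(self.gen, n_per_cell=50, seed=8)
        fit = fit_psychometric(table)
        again = FitResult.from_text(fit.to_text())
        assert again == fit
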