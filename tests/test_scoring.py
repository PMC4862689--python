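"""Scoring-layer tests: score arithmetic on closed-form stubs, protocol
drivers on the ODE layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scaffold_cycle as sc
from scaffold_cycle.scoring import (
    PulseProtocol,
    PulseRecord,
    StaircaseProtocol,
    adaptation_fitness,
    adaptation_precision,
    adaptation_sensitivity,
    pulse_level,
    run_pulse_train,
    run_staircase,
    staircase_deltas,
    ultrasensitivity_score,
)
from tests.conftest import random_parameter_sets


def hill_plateaus(protocol, n=1.0, threshold=None, y_total=1.0):
    """Closed-form dose-response stub: Hill function over the staircase."""
    thr = threshold if threshold is not None else protocol.levels[1]
    def hill(I):
        return y_total * I ** n / (thr ** n + I ** n)
    return np.array([hill(v) for v in protocol.visiting_order()])


class TestUltrasensitivityArithmetic:
    def test_flat_response_scores_zero(self):
        res = ultrasensitivity_score(np.full(7, 0.3), y_total=1.0)
        assert res.F == 0.0
        assert res.S_amp == 0.0

    def test_ideal_step_at_middle_plateau_scores_one(self):
        # all of the swing happens at step 2, up and down
        outputs = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        res = ultrasensitivity_score(outputs, y_total=1.0)
        assert res.S_amp == pytest.approx(1.0)
        assert res.S_ult == pytest.approx(1.0, abs=1e-5)
        assert res.F == pytest.approx(1.0, abs=1e-5)

    def test_hand_computed_hill_staircase(self):
        # Eq-by-eq hand evaluation on an analytic Hill-response staircase
        prot = StaircaseProtocol()
        outputs = hill_plateaus(prot, n=2.0)
        o = outputs
        dy_up = (abs(o[1] - o[0]), abs(o[2] - o[1]), abs(o[3] - o[2]))
        dy_dn = (abs(o[6] - o[5]), abs(o[5] - o[4]), abs(o[4] - o[3]))
        s_u1 = (dy_up[1] + dy_dn[1]) / (dy_up[0] + dy_dn[0])
        s_u3 = (dy_up[1] + dy_dn[1]) / (dy_up[2] + dy_dn[2])
        S_amp = (dy_up[1] + dy_dn[1]) / 2.0
        S_ult = (s_u1 / (1 + s_u1)) * (s_u3 / (1 + s_u3))
        res = ultrasensitivity_score(outputs, y_total=1.0)
        assert res.S_amp == pytest.approx(S_amp, rel=1e-14)
        assert res.s_u1 == pytest.approx(s_u1, rel=1e-14)
        assert res.s_u3 == pytest.approx(s_u3, rel=1e-14)
        assert res.F == pytest.approx(S_amp * S_ult, rel=1e-14)

    def test_sharper_hill_scores_higher(self):
        prot = StaircaseProtocol()
        f_steep = ultrasensitivity_score(hill_plateaus(prot, n=20.0), 1.0).F
        f_shallow = ultrasensitivity_score(hill_plateaus(prot, n=1.0), 1.0).F
        assert f_steep > f_shallow

    def test_scale_invariance(self):
        prot = StaircaseProtocol()
        outputs = hill_plateaus(prot, n=4.0)
        r1 = ultrasensitivity_score(outputs, y_total=1.0)
        r2 = ultrasensitivity_score(outputs * 37.0, y_total=37.0)
        assert r1.F == pytest.approx(r2.F, rel=1e-12)
        assert r1.S_amp == pytest.approx(r2.S_amp, rel=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=7, max_size=7))
    @settings(max_examples=100, deadline=None)
    def test_score_bounds(self, outputs):
        res = ultrasensitivity_score(np.array(outputs), y_total=1.0)
        assert 0.0 <= res.S_amp <= 1.0
        assert 0.0 <= res.S_ult <= 1.0
        assert 0.0 <= res.F <= 1.0

    def test_floored_denominator_saturates_not_raises(self):
        outputs = np.array([0.0, 0.0, 0.5, 0.5, 0.5, 0.0, 0.0])
        res = ultrasensitivity_score(outputs, y_total=1.0)
        assert res.s_u1 == pytest.approx(1e6)
        assert np.isfinite(res.F)


class TestAdaptationArithmetic:
    def test_sensitivity_direct_substitution(self):
        assert adaptation_sensitivity(1.0, 2.0, 1.0, 2.0) == pytest.approx(1.0)
        assert adaptation_sensitivity(1.0, 1.0, 1.0, 2.0) == 0.0
        # O_0=1, O_*=1.5, I_0=1, I_1=11 -> 0.5/10 = 0.05
        assert adaptation_sensitivity(1.0, 1.5, 1.0, 11.0) == \
            pytest.approx(0.05)

    def test_sensitivity_preconditions(self):
        with pytest.raises(ZeroDivisionError):
            adaptation_sensitivity(0.0, 1.0, 1.0, 2.0)
        with pytest.raises(ZeroDivisionError):
            adaptation_sensitivity(1.0, 1.0, 1.0, 1.0)

    def test_precision_hand_arithmetic(self):
        # O_0=1, O_1=1.1, I_0=1, I_1=2 -> |0.1/1|^-1 = 10
        assert adaptation_precision(1.0, 1.1, 1.0, 2.0) == pytest.approx(10.0)

    def test_perfect_adaptation_hits_cap(self):
        assert adaptation_precision(1.0, 1.0, 1.0, 2.0) == pytest.approx(1e6)

    def test_precision_equals_inverse_sensitivity_without_relaxation(self):
        # O_1 == O_*: the two formulas coincide reciprocally
        s = adaptation_sensitivity(1.0, 1.5, 1.0, 3.0)
        p = adaptation_precision(1.0, 1.5, 1.0, 3.0)
        assert p == pytest.approx(1.0 / s)

    def test_pulse_with_zero_peak_annihilates_fitness(self):
        recs = [PulseRecord(m, 0.0, 0.0, 0.0, 0.0, 0.5)
                for m in (1.0, 10.0, 100.0)]
        res = adaptation_fitness(recs, C=2.0, K_thresh=0.1)
        assert res.w == 0.0

    def test_perfect_pulses_score_one(self):
        # peaks at 1/C with exact return in both directions
        recs = [PulseRecord(m, 0.5, 0.0, 0.5, 0.0, 0.5)
                for m in (1.0, 10.0, 100.0)]
        res = adaptation_fitness(recs, C=2.0, K_thresh=0.1)
        assert res.w_i == pytest.approx((1.0, 1.0, 1.0))
        assert res.w == pytest.approx(1.0)

    def test_geometric_mean_hand_arithmetic(self):
        # w_i = (0.25, 1, 1) -> w = 0.25^(1/3)
        recs = [PulseRecord(1.0, 0.25, 0.0, 0.25, 0.0, 0.5),
                PulseRecord(10.0, 0.5, 0.0, 0.5, 0.0, 0.5),
                PulseRecord(100.0, 0.5, 0.0, 0.5, 0.0, 0.5)]
        res = adaptation_fitness(recs, C=2.0, K_thresh=0.1)
        assert res.w_i[0] == pytest.approx(0.25)
        assert res.w == pytest.approx(0.25 ** (1.0 / 3.0))

    def test_up_down_exchange_symmetry(self):
        a = PulseRecord(1.0, 0.4, 0.02, 0.1, 0.05, 0.5)
        b = PulseRecord(1.0, 0.1, 0.05, 0.4, 0.02, 0.5)
        assert pulse_level(a, 2.0, 0.1) == pytest.approx(
            pulse_level(b, 2.0, 0.1))

    def test_hand_computed_w_i(self):
        r = PulseRecord(1.0, 0.3, 0.05, 0.2, 0.01, 0.4)
        C, K = 2.0, 0.1
        expect = (0.6 * (0.1 / 0.15)) * (0.4 * (0.1 / 0.11))
        assert pulse_level(r, C, K) == pytest.approx(expect, rel=1e-14)

    def test_fitness_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            recs = [PulseRecord(m, rng.uniform(0, 1), rng.uniform(0, 1),
                                rng.uniform(0, 1), rng.uniform(0, 1), 0.5)
                    for m in (1.0, 10.0, 100.0)]
            res = adaptation_fitness(recs, C=2.0, K_thresh=0.1)
            assert 0.0 <= res.w <= 1.0


class TestProtocolDrivers:
    def test_dead_model_staircase_is_flat(self):
        # k3 ~ 0: no phosphorylation anywhere
        rates = sc.RateConstants(1, 1, 1e-300, 1, 1, 1, 1, 1, 1, 1)
        model = sc.build_model(rates)
        tot = sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.1)
        plat = run_staircase(model, tot)
        assert np.allclose(plat.outputs, 0.0, atol=1e-12)
        res = ultrasensitivity_score(plat, tot.S_total)
        assert res.F == 0.0

    def test_dead_model_pulses_are_flat(self):
        rates = sc.RateConstants(1, 1, 1e-300, 1, 1, 1, 1, 1, 1, 1)
        model = sc.build_model(rates)
        tot = sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.1)
        recs = run_pulse_train(model, tot)
        for r in recs:
            assert r.dO_max_up == pytest.approx(0.0, abs=1e-12)
            assert r.dO_ss_up == pytest.approx(0.0, abs=1e-12)

    def test_no_hysteresis_up_down_plateaus_agree(self):
        # up-plateau at level L equals down-plateau at the same L for
        # systems with a unique steady state
        mismatches = 0
        for rates, totals in random_parameter_sets(40, seed=99):
            model = sc.build_model(rates)
            plat = run_staircase(model, totals, raise_on_failure=False)
            if not plat.converged:
                continue
            o = plat.outputs
            scale = max(totals.S_total, 1e-30)
            # visiting order [b, L1, L2, L3, L2, L1, b]
            if not (np.isclose(o[2], o[4], atol=1e-5 * scale)
                    and np.isclose(o[1], o[5], atol=1e-5 * scale)
                    and np.isclose(o[0], o[6], atol=1e-5 * scale)):
                mismatches += 1
        assert mismatches <= 2  # flagged, expected rare

    def test_scaffold_free_dose_response_is_monotone(self):
        # T_total = 0: classic covalent-modification cycle, monotone in input
        rates = sc.RateConstants(5.0, 1.0, 2.0, 5.0, 1.0, 2.0, 1, 1, 1, 1)
        model = sc.build_model(rates)
        grid = np.geomspace(1e-4, 1.0, 12)
        outs = []
        for K_tot in grid:
            tot = sc.ConcentrationTotals(1.0, K_tot, 0.1, 0.0)
            outs.append(sc.steady_state(model, tot).Sp)
        assert np.all(np.diff(outs) >= -1e-9)

    def test_pulse_records_relative_increments(self):
        prot = PulseProtocol(baseline=0.01, magnitudes=(1.0, 10.0))
        assert prot.absolute_increments() == pytest.approx((0.01, 0.1))
        prot_abs = PulseProtocol(baseline=0.01, magnitudes=(1.0, 10.0),
                                 relative=False)
        assert prot_abs.absolute_increments() == pytest.approx((1.0, 10.0))

    def test_staircase_validation(self):
        with pytest.raises(ValueError):
            StaircaseProtocol(levels=(1.0, 0.5, 2.0))
        with pytest.raises(ValueError):
            StaircaseProtocol(baseline=0.5, levels=(0.1, 1.0, 10.0))

    def test_staircase_deltas_requires_seven_plateaus(self):
        with pytest.raises(ValueError):
            staircase_deltas(np.zeros(5))
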