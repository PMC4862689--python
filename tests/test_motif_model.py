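"""Unit and property tests of the mass-action motif layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import null_space

import scaffold_cycle as sc
from scaffold_cycle import _kernel
from scaffold_cycle.motif_model import (
    CONSERVATION,
    InvalidParameterError,
    SPECIES,
    STOICHIOMETRY,
    UndefinedFractionError,
    apply_kinase_change,
    derived_constants,
    geometric_mean_saturation,
    goldbeter_koshland_fraction,
    initial_state,
    jacobian,
    saturation_index,
    sequestration_fractions,
)
from tests.conftest import random_parameter_sets


class TestModelStructure:
    def test_counts(self, unit_model):
        assert unit_model.n_species == 9
        assert unit_model.n_rates == 10
        assert unit_model.stoichiometry.shape == (9, 10)

    def test_stoichiometry_rank_and_conservation_laws(self, unit_model):
        # brute-force null space of N^T: independent conservation laws
        assert np.linalg.matrix_rank(unit_model.stoichiometry) == 5
        left_null = null_space(unit_model.stoichiometry.T)
        assert left_null.shape[1] == 4
        # the four documented moiety vectors annihilate the stoichiometry
        assert np.allclose(CONSERVATION @ STOICHIOMETRY, 0.0)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(InvalidParameterError):
            sc.RateConstants(0.0, *([1.0] * 9))
        with pytest.raises(InvalidParameterError):
            sc.RateConstants(-1.0, *([1.0] * 9))
        with pytest.raises(InvalidParameterError):
            sc.RateConstants(float("nan"), *([1.0] * 9))


class TestRhs:
    def test_hand_evaluated_complex_formation(self):
        # S=1, K=1, all else 0, k1=2: d(SK)/dt = 2*1*1 - (k2+k3)*0 = 2
        rates = sc.RateConstants(2.0, 3.0, 5.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                                 1.0, 1.0)
        model = sc.build_model(rates)
        y = np.zeros(9)
        y[SPECIES.index("S")] = 1.0
        y[SPECIES.index("K")] = 1.0
        dy = sc.rhs(model, y)
        assert dy[SPECIES.index("SK")] == pytest.approx(2.0)
        assert dy[SPECIES.index("S")] == pytest.approx(-2.0)
        assert dy[SPECIES.index("K")] == pytest.approx(-2.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_moiety_conservation_of_rhs(self, seed):
        rng = np.random.default_rng(seed)
        rates = sc.RateConstants(*np.exp(rng.uniform(-3, 3, 10)))
        model = sc.build_model(rates)
        y = rng.uniform(0, 2.0, 9)
        dy = sc.rhs(model, y)
        assert np.allclose(CONSERVATION @ dy, 0.0, atol=1e-12 * dy.max())

    def test_reduced_kernel_rhs_matches_full_rhs(self, random_sets_small):
        for rates, totals in random_sets_small[:10]:
            model = sc.build_model(rates)
            tot = totals.with_K_total(0.05)
            rng = np.random.default_rng(1)
            x = rng.uniform(0, 0.01, 5)
            state = sc.SpeciesState.from_reduced(x, tot)
            out = np.empty(5)
            _kernel.rhs5(rates.as_array(), tot.as_array(), x, out)
            full = sc.rhs(model, state)
            # reduced coords are (Sp, SK, SpP, KT, PT)
            idx = [SPECIES.index(n) for n in ("Sp", "SK", "SpP", "KT", "PT")]
            assert np.allclose(out, full[idx], rtol=1e-12, atol=1e-14)

    def test_kernel_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        k = np.exp(rng.uniform(-2, 2, 10))
        tot = np.array([1.0, 0.3, 0.1, 0.2])
        x = rng.uniform(0, 0.05, 5)
        J = np.empty((5, 5))
        _kernel.jac5(k, tot, x, J)
        f0 = np.empty(5)
        _kernel.rhs5(k, tot, x, f0)
        eps = 1e-7
        for j in range(5):
            xp = x.copy()
            xp[j] += eps
            fp = np.empty(5)
            _kernel.rhs5(k, tot, xp, fp)
            assert np.allclose((fp - f0) / eps, J[:, j], rtol=2e-5,
                               atol=1e-6)


class TestDerivedConstants:
    def test_formulas(self):
        rates = sc.RateConstants(1.0, 1.0, 1.0, 2.0, 1.0, 3.0, 10.0, 1.0,
                                 4.0, 2.0)
        d = derived_constants(rates)
        assert d.KM_K == pytest.approx(2.0)
        assert d.KM_P == pytest.approx(2.0)
        assert d.KD_K == pytest.approx(0.1)
        assert d.KD_P == pytest.approx(0.5)

    def test_homogeneity_doubling_k1_halves_KM(self):
        r1 = sc.RateConstants(1.0, 1.0, 1.0, 1, 1, 1, 1, 1, 1, 1)
        r2 = sc.RateConstants(2.0, 1.0, 1.0, 1, 1, 1, 1, 1, 1, 1)
        assert derived_constants(r2).KM_K == pytest.approx(
            derived_constants(r1).KM_K / 2.0)

    def test_saturation_index(self):
        d = derived_constants(sc.RateConstants(20.0, 1.0, 1.0, 2.0, 1.0,
                                               1.0, 1, 1, 1, 1))
        sk, sp = saturation_index(d, 1.0)
        assert sk == pytest.approx(0.1)
        assert sp == pytest.approx(1.0)  # boundary: index exactly 1

    def test_geometric_mean_two_enzymes(self):
        # normalised K_M of 0.01 and 1 -> geometric mean 0.1
        assert geometric_mean_saturation([0.01, 1.0], 1.0) == \
            pytest.approx(0.1)


class TestSteadyState:
    def test_no_kinase_means_no_phosphorylation(self, unit_model):
        tot = sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.2)
        ss = sc.steady_state(unit_model, tot)
        assert ss.Sp == pytest.approx(0.0, abs=1e-12)
        assert ss.SK == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_system_gives_equal_halves(self):
        # k1..k3 == k4..k6, (k7,k8) == (k9,k10), K_total == P_total:
        # swapping S<->Sp and K<->P is a symmetry, so Sp == S at steady state
        rates = sc.RateConstants(2.0, 1.0, 3.0, 2.0, 1.0, 3.0, 5.0, 1.0,
                                 5.0, 1.0)
        model = sc.build_model(rates)
        tot = sc.ConcentrationTotals(1.0, 0.1, 0.1, 0.3)
        ss = sc.steady_state(model, tot)
        assert ss.Sp == pytest.approx(ss.S, rel=1e-8)
        assert ss.SK == pytest.approx(ss.SpP, rel=1e-8)
        assert ss.KT == pytest.approx(ss.PT, rel=1e-8)

    def test_goldbeter_koshland_limit(self):
        # T_total = 0, enzymes at 1e-3 of substrate: fractional
        # phosphorylation tracks the closed-form zero-order solution to 1%
        rates = sc.RateConstants(10.0, 1.0, 1.0, 10.0, 1.0, 1.0,
                                 1.0, 1.0, 1.0, 1.0)
        model = sc.build_model(rates)
        d = derived_constants(rates)
        S_tot, P_tot = 1.0, 1e-3
        for u in np.geomspace(0.2, 5.0, 10):
            K_tot = u * P_tot
            tot = sc.ConcentrationTotals(S_tot, K_tot, P_tot, 0.0)
            ss = sc.steady_state(model, tot)
            f_num = (ss.Sp + ss.SpP) / S_tot
            f_gk = goldbeter_koshland_fraction(
                rates.k3 * K_tot, rates.k6 * P_tot, d.KM_K, d.KM_P, S_tot)
            assert f_num == pytest.approx(f_gk, abs=0.01)

    def test_detailed_balance_without_catalysis(self):
        # k3 = k6 = 0: pure binding network equilibrates with
        # [SK]/([S][K]) = k1/k2 etc.
        k = np.array([2.0, 1.0, 1e-300, 3.0, 2.0, 1e-300, 4.0, 1.0, 5.0,
                      2.0])
        tot = np.array([1.0, 0.3, 0.2, 0.4])
        x0 = np.zeros(5)
        x0[0] = 0.4  # some phosphosubstrate to engage the SpP pair
        x, ok = _kernel.steady5(k, tot, x0)
        assert ok
        S, K, P, T = _kernel.free_species(x, tot)
        assert x[1] / (S * K) == pytest.approx(2.0 / 1.0, rel=1e-6)
        assert x[2] / (x[0] * P) == pytest.approx(3.0 / 2.0, rel=1e-6)
        assert x[3] / (K * T) == pytest.approx(4.0 / 1.0, rel=1e-6)
        assert x[4] / (P * T) == pytest.approx(5.0 / 2.0, rel=1e-6)

    def test_steady_state_agrees_with_long_integration(self):
        # Newton-based steady states match the scipy trajectory endpoint
        for rates, totals in random_parameter_sets(25, seed=321):
            model = sc.build_model(rates)
            tot = totals.with_K_total(0.03)
            try:
                ss = sc.steady_state(model, tot)
            except sc.motif_model.ConvergenceError:
                continue
            tc = sc.simulate_timecourse(model, tot, initial_state(tot),
                                        horizon=1e7, n_points=5)
            end = tc.states[-1]
            scale = max(tot.as_array().max(), 1e-30)
            assert np.allclose(ss.as_array(), end, atol=2e-6 * scale), \
                (rates, tot)


class TestTimecourse:
    def test_conservation_along_trajectory(self, random_sets_small):
        for rates, totals in random_sets_small[:8]:
            model = sc.build_model(rates)
            tot = totals.with_K_total(0.05)
            tc = sc.simulate_timecourse(model, tot, initial_state(tot),
                                        horizon=1e4)
            assert tc.max_conservation_residual() < 1e-6
            assert np.all(np.diff(tc.times) > 0)
            assert tc.states.min() >= 0.0

    def test_no_kinase_keeps_substrate_unphosphorylated(self, unit_model):
        tot = sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.2)
        tc = sc.simulate_timecourse(unit_model, tot, initial_state(tot),
                                    horizon=100.0)
        assert np.all(tc.species_trace("Sp") == 0.0)

    def test_no_scaffold_means_no_scaffold_complexes(self, unit_model):
        tot = sc.ConcentrationTotals(1.0, 0.2, 0.1, 0.0)
        tc = sc.simulate_timecourse(unit_model, tot, initial_state(tot),
                                    horizon=100.0)
        assert np.all(tc.species_trace("KT") == 0.0)
        assert np.all(tc.species_trace("PT") == 0.0)

    def test_kinase_events_change_totals_and_conserve(self, unit_model):
        tot = sc.ConcentrationTotals(1.0, 0.01, 0.1, 0.2)
        tc = sc.simulate_timecourse(
            unit_model, tot, initial_state(tot), horizon=30.0,
            events=[(10.0, 0.5), (20.0, 0.01)])
        assert tc.max_conservation_residual() < 1e-6
        k_tot = tc.totals[:, 1]
        assert k_tot.min() == pytest.approx(0.01)
        assert k_tot.max() == pytest.approx(0.5)

    def test_jacobian_consistent_with_rhs(self, unit_model):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, 9)
        J = jacobian(unit_model, y)
        f0 = sc.rhs(unit_model, y)
        eps = 1e-7
        for j in range(9):
            yp = y.copy()
            yp[j] += eps
            col = (sc.rhs(unit_model, yp) - f0) / eps
            assert np.allclose(col, J[:, j], rtol=1e-5, atol=1e-6)


class TestSequestrationFractions:
    def test_full_titration_boundary(self):
        tot = sc.ConcentrationTotals(1.0, 0.2, 0.1, 0.5)
        st_ = sc.SpeciesState(S=1.0, Sp=0.0, K=0.0, P=0.1, T=0.3, SK=0.0,
                              SpP=0.0, KT=0.2, PT=0.0)
        fr = sequestration_fractions(st_, tot)
        assert fr["kinase"] == pytest.approx((0.0, 1.0, 0.0))

    def test_triples_sum_to_one_at_steady_state(self, random_sets_small):
        for rates, totals in random_sets_small[:8]:
            model = sc.build_model(rates)
            tot = totals.with_K_total(0.05)
            ss = sc.steady_state(model, tot)
            fr = sequestration_fractions(ss, tot)
            assert sum(fr["kinase"]) == pytest.approx(1.0, abs=1e-8)
            assert sum(fr["phosphatase"]) == pytest.approx(1.0, abs=1e-8)

    def test_zero_enzyme_total_raises(self, default_totals):
        st_ = initial_state(sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.0))
        with pytest.raises(UndefinedFractionError):
            sequestration_fractions(
                st_, sc.ConcentrationTotals(1.0, 0.0, 0.1, 0.0))


class TestKinaseEvents:
    def test_raising_adds_free_kinase(self, default_totals):
        st_ = initial_state(default_totals)
        new, tot = apply_kinase_change(st_, default_totals, 0.8)
        assert tot.K_total == pytest.approx(0.8)
        assert new.K == pytest.approx(0.8)
        assert np.allclose(new.conservation_residual(tot), 0.0, atol=1e-12)

    def test_proportional_lowering_scales_pools(self):
        tot = sc.ConcentrationTotals(1.0, 0.4, 0.1, 0.5)
        st_ = sc.SpeciesState(S=0.9, Sp=0.0, K=0.2, P=0.1, T=0.4, SK=0.1,
                              SpP=0.0, KT=0.1, PT=0.0)
        new, ntot = apply_kinase_change(st_, tot, 0.2, policy="proportional")
        assert ntot.K_total == pytest.approx(0.2)
        assert new.SK == pytest.approx(0.05)
        assert new.KT == pytest.approx(0.05)
        assert new.K == pytest.approx(0.1)
        assert np.allclose(new.conservation_residual(ntot), 0.0, atol=1e-12)

    def test_free_first_lowering_empties_free_pool(self):
        tot = sc.ConcentrationTotals(1.0, 0.4, 0.1, 0.5)
        st_ = sc.SpeciesState(S=0.9, Sp=0.0, K=0.2, P=0.1, T=0.4, SK=0.1,
                              SpP=0.0, KT=0.1, PT=0.0)
        new, ntot = apply_kinase_change(st_, tot, 0.1)
        assert ntot.K_total == pytest.approx(0.1)
        assert new.K == pytest.approx(0.0, abs=1e-12)
        # shortfall 0.1 removed pro rata from SK and KT (0.1 each)
        assert new.SK == pytest.approx(0.05)
        assert new.KT == pytest.approx(0.05)
        assert np.allclose(new.conservation_residual(ntot), 0.0, atol=1e-12)
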