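"""Core model: resource allocation solvers, ODEs, steady states, rate curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txtlkit as tk
from txtlkit.model import _rnap_conservation_residual

from conftest import bisect_root, ribosome_balance_residual, rnap_balance_residual

pytestmark = pytest.mark.filterwarnings("ignore:simulated mRNA reached")


# ---------------------------------------------------------------------------
# free RNA polymerase
# ---------------------------------------------------------------------------

class TestFreeRNAP:
    def test_no_sigma_leaves_pool_free(self, bestfit):
        p = bestfit.replace(S70_total=1e-12, P70=0.0)
        assert tk.solve_free_rnap(p).E0 == pytest.approx(400.0, abs=1e-6)

    def test_no_template_matches_quadratic(self, bestfit):
        # with P70 = 0 the balance is E0^2 + E0*(S70 + K70 - E_tot) - K70*E_tot = 0
        p = bestfit.replace(P70=0.0)
        b = p.S70_total + p.K70 - p.E_total
        e0_quad = (-b + np.sqrt(b * b + 4 * p.K70 * p.E_total)) / 2
        alloc = tk.solve_free_rnap(p)
        assert alloc.E0 == pytest.approx(e0_quad, rel=1e-12)
        assert alloc.E0 == pytest.approx(370.02, abs=0.01)

    def test_bestfit_at_5nM_matches_bisection_oracle(self, bestfit):
        p = bestfit.replace(P70=5.0)
        oracle = bisect_root(lambda e: rnap_balance_residual(e, p), 0.0, p.E_total, tol=1e-9)
        e0 = tk.solve_free_rnap(p).E0
        assert e0 == pytest.approx(oracle, abs=1e-8)
        assert e0 == pytest.approx(341.596, abs=1e-3)

    def test_allocation_conserves_pools(self, bestfit):
        p = bestfit.replace(P70=5.0)
        a = tk.solve_free_rnap(p)
        assert a.E0 + a.E70 + a.Em == pytest.approx(p.E_total, abs=1e-9)
        assert a.S70_free + a.E70 == pytest.approx(p.S70_total, abs=1e-9)
        assert min(a.E0, a.E70, a.Em, a.S70_free) >= 0

    def test_residual_strictly_increasing_in_E0(self, bestfit):
        p = bestfit.replace(P70=5.0)
        grid = np.linspace(0.0, p.E_total, 200)
        res = np.array([_rnap_conservation_residual(e, p) for e in grid])
        assert np.all(np.diff(res) > 0)

    @given(st.floats(min_value=0.01, max_value=50.0), st.floats(min_value=1.01, max_value=3.0))
    @settings(max_examples=30, deadline=None)
    def test_E0_strictly_decreasing_in_plasmid(self, conc, ratio):
        p = tk.best_fit_parameters()
        lo = tk.solve_free_rnap(p.replace(P70=conc)).E0
        hi = tk.solve_free_rnap(p.replace(P70=conc * ratio)).E0
        assert hi < lo


# ---------------------------------------------------------------------------
# free ribosomes
# ---------------------------------------------------------------------------

class TestFreeRibosomes:
    def test_no_mrna_leaves_pool_free(self, bestfit):
        assert tk.solve_free_ribosomes(bestfit, 0.0).R0 == 1100.0

    def test_exact_quadratic_case(self, bestfit):
        # m chosen so that demand m*(1 + kcat_p*Lm/Cp) equals R_total:
        # discriminant is a perfect square and R0 = 100 exactly
        p = bestfit.replace(kcat_p=6e-3, Lm=750.0, Cp=2.5, KM_R=10.0, R_total=1100.0)
        assert tk.solve_free_ribosomes(p, 1100.0 / 2.8).R0 == pytest.approx(100.0, abs=1e-9)

    def test_closed_form_matches_bisection_on_grid(self, bestfit):
        for m in np.linspace(0.0, 1e4, 150):
            oracle = bisect_root(
                lambda r: ribosome_balance_residual(r, m, bestfit), 0.0, bestfit.R_total
            )
            assert tk.solve_free_ribosomes(bestfit, m).R0 == pytest.approx(oracle, abs=1e-9)

    def test_large_m_limit_and_conservation(self, bestfit):
        prev = bestfit.R_total
        for m in [1e2, 1e4, 1e6, 1e8]:
            a = tk.solve_free_ribosomes(bestfit, m)
            assert 0 <= a.R0 < prev
            assert a.R0 + a.Rm == pytest.approx(bestfit.R_total, abs=1e-9)
            prev = a.R0
        assert prev < 1e-3  # R0 -> 0 as m -> inf

    @given(st.floats(min_value=0.0, max_value=1e4), st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_R0_strictly_decreasing_in_m(self, m, dm):
        p = tk.best_fit_parameters()
        assert tk.solve_free_ribosomes(p, m + dm).R0 < tk.solve_free_ribosomes(p, m).R0

    def test_negative_m_rejected(self, bestfit):
        with pytest.raises(ValueError):
            tk.solve_free_ribosomes(bestfit, -1.0)


# ---------------------------------------------------------------------------
# holoenzyme
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "E0, expected",
    [
        (0.0, 0.0),
        (0.26, 15.0),  # E0 = K70 -> half the sigma pool
        (26.0, pytest.approx(30.0, rel=0.01)),  # E0 = 100*K70 -> saturation
    ],
)
def test_holoenzyme_limits(bestfit, E0, expected):
    assert tk.holoenzyme(E0, bestfit) == expected


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

class TestRHS:
    def test_all_zero_without_template(self, bestfit):
        p = bestfit.replace(P70=0.0)
        state = tk.ModelState(0.0, 0.0, 0.0)
        alloc = tk.model.allocate_resources(p, 0.0)
        d = tk.ode_rhs(state, p, alloc)
        assert (d.m, d.deGFP_dark, d.deGFP_mat) == (0.0, 0.0, 0.0)

    def test_linear_mrna_growth_without_decay_or_translation(self, bestfit):
        p = bestfit.replace(kd_m=1e-30, kcat_p=1e-30, P70=1.0)
        alloc = tk.model.allocate_resources(p, 0.0)
        ktx = tk.transcription_initiation_rate(p, alloc.E0)
        for m in [0.0, 10.0, 200.0]:
            d = tk.ode_rhs(tk.ModelState(m, 0.0, 0.0), p, tk.model.allocate_resources(p, m))
            assert d.m == pytest.approx(ktx * p.P70, rel=1e-12)

    def test_steady_state_is_fixed_point(self, bestfit):
        p = bestfit.replace(P70=1.0)
        m_ss = tk.model.steady_state_mrna_exact(p)
        d = tk.ode_rhs(tk.ModelState(m_ss, 0.0, 0.0), p, tk.model.allocate_resources(p, m_ss))
        assert abs(d.m) <= 1e-9


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class TestSimulation:
    def test_no_template_gives_zero_trace(self, bestfit):
        tr = tk.simulate_kinetics(bestfit.replace(P70=0.0), t_end=3600.0)
        assert np.all(tr.m == 0) and np.all(tr.deGFP_mat == 0)

    def test_late_slope_matches_analytic_linear_rate(self, bestfit):
        p = bestfit.replace(P70=1.0)
        tr = tk.simulate_kinetics(p, t_end=4 * 3600.0)
        sel = (tr.times >= 2 * 3600) & (tr.times <= 4 * 3600)
        slope = np.polyfit(tr.times[sel], tr.deGFP_mat[sel], 1)[0]
        assert slope == pytest.approx(tk.linear_regime_protein_rate(p), rel=0.05)

    def test_maturation_rate_does_not_change_total_protein(self, bestfit):
        p = bestfit.replace(P70=1.0)
        tr1 = tk.simulate_kinetics(p, t_end=2 * 3600.0)
        tr2 = tk.simulate_kinetics(p.replace(k_mat=2 * p.k_mat), t_end=2 * 3600.0)
        assert np.allclose(tr1.total_protein, tr2.total_protein, rtol=1e-6, atol=1e-6)

    def test_states_nonnegative_and_total_protein_monotone(self, bestfit):
        tr = tk.simulate_kinetics(bestfit.replace(P70=5.0), t_end=4 * 3600.0)
        for arr in (tr.m, tr.deGFP_dark, tr.deGFP_mat):
            assert np.all(arr >= 0)
        assert np.all(np.diff(tr.total_protein) >= -1e-9)

    def test_conservation_along_trajectory(self, bestfit):
        p = bestfit.replace(P70=5.0)
        tr = tk.simulate_kinetics(p, t_end=4 * 3600.0)
        assert abs(rnap_balance_residual(tr.E0, p)) <= 1e-6
        for m, r0 in zip(tr.m, tr.R0):
            assert abs(ribosome_balance_residual(r0, m, p)) <= 1e-6

    def test_high_mrna_triggers_KMm_warning(self, bestfit):
        with pytest.warns(UserWarning, match="KM_m"):
            tk.simulate_kinetics(bestfit.replace(P70=30.0), t_end=4 * 3600.0)

    def test_invalid_duration_rejected(self, bestfit):
        with pytest.raises(ValueError):
            tk.simulate_kinetics(bestfit, t_end=-1.0)


# ---------------------------------------------------------------------------
# steady-state relations
# ---------------------------------------------------------------------------

class TestSteadyState:
    def test_mrna_zero_without_template(self, bestfit):
        assert tk.mrna_steady_state(bestfit.replace(P70=0.0)) == 0.0

    def test_mrna_level_bestfit_regime(self, bestfit):
        # in the reservoir regime (holoenzyme >> KM_70) the steady state is
        # kcat_m/kdeg_m * P70 = 78.8 nM at 1 nM plasmid (quoted as ~80)
        p = bestfit.replace(P70=1.0, KM_70=1e-9)
        assert tk.mrna_steady_state(p) == pytest.approx(78.79, abs=0.05)
        # the full model (KM_70 = 1 nM) sits a few percent below
        assert tk.mrna_steady_state(bestfit.replace(P70=1.0)) == pytest.approx(78.79, rel=0.05)

    def test_mrna_theoretical_ceiling(self, bestfit):
        p = bestfit.replace(P70=1.0, kcat_m=0.5, KM_70=1e-9)
        assert tk.mrna_steady_state(p) == pytest.approx(606.1, abs=0.5)

    @pytest.mark.parametrize(
        "changes, expected",
        [
            ({"P70": 1.0}, 0.4727),
            ({"P70": 0.0}, 0.0),
            ({"P70": 1.0, "kcat_m": 0.5, "kcat_p": 0.5}, 303.0),
        ],
    )
    def test_linear_regime_rate(self, bestfit, changes, expected):
        assert tk.linear_regime_protein_rate(bestfit.replace(**changes)) == pytest.approx(
            expected, rel=1e-3
        )

    def test_linearity_limit_rate_doubles_with_plasmid(self, bestfit):
        r1 = tk.steady_state_rate(bestfit.replace(P70=0.05))
        r2 = tk.steady_state_rate(bestfit.replace(P70=0.10))
        assert r2 / r1 == pytest.approx(2.0, rel=0.01)

    def test_saturation_onset_in_expected_window(self, bestfit):
        # plasmid level where ribosome demand m_ss*(1+kcat_p*Lm/Cp) crosses R_total
        from scipy.optimize import brentq

        onset = brentq(
            lambda c: tk.mrna_steady_state(bestfit.replace(P70=c)) * bestfit.tl_occupancy
            - bestfit.R_total,
            1.0,
            20.0,
        )
        assert 4.0 <= onset <= 7.0


# ---------------------------------------------------------------------------
# rate extraction
# ---------------------------------------------------------------------------

class TestMaxRate:
    def test_linear_trace_returns_slope(self):
        t = np.arange(0.0, 4 * 3600.0, 180.0)
        tr = tk.KineticsTrace(times=t, m=np.zeros_like(t), deGFP_dark=np.zeros_like(t),
                              deGFP_mat=0.3 * t)
        assert tk.max_synthesis_rate(tr) == pytest.approx(0.3, rel=1e-9)

    def test_slope_then_plateau_returns_slope(self):
        t = np.arange(0.0, 4 * 3600.0, 180.0)
        y = np.minimum(0.2 * t, 0.2 * 7200.0)
        tr = tk.KineticsTrace(times=t, m=np.zeros_like(t), deGFP_dark=np.zeros_like(t),
                              deGFP_mat=y)
        assert tk.max_synthesis_rate(tr) == pytest.approx(0.2, rel=1e-9)

    def test_simulated_rate_crosschecks_analytic(self, bestfit):
        p = bestfit.replace(P70=1.0)
        tr = tk.simulate_kinetics(p, t_end=4 * 3600.0)
        assert tk.max_synthesis_rate(tr) == pytest.approx(
            tk.linear_regime_protein_rate(p), rel=0.05
        )

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 1800.0, 180.0)
        tr = tk.KineticsTrace(times=t, m=np.zeros_like(t), deGFP_dark=np.zeros_like(t),
                              deGFP_mat=t)
        with pytest.raises(ValueError):
            tk.max_synthesis_rate(tr)


class TestRateCurve:
    def test_zero_only_grid(self, bestfit):
        rc = tk.rate_vs_plasmid(bestfit, [0.0])
        assert rc.max_rates[0] == 0.0 and rc.regime_labels[0] == "linear"

    def test_low_concentrations_collinear_through_origin(self, bestfit):
        rc = tk.rate_vs_plasmid(bestfit, [0.5, 1.0, 2.0])
        ratios = rc.max_rates / rc.plasmid_concs
        assert ratios.max() / ratios.min() <= 1.10
        assert all(lbl == "linear" for lbl in rc.regime_labels)

    def test_weak_parts_never_saturate(self, bestfit):
        weak = bestfit.replace(kcat_m=bestfit.kcat_m / 10, kcat_p=bestfit.kcat_p / 10)
        rc = tk.rate_vs_plasmid(weak, [0.5, 2.0, 10.0, 30.0])
        assert all(lbl == "linear" for lbl in rc.regime_labels)

    def test_bestfit_curve_saturates_and_is_monotone(self, bestfit):
        rc = tk.rate_vs_plasmid(bestfit, [0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0])
        assert np.all(np.diff(rc.max_rates) >= -1e-12)
        assert rc.regime_labels[-1] == "saturated"
        assert rc.slope_linear == pytest.approx(tk.steady_state_rate(bestfit.replace(P70=1.0)),
                                                rel=0.10)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

class TestParameters:
    def test_negative_parameter_rejected(self):
        with pytest.raises(Exception):
            tk.TXTLParameters(kcat_m=-1.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(Exception):
            tk.TXTLParameters(kcat_x=1.0)

    def test_excess_kcat_warns(self, bestfit):
        with pytest.warns(tk.params.RateLimitWarning):
            bestfit.replace(kcat_m=0.6)

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            tk.KineticsTrace(times=[0.0, 1.0], m=[0.0], deGFP_dark=[0.0, 0.0],
                             deGFP_mat=[0.0, 0.0])
        with pytest.raises(ValueError):
            tk.KineticsTrace(times=[1.0, 2.0], m=[0.0, 0.0], deGFP_dark=[0.0, 0.0],
                             deGFP_mat=[0.0, 0.0])
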