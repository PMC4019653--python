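import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import bisect

from cdkcycle import (
    NonCyclingError,
    ResetSpec,
    Trajectory,
    default_initial_state,
    default_parameters,
    goldbeter_koshland,
    rhs,
    simulate,
    simulate_cycles,
)
from cdkcycle.model import _rhs_compiled
from cdkcycle.species import (
    ACTIVE_TOTAL_PAIRS,
    N_SPECIES,
    RB_MOIETY,
    SPECIES_INDEX,
    SPECIES_NAMES,
)


# ---------------------------------------------------------------- GK switch

class TestGoldbeterKoshland:
    def test_symmetric_rates_give_half(self):
        assert goldbeter_koshland(1.0, 1.0, 0.01, 0.01) == pytest.approx(0.5)

    def test_no_activation_gives_zero(self):
        assert goldbeter_koshland(0.0, 0.7, 0.01, 0.02) == 0.0

    def test_matches_bisection_root_of_balance_equation(self):
        va, vi, Ja, Ji = 2.0, 1.0, 0.05, 0.05
        root = bisect(lambda f: va * (1 - f) / (Ja + 1 - f) - vi * f / (Ji + f),
                      1e-12, 1 - 1e-12, xtol=1e-14)
        assert goldbeter_koshland(va, vi, Ja, Ji) == pytest.approx(root, abs=1e-12)
        assert root == pytest.approx(0.9547405025104254, abs=1e-12)

    @given(va=st.floats(0.01, 50), vi=st.floats(0.01, 50),
           J=st.floats(1e-4, 1.0))
    def test_fraction_in_unit_interval_and_monotone_in_activation(self, va, vi, J):
        f = goldbeter_koshland(va, vi, J, J)
        assert 0.0 <= f <= 1.0
        assert goldbeter_koshland(va * 1.5, vi, J, J) >= f - 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            goldbeter_koshland(-1.0, 1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            goldbeter_koshland(1.0, 1.0, 0.0, 0.1)


# ---------------------------------------------------------------- rhs

class TestRhs:
    def test_output_dimension_is_25(self, params):
        d = rhs(0.0, default_initial_state(), params)
        assert d.shape == (25,)
        assert N_SPECIES == 25

    def test_zero_species_have_nonnegative_derivative(self, params):
        # forward invariance of the nonnegative orthant: mass-action removal
        # terms vanish at zero while synthesis terms remain >= 0
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.uniform(0.0, 1.0, N_SPECIES)
            zero = rng.integers(0, N_SPECIES, size=5)
            y[zero] = 0.0
            d = rhs(0.0, y, params)
            assert np.all(d[zero] >= -1e-12)

    def test_wrong_dimension_rejected(self, params):
        with pytest.raises(ValueError, match="25"):
            rhs(0.0, np.zeros(24), params)

    def test_nan_state_rejected(self, params):
        y = default_initial_state()
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rhs(0.0, y, params)

    def test_finite_difference_consistency_along_trajectory(self, params):
        # central differences of a finely resolved trajectory reproduce the
        # vector field (smooth mid-S window)
        tr = simulate(params, t_span=(0.40, 0.41), n_out=2001)
        t, Y = tr.times, tr.states
        fd = (Y[2:] - Y[:-2]) / (t[2] - t[0])
        for i in range(1, len(t) - 1, 50):
            d = rhs(t[i], Y[i], params)
            denom = np.maximum(np.abs(d), 1e-3 * np.abs(d).max())
            assert np.max(np.abs(fd[i - 1] - d) / denom) < 1e-4


# ---------------------------------------------------------------- simulate

class TestSimulate:
    def test_zero_length_span_returns_init_exactly(self, params):
        y0 = default_initial_state()
        tr = simulate(params, y0, t_span=(0.3, 0.3))
        assert len(tr) == 1
        np.testing.assert_array_equal(tr.states[0], y0)

    def test_total_cyclin_a_delayed_through_early_cycle(self, params, wt1):
        from cdkcycle.observables import observable_series

        a = observable_series(wt1, "cyclinA_total")
        period = wt1.periods[0]
        early = wt1.times <= 0.15 * period
        assert np.all(a.values[early] < 0.05 * a.values.max())

    def test_agreement_with_fixed_step_rk4_oracle(self, params):
        # classical RK4 at step 1e-5 of a cycle over the first 10%
        y = default_initial_state().copy()
        p = params.to_array()
        h = 1e-5
        for i in range(10_000):
            t = i * h
            k1 = _rhs_compiled(t, y, p)
            k2 = _rhs_compiled(t + h / 2, y + h / 2 * k1, p)
            k3 = _rhs_compiled(t + h / 2, y + h / 2 * k2, p)
            k4 = _rhs_compiled(t + h, y + h * k3, p)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        tr = simulate(params, t_span=(0.0, 0.1), n_out=11)
        scale = np.abs(y).max()
        rel = np.abs(tr.states[-1] - y) / np.maximum(np.abs(y), 1e-3 * scale)
        assert rel.max() < 1e-6

    def test_tolerance_refinement_changes_solution_below_0p1_percent(self, params):
        tr1 = simulate(params, t_span=(0.0, 0.9), n_out=10)
        tr2 = simulate(params, t_span=(0.0, 0.9), n_out=10,
                       rtol=params.rtol / 10, atol=params.atol / 10)
        scale = np.abs(tr2.states).max()
        rel = np.abs(tr1.states - tr2.states) / np.maximum(np.abs(tr2.states),
                                                           1e-3 * scale)
        assert rel.max() < 1e-3

    def test_nonnegativity_under_parameter_perturbations(self, params):
        # +/-20% multiplicative draws around the defaults keep every state
        # component nonnegative at all output times
        rng = np.random.default_rng(11)
        from cdkcycle.params import PARAM_NAMES

        for _ in range(3):
            factors = rng.uniform(0.8, 1.2, len(PARAM_NAMES))
            p = params.with_overrides(
                {n: params[n] * f for n, f in zip(PARAM_NAMES, factors)})
            tr = simulate(p, t_span=(0.0, 1.0), n_out=201)
            assert tr.states.min() >= -p.atol


# ---------------------------------------------------------------- cycles

class TestSimulateCycles:
    def test_three_cycles_give_three_cyclin_b_peaks(self, wt3):
        from scipy.signal import find_peaks

        b = wt3.species("CycB")
        peaks, _ = find_peaks(b, prominence=0.5 * b.max())
        assert len(peaks) == 3
        assert len(wt3.division_times) == 3

    def test_single_cycle_matches_plain_simulation(self, params, wt1):
        period = wt1.periods[0]
        tr = simulate(params, t_span=(0.0, period), n_out=501)
        for name in ("CycB", "CycA2", "Cdh1"):
            a = np.interp(tr.times, wt1.times, wt1.species(name))
            scale = np.abs(tr.species(name)).max()
            assert np.allclose(tr.species(name), a, atol=5e-3 * scale)

    def test_periods_of_cycles_2_and_3_agree_within_1_percent(self, wt3):
        p2, p3 = wt3.periods[1], wt3.periods[2]
        assert abs(p3 - p2) / p2 < 0.01

    def test_cyclin_b_peak_amplitude_stable_between_cycles(self, wt3):
        b = wt3.species("CycB")
        bounds = [0.0] + wt3.division_times
        amps = []
        for c0, c1 in zip(bounds[1:-1], bounds[2:]):
            sel = (wt3.times >= c0) & (wt3.times <= c1)
            amps.append(b[sel].max())
        assert abs(amps[1] - amps[0]) / amps[0] < 0.02

    def test_reset_variables_restored_at_division(self, wt3):
        # the sample at the division event carries the pre-reset state; the
        # first sample of the next cycle starts from the reset values (DRG
        # and the cyclin D pools drop back to their start-of-cycle levels)
        reset = ResetSpec.default()
        i = int(np.searchsorted(wt3.times, wt3.division_times[0]))
        dt = wt3.times[i + 1] - wt3.times[i]
        assert wt3.states[i, SPECIES_INDEX["DRG"]] > 0.5  # high before division
        for name, value in reset.resets.items():
            post = wt3.states[i + 1, SPECIES_INDEX[name]]
            assert post == pytest.approx(value, abs=60.0 * dt)

    def test_non_cycling_parameters_raise(self, params):
        # removing cyclin B synthesis entirely prevents mitosis
        dead = params.with_overrides({"k_sb_basal": 0.0, "k_sb_e2f": 0.0,
                                      "k_sb_ab": 0.0, "k_sb_b": 0.0})
        with pytest.raises(NonCyclingError):
            simulate_cycles(dead, n_cycles=1, horizon_factor=3.0)

    def test_reset_spec_validates_names_and_values(self):
        with pytest.raises(ValueError, match="NotASpecies"):
            ResetSpec({"NotASpecies": 0.0})
        with pytest.raises(ValueError):
            ResetSpec({"DRG": -1.0})


# ---------------------------------------------------------------- invariants

class TestInvariants:
    def test_rb_moiety_conserved(self, wt3):
        total = sum(wt3.species(n) for n in RB_MOIETY)
        assert (total.max() - total.min()) / total.mean() < 1e-6

    def test_active_pools_do_not_exceed_totals(self, wt3):
        for active, tot in ACTIVE_TOTAL_PAIRS:
            slack = 1e-6 * wt3.species(tot).max()
            assert np.all(wt3.species(active) <= wt3.species(tot) + slack)

    def test_trajectory_requires_strictly_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(np.array([0.0, 0.0]), np.zeros((2, N_SPECIES)))

    def test_staggered_degradation_in_every_cycle(self, wt3):
        from cdkcycle.observables import observable_series

        a = observable_series(wt3, "cyclinA_total").values
        b = observable_series(wt3, "cyclinB_total").values
        bounds = [0.0] + wt3.division_times
        for c0, c1 in zip(bounds[:-1], bounds[1:]):
            sel = (wt3.times >= c0) & (wt3.times <= c1)
            t = wt3.times[sel]

            def half_decay(x):
                ip = int(np.argmax(x))
                below = np.nonzero(x[ip:] < 0.5 * x[ip])[0]
                return t[ip + below[0]]

            assert half_decay(a[sel]) < half_decay(b[sel])

    def test_abrupt_mitotic_switch(self, wt1):
        act = wt1.species("actCycB")
        period = wt1.periods[0]
        norm = (act - act.min()) / (act.max() - act.min())
        t10 = wt1.times[np.nonzero(norm > 0.1)[0][0]]
        t90 = wt1.times[np.nonzero(norm > 0.9)[0][0]]
        assert (t90 - t10) / period <= 0.05
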