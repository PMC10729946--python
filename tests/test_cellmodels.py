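"""Single-cell electrophysiology and ChR2 photocycle unit tests."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from optospiral.cellmodels import (
    CHR2_ZERO_CROSSING_MV,
    ChR2Params,
    ChR2State,
    IonicParams,
    IonicState,
    chr2_equilibrium,
    chr2_photocurrent,
    chr2_step,
    ionic_step,
    resting_state,
    simulate_cell,
)
from optospiral.errors import InvalidStateError


class TestChR2Photocurrent:
    @pytest.mark.parametrize("vm,o1,expected_per_g", [
        # closed channel carries no current at any voltage
        (-80.0, 0.0, 0.0),
        # V = 0 limit of the rectification product: 10.6408 - 14.6408 = -4
        (0.0, 1.0, -4.0),
        # fully open at rest: strongly inward
        (-80.0, 1.0, -84.41),
        # depolarized: weakly outward
        (40.0, 1.0, 4.894),
    ])
    def test_known_values(self, vm, o1, expected_per_g):
        p = ChR2Params(g_chr2=1.0)
        i = chr2_photocurrent(vm, ChR2State(o1=o1, c1=1.0 - o1), p)
        assert i == pytest.approx(expected_per_g, abs=5e-3)

    def test_scales_with_conductance_and_gamma(self):
        p1 = ChR2Params(g_chr2=0.3, gamma=0.1)
        s = ChR2State(o1=0.2, o2=0.5, c1=0.3, c2=0.0)
        i = chr2_photocurrent(-60.0, s, p1)
        s_eq = ChR2State(o1=0.2 + 0.1 * 0.5, c1=1.0 - 0.25, c2=0.0)
        assert i == pytest.approx(chr2_photocurrent(-60.0, s_eq, p1), rel=1e-12)

    def test_rectification_zero_crossing(self):
        """The current reverses sign at 42.7671 ln(14.6408/10.6408) mV."""
        p = ChR2Params(g_chr2=1.0)
        s = ChR2State(o1=1.0, c1=0.0)
        assert CHR2_ZERO_CROSSING_MV == pytest.approx(13.65, abs=0.01)
        assert chr2_photocurrent(CHR2_ZERO_CROSSING_MV - 0.5, s, p) < 0
        assert chr2_photocurrent(CHR2_ZERO_CROSSING_MV + 0.5, s, p) > 0
        # inward (depolarizing) for any vm <= 0 with open channel
        for vm in (-100.0, -40.0, 0.0):
            assert chr2_photocurrent(vm, s, p) < 0

    def test_invalid_state_rejected(self):
        p = ChR2Params()
        with pytest.raises(InvalidStateError):
            chr2_photocurrent(np.nan, ChR2State(), p)
        with pytest.raises(InvalidStateError):
            chr2_photocurrent(-80.0, ChR2State(o1=0.8, c1=0.8), p)


class TestPhotocycle:
    def test_dark_adapted_fixed_point(self):
        p = ChR2Params()
        s = ChR2State()
        for _ in range(100):
            s = chr2_step(s, 0.0, 0.5, p)
        assert s.c1 == pytest.approx(1.0, abs=1e-12)
        assert s.o1 == 0.0 and s.o2 == 0.0 and s.c2 == 0.0

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            chr2_step(ChR2State(), -1.0, 0.01, ChR2Params())

    def test_occupancy_conservation_long_run(self):
        """Sum of occupancies deviates from 1 by < 1e-6 over 1e5 steps."""
        p = ChR2Params()
        s = ChR2State()
        for k in range(100_000):
            s = chr2_step(s, 30.0, 0.01, p)
        total = s.o1 + s.o2 + s.c1 + s.c2
        assert abs(total - 1.0) < 1e-6
        s.validate(atol=1e-6)

    def test_matrix_exponential_oracle(self):
        """Stepped kinetics match expm(Q t) @ p0 at fixed irradiance."""
        p = ChR2Params()
        q = p.rate_matrix(30.0)
        p0 = np.array([1.0, 0.0, 0.0, 0.0])  # (c1, o1, o2, c2)
        t_end = 50.0
        exact = expm(q * t_end) @ p0
        s = ChR2State()
        for _ in range(int(t_end / 0.01)):
            s = chr2_step(s, 30.0, 0.01, p)
        stepped = np.array([s.c1, s.o1, s.o2, s.c2])
        np.testing.assert_allclose(stepped, exact, atol=2e-4)

    def test_equilibrium_matches_null_space(self):
        """Long-time occupancies converge to the rate-matrix null space."""
        p = ChR2Params()
        eq = chr2_equilibrium(30.0, p)
        s = ChR2State()
        for _ in range(600_000):           # 60 s at dt = 0.1 ms
            s = chr2_step(s, 30.0, 0.1, p)
        stepped = np.array([s.c1, s.o1, s.o2, s.c2])
        np.testing.assert_allclose(stepped, eq, atol=1e-6)
        # activation rates non-decreasing in irradiance
        q1, q2 = p.rate_matrix(10.0), p.rate_matrix(40.0)
        assert q2[1, 0] >= q1[1, 0] and q2[2, 3] >= q1[2, 3]

    def test_peak_then_plateau_under_strong_light(self):
        """Constant light: open fraction peaks early, then sags to a plateau."""
        p = ChR2Params()
        s = ChR2State()
        of = []
        for _ in range(50_000):
            s = chr2_step(s, 1000.0, 0.01, p)
            of.append(s.o1 + p.gamma * s.o2)
        of = np.array(of)
        assert np.argmax(of) * 0.01 < 50.0
        assert of.max() > 1.5 * of[-1]


class TestIonicModel:
    def test_resting_stability(self):
        """Without stimulus or light the cell stays at rest (< 0.5 mV/100 ms)."""
        _, vm, _, _ = simulate_cell(100.0)
        assert abs(vm[-1] - vm[0]) < 0.5

    def test_action_potential_elicited(self):
        """A 1-ms supra-threshold current injection fires a full AP."""
        ts, vm, _, _ = simulate_cell(
            120.0, i_ext_fn=lambda t: 80.0 if 1.0 <= t < 2.0 else 0.0)
        assert vm.max() > 0.0
        assert vm[-1] < -70.0

    def test_dt_refinement_activation_time(self):
        """Halving dt moves the AP activation marker (interpolated -20 mV
        upstroke crossing) by < 1%."""
        stim = lambda t: 40.0 if 1.0 <= t < 1.5 else 0.0

        def activation(dt):
            ts, vm, _, _ = simulate_cell(20.0, dt=dt, i_ext_fn=stim,
                                         record_every=0.01)
            i = np.nonzero((vm[1:] >= -20) & (vm[:-1] < -20))[0][0]
            frac = (-20 - vm[i]) / (vm[i + 1] - vm[i])
            return ts[i] + frac * (ts[i + 1] - ts[i])

        a1, a2 = activation(0.01), activation(0.005)
        assert abs(a1 - a2) / a1 < 0.01

    def test_ionic_step_contract(self):
        p = IonicParams()
        s = resting_state(p)
        s2 = ionic_step(s, 0.0, 0.01, p)
        assert abs(s2.vm - p.v_rest) < 1e-6
        for g in s2.gates.values():
            assert 0.0 <= g <= 1.0
        with pytest.raises(ValueError):
            ionic_step(s, 0.0, 1.0, p)   # beyond the stability bound
        bad = IonicState(vm=-80.0, gates={"v": 1.5, "w": 1.0})
        with pytest.raises(InvalidStateError):
            ionic_step(bad, 0.0, 0.01, p)

    def test_optical_subthreshold_vs_suprathreshold(self):
        """500-ms light at 10 and 20 µW/mm² stays sub-threshold; 25 fires.

        This is the calibration constraint tying g_chr2 to the régime
        boundary between sub- and supra-threshold illumination.
        """
        for li, fires in ((10.0, False), (20.0, False), (25.0, True)):
            _, vm, _, _ = simulate_cell(600.0, irradiance=li,
                                        light_window=(0.0, 500.0))
            assert (vm.max() > 0.0) == fires, f"LI={li}"

    def test_subthreshold_light_current_is_inward(self):
        _, vm, ich, _ = simulate_cell(300.0, irradiance=10.0,
                                      light_window=(0.0, 300.0))
        assert ich.min() < -0.5          # inward photocurrent flows
        assert -80.0 < vm.max() < -70.0  # bounded sub-threshold elevation
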