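"""Monodomain solver unit and property tests."""

import numpy as np
import pytest

from optospiral.cellmodels import IonicParams
from optospiral.errors import PropagationFailureError, SpiralInitError, StabilityError
from optospiral.tissue import (
    LightPulse,
    Stimulus,
    TissueParams,
    TissueState,
    init_spiral,
    integrate,
    laplacian,
    make_ensemble,
    measure_cv,
    spiral_period,
)


class TestLaplacian:
    def setup_method(self):
        self.p = TissueParams(nx=20, ny=16)

    def test_uniform_field_is_zero(self):
        f = np.full((16, 20), -80.0)
        assert np.all(laplacian(f, self.p) == 0.0)

    def test_linear_ramp_interior_zero(self):
        x = np.arange(20, dtype=float)
        f = np.tile(x, (16, 1))
        lap = laplacian(f, self.p)
        # interior columns are exactly zero; the edge columns carry the
        # mirrored ghost-node correction of the no-flux boundary
        assert np.all(lap[:, 1:-1] == 0.0)
        assert np.all(lap[:, 0] > 0.0) and np.all(lap[:, -1] < 0.0)

    def test_delta_stencil(self):
        f = np.zeros((16, 20))
        h = 3.0
        f[8, 10] = h
        lap = laplacian(f, self.p)
        inv2 = 1.0 / self.p.dx ** 2
        assert lap[8, 10] == pytest.approx(-4 * h * inv2)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert lap[8 + di, 10 + dj] == pytest.approx(h * inv2)

    def test_no_flux_conservation(self):
        rng = np.random.default_rng(7)
        f = rng.normal(-60.0, 25.0, (16, 20))
        lap = laplacian(f, self.p)
        assert abs(lap.sum()) < 1e-9 * f.size / self.p.dx ** 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros((5, 5)), self.p)


class TestIntegrate:
    def test_quiescent_tissue_stays_at_rest(self):
        p = TissueParams(nx=30, ny=30)
        st = TissueState.resting(p)
        rec = integrate(st, p, duration=100.0, frame_interval=10.0)
        assert np.max(np.abs(rec.frames[-1] - rec.frames[0])) < 0.5

    def test_bitwise_determinism(self):
        p = TissueParams(nx=30, ny=30)
        stim = Stimulus(amp=80.0, t_on=1.0, duration=1.0, rows=(0, 30), cols=(0, 3))
        recs = []
        for _ in range(2):
            st = TissueState.resting(p)
            recs.append(integrate(st, p, stimuli=[stim], duration=30.0,
                                  frame_interval=1.0))
        assert np.array_equal(recs[0].frames, recs[1].frames)
        assert np.array_equal(recs[0].probes["p0"], recs[1].probes["p0"])

    def test_stability_guard(self):
        with pytest.raises(StabilityError):
            TissueParams(dt=2.0).validate()
        with pytest.raises(StabilityError):
            integrate(TissueState.resting(TissueParams(dt=2.0)),
                      TissueParams(dt=2.0), duration=1.0)

    def test_probe_sampling_interval_capped(self):
        p = TissueParams(nx=20, ny=20)
        with pytest.raises(ValueError):
            integrate(TissueState.resting(p), p, duration=5.0, probe_interval=2.0)

    def test_global_light_depolarizes_quiescent_tissue(self):
        """A supra-threshold global pulse excites the resting sheet."""
        p = TissueParams(nx=30, ny=30)
        st = TissueState.resting(p)
        pulse = LightPulse(li=30.0, pl=500.0, t_on=5.0)
        rec = integrate(st, p, pulses=[pulse], duration=520.0, frame_interval=5.0)
        assert rec.frames.min(axis=(1, 2)).max() > -55.0


class TestConductionVelocity:
    def test_vanishing_coupling_blocks_propagation(self):
        with pytest.raises(PropagationFailureError):
            measure_cv(params=TissueParams(d_coeff=1e-6))


class TestSpiral:
    def test_settled_state_carries_one_singularity(self, settled_spiral,
                                                   tissue_params, spiral_recording):
        from collections import Counter

        from optospiral.analysis import tip_trajectory

        tips = tip_trajectory(spiral_recording)
        per_frame = Counter(t for t, _, _ in tips)
        counts = np.array([per_frame.get(t, 0)
                           for t in spiral_recording.frame_times[:-1]])
        assert np.mean(counts == 1) > 0.9
        # the rotor's core sits interior to the domain
        xs = [x for _, x, _ in tips]
        ys = [y for _, _, y in tips]
        assert 2.0 < np.median(xs) < 23.0 and 2.0 < np.median(ys) < 23.0

    def test_failed_initiation_raises(self, tissue_params):
        with pytest.raises(SpiralInitError):
            init_spiral(tissue_params, settle_time=150.0, s1_transit=2.0)

    def test_ensemble_phases(self, settled_spiral, tissue_params):
        base = settled_spiral
        single = make_ensemble(base, tissue_params, n=1)
        assert len(single) == 1
        assert np.array_equal(single[0].vm, base.vm)
        with pytest.raises(ValueError):
            make_ensemble(base, tissue_params, n=0)
        members = make_ensemble(base, tissue_params, n=4, period=28.75)
        assert len(members) == 4
        for a in range(4):
            for b in range(a + 1, 4):
                assert not np.array_equal(members[a].vm, members[b].vm)

    def test_ensemble_members_sustain_the_arrhythmia(self, settled_spiral,
                                                     tissue_params):
        """Unlit ensemble members keep rotating (control persistence)."""
        members = make_ensemble(settled_spiral, tissue_params, n=3, period=28.75)
        for m in members:
            rec = integrate(m, tissue_params, duration=300.0, frame_interval=50.0)
            assert rec.frames[-1].max() > -60.0
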