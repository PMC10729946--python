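"""2D monodomain tissue simulator.

Solves

    dV/dt = div(D grad V) - (I_ion + I_ChR2)/C_m

on a regular nx × ny lattice (default 100 × 100 nodes, 0.25 mm spacing,
i.e. a 25 mm × 25 mm sheet) with no-flux (mirrored ghost node) boundaries,
explicit forward time stepping and Rush–Larsen gate updates.  Illumination
is global and uniform; local current stimuli are applied to node rectangles.
The solver is fully deterministic: identical configuration yields bitwise
identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from . import cellmodels as cm
from .errors import (
    IntegrationError,
    PropagationFailureError,
    SpiralInitError,
    StabilityError,
)

#: documented reaction-kinetics bound on dt (ms); the diffusion bound
#: dx²/(4 D) is checked separately per configuration.
DT_MAX_REACTION_MS = cm.DT_MAX_MS


@dataclass(frozen=True)
class TissueParams:
    """Geometry, coupling and time step of the monodomain sheet.

    ``dx`` is in cm (0.025 cm = 0.25 mm); ``d_coeff`` in cm²/ms; ``dt`` in ms.
    Node (i, j) sits at x = j·dx, y = i·dx (0-based).
    """

    nx: int = 100
    ny: int = 100
    dx: float = 0.025
    d_coeff: float = 0.00014
    c_m: float = 1.0
    dt: float = 0.01

    @property
    def dx_mm(self) -> float:
        return self.dx * 10.0

    @property
    def size_mm(self) -> tuple[float, float]:
        return (self.nx * self.dx_mm, self.ny * self.dx_mm)

    def dt_max(self) -> float:
        """Stability bound: min of the diffusion CFL and the reaction bound."""
        return min(self.dx ** 2 / (4.0 * self.d_coeff), DT_MAX_REACTION_MS)

    def validate(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3 x 3")
        if self.dt <= 0 or self.dt >= self.dt_max():
            raise StabilityError(
                f"dt = {self.dt} ms violates the stability bound "
                f"dt < {self.dt_max():.4g} ms (diffusion dx^2/4D and reaction limits)"
            )


@dataclass(frozen=True)
class LightPulse:
    """Global uniform illumination: irradiance ``li`` (µW/mm²) on during
    [t_on, t_on + pl)."""

    li: float
    pl: float
    t_on: float = 0.0
    spatial_mode: str = "global-uniform"

    def __post_init__(self):
        if self.li < 0:
            raise ValueError("irradiance must be non-negative")
        if self.pl <= 0:
            raise ValueError("pulse length must be positive")
        if self.spatial_mode != "global-uniform":
            raise ValueError("only global-uniform illumination is supported")


@dataclass(frozen=True)
class Stimulus:
    """Local depolarizing current (µA/cm², positive inward-depolarizing)
    applied to the node rectangle rows [r0, r1) × cols [c0, c1) during
    [t_on, t_on + duration)."""

    amp: float
    t_on: float
    duration: float
    rows: tuple[int, int]
    cols: tuple[int, int]


@dataclass
class TissueState:
    """Lattice of per-node cell state advanced by the solver."""

    vm: np.ndarray
    v: np.ndarray
    w: np.ndarray
    o1: np.ndarray
    o2: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    t: float = 0.0

    @classmethod
    def resting(cls, params: TissueParams, ionic: cm.IonicParams | None = None) -> "TissueState":
        p = ionic or cm.IonicParams()
        shape = (params.ny, params.nx)
        return cls(
            vm=np.full(shape, p.v_rest),
            v=np.full(shape, p.v_inf(0.0)),
            w=np.ones(shape),
            o1=np.zeros(shape),
            o2=np.zeros(shape),
            c1=np.ones(shape),
            c2=np.zeros(shape),
            t=0.0,
        )

    def copy(self) -> "TissueState":
        return TissueState(
            vm=self.vm.copy(), v=self.v.copy(), w=self.w.copy(),
            o1=self.o1.copy(), o2=self.o2.copy(), c1=self.c1.copy(),
            c2=self.c2.copy(), t=self.t,
        )


@dataclass
class Recording:
    """Voltage movie + probe traces + light log produced by :func:`integrate`.

    ``frames`` has shape (n_frames, ny, nx); ``frame_times`` are absolute ms.
    ``probes`` maps name -> voltage trace sampled at ``probe_times``
    (interval <= 1 ms).  ``meta`` echoes solver parameters.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    probes: dict
    probe_times: np.ndarray
    light_log: list
    meta: dict = field(default_factory=dict)

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0]) if len(self.frame_times) > 1 else 0.0


# ---------------------------------------------------------------------------
# Spatial operator
# ---------------------------------------------------------------------------

def laplacian(v_field: np.ndarray, params: TissueParams) -> np.ndarray:
    """Five-point Laplacian with no-flux (mirrored ghost node) boundaries.

    Because ghost nodes mirror their interior neighbours, the discrete sum of
    the operator over the lattice vanishes identically (no-flux conservation).
    """
    if v_field.shape != (params.ny, params.nx):
        raise ValueError(f"field shape {v_field.shape} does not match grid "
                         f"({params.ny}, {params.nx})")
    out = np.empty_like(v_field, dtype=np.float64)
    _laplacian_kernel(np.ascontiguousarray(v_field, dtype=np.float64), out, params.dx)
    return out


@njit(cache=True, fastmath=True)
def _laplacian_kernel(vf, out, dx):
    ny, nx = vf.shape
    inv2 = 1.0 / (dx * dx)
    for i in range(ny):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < ny - 1 else ny - 1
        for j in range(nx):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < nx - 1 else nx - 1
            out[i, j] = (vf[im, j] + vf[ip, j] + vf[i, jm] + vf[i, jp] - 4.0 * vf[i, j]) * inv2


@njit(cache=True, fastmath=True)
def _integrate_kernel(vm, v, w, o1, o2, c1, c2,
                      light, stim, nsteps, dt, dx, dcoeff,
                      ip, cp,
                      frames, frame_stride,
                      probe_rc, probe_out, probe_stride, t0):
    """Advance the full tissue ``nsteps`` steps, filling frames/probe buffers.

    ``light``: per-step irradiance (mW/mm²).  ``stim``: rows of
    (r0, r1, c0, c1, t_on, t_off, amp) in ms / µA/cm².  Returns the step
    index at which divergence was detected, or -1 on success.
    """
    ny, nx = vm.shape
    lap = np.empty_like(vm)
    fidx = 0
    pidx = 0
    inv2 = dcoeff / (dx * dx)
    # Rush–Larsen gate factors are constants of the run
    f_vp = np.exp(-dt / ip[7])    # tau_v_plus
    f_v1 = np.exp(-dt / ip[8])    # tau_v1_minus
    f_v2 = np.exp(-dt / ip[9])    # tau_v2_minus
    f_wp = np.exp(-dt / ip[10])   # tau_w_plus
    f_wm = np.exp(-dt / ip[11])   # tau_w_minus
    vrest = ip[0]
    vamp = ip[1]
    u_c = ip[2]
    u_v = ip[3]
    u_h = ip[16]
    k_h = ip[17]
    q_vc = ip[18]
    for k in range(nsteps + 1):
        if k % frame_stride == 0 and fidx < frames.shape[0]:
            for i in range(ny):
                for j in range(nx):
                    frames[fidx, i, j] = vm[i, j]
            fidx += 1
        if k % probe_stride == 0 and pidx < probe_out.shape[1]:
            for p in range(probe_rc.shape[0]):
                probe_out[p, pidx] = vm[probe_rc[p, 0], probe_rc[p, 1]]
            pidx += 1
        if k == nsteps:
            break
        t = t0 + k * dt
        e_mw = light[k]
        any_stim = False
        for s in range(stim.shape[0]):
            if stim[s, 4] <= t < stim[s, 5]:
                any_stim = True
        # diffusion term with mirrored ghosts
        for i in range(ny):
            im = i - 1 if i > 0 else 0
            ii = i + 1 if i < ny - 1 else ny - 1
            for j in range(nx):
                jm = j - 1 if j > 0 else 0
                jj = j + 1 if j < nx - 1 else nx - 1
                lap[i, j] = (vm[im, j] + vm[ii, j] + vm[i, jm] + vm[i, jj]
                             - 4.0 * vm[i, j]) * inv2
        # reaction update
        for i in range(ny):
            for j in range(nx):
                i_ext = 0.0
                if any_stim:
                    for s in range(stim.shape[0]):
                        if (stim[s, 4] <= t < stim[s, 5]
                                and stim[s, 0] <= i < stim[s, 1]
                                and stim[s, 2] <= j < stim[s, 3]):
                            i_ext += stim[s, 6]
                o1v = o1[i, j]
                o2v = o2[i, j]
                c2v = c2[i, j]
                i_ion = cm._ionic_currents(vm[i, j], v[i, j], w[i, j], ip)
                if e_mw > 0.0 or o1v > 1e-14 or o2v > 1e-14 or c2v > 1e-14:
                    i_chr2 = cm._chr2_current(vm[i, j], o1v, o2v, cp)
                    o1n, o2n, c1n, c2n = cm._chr2_step(
                        o1v, o2v, c1[i, j], c2v, e_mw, dt, cp)
                    o1[i, j] = o1n
                    o2[i, j] = o2n
                    c1[i, j] = c1n
                    c2[i, j] = c2n
                else:
                    i_chr2 = 0.0   # dark-adapted node: photocycle is a fixed point
                u = (vm[i, j] - vrest) / vamp
                if u > u_c + q_vc * (1.0 - v[i, j]):
                    vn = v[i, j] * f_vp
                    wn = w[i, j] * f_wp
                else:
                    v_inf = 1.0 / (1.0 + np.exp((u - u_h) / k_h))
                    fv = f_v1 if u > u_v else f_v2
                    vn = v_inf + (v[i, j] - v_inf) * fv
                    wn = 1.0 + (w[i, j] - 1.0) * f_wm
                vm[i, j] = vm[i, j] + dt * ((-(i_ion + i_chr2) + i_ext) / ip[15]
                                            + lap[i, j])
                v[i, j] = vn
                w[i, j] = wn
        if k % 200 == 0:
            bad = False
            for i in range(ny):
                for j in range(nx):
                    if not np.isfinite(vm[i, j]) or abs(vm[i, j]) > 500.0:
                        bad = True
            if bad:
                return k
    return -1


def _light_schedule(pulses, t0, nsteps, dt):
    light = np.zeros(nsteps, dtype=np.float64)
    log = []
    for p in pulses:
        k0 = max(0, int(np.ceil((p.t_on - t0) / dt - 1e-9)))
        k1 = min(nsteps, int(round((p.t_on + p.pl - t0) / dt)))
        if k1 > k0:
            light[k0:k1] = p.li * 1e-3
        log.append({"li": p.li, "pl": p.pl, "t_on": p.t_on, "spatial_mode": p.spatial_mode})
    return light, log


def integrate(
    state: TissueState,
    params: TissueParams,
    pulses: list[LightPulse] = (),
    stimuli: list[Stimulus] = (),
    duration: float = 100.0,
    frame_interval: float = 1.0,
    probes: dict | None = None,
    probe_interval: float = 0.1,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> Recording:
    """Advance ``state`` in place by ``duration`` ms and return a Recording.

    ``probes`` maps name -> (row, col).  The default probe sits at the
    quarter-domain point (ny//4, 3*nx//4), away from the central core.
    Deterministic: no randomness anywhere in the solver.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    ionic = ionic or cm.IonicParams()
    chr2 = chr2 or cm.ChR2Params()
    dt = params.dt
    nsteps = int(round(duration / dt))
    frame_stride = max(1, int(round(frame_interval / dt)))
    probe_stride = max(1, int(round(probe_interval / dt)))
    if probe_stride * dt > 1.0 + 1e-9:
        raise ValueError("probe sampling interval must be <= 1 ms")
    if probes is None:
        probes = {"p0": (params.ny // 4, 3 * params.nx // 4)}
    probe_rc = np.array([list(rc) for rc in probes.values()], dtype=np.int64).reshape(-1, 2)

    t0 = state.t
    light, log = _light_schedule(pulses, t0, nsteps, dt)
    stim_arr = np.array(
        [[s.rows[0], s.rows[1], s.cols[0], s.cols[1], s.t_on, s.t_on + s.duration, s.amp]
         for s in stimuli], dtype=np.float64).reshape(-1, 7)

    n_frames = nsteps // frame_stride + 1
    n_psamp = nsteps // probe_stride + 1
    frames = np.empty((n_frames, params.ny, params.nx), dtype=np.float64)
    probe_out = np.empty((len(probes), n_psamp), dtype=np.float64)

    bad = _integrate_kernel(
        state.vm, state.v, state.w, state.o1, state.o2, state.c1, state.c2,
        light, stim_arr, nsteps, dt, params.dx, params.d_coeff,
        ionic.as_array(), chr2.as_array(),
        frames, frame_stride, probe_rc, probe_out, probe_stride, t0)
    if bad >= 0:
        raise IntegrationError("tissue integration diverged",
                               t_last=t0 + bad * dt, variable="vm")
    state.t = t0 + nsteps * dt

    frame_times = t0 + np.arange(n_frames) * frame_stride * dt
    probe_times = t0 + np.arange(n_psamp) * probe_stride * dt
    meta = {
        "params": asdict(params),
        "ionic": asdict(ionic),
        "chr2": asdict(chr2),
        "probe_nodes": {k: list(v) for k, v in probes.items()},
        "schema": "optospiral-recording-1",
    }
    return Recording(
        frames=frames,
        frame_times=frame_times,
        probes={name: probe_out[i] for i, name in enumerate(probes)},
        probe_times=probe_times,
        light_log=log,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def measure_cv(
    params: TissueParams | None = None,
    ionic: cm.IonicParams | None = None,
    strip_rows: int = 7,
    upstroke_mv: float = -20.0,
) -> float:
    """Plane-wave conduction velocity (cm/s) on a thin strip.

    One edge of a quiescent strip is stimulated; activation times (upstroke
    crossing of ``upstroke_mv``) are recorded at two interior points 10 mm
    apart on the propagation axis, and CV = distance / Δt.
    """
    base = params or TissueParams()
    p = TissueParams(nx=base.nx, ny=strip_rows, dx=base.dx,
                     d_coeff=base.d_coeff, c_m=base.c_m, dt=base.dt)
    state = TissueState.resting(p, ionic)
    mid = strip_rows // 2
    ja = int(round(0.75 / (p.dx)))   # 7.5 mm
    jb = int(round(1.75 / (p.dx)))   # 17.5 mm
    stim = Stimulus(amp=80.0, t_on=1.0, duration=1.0, rows=(0, strip_rows), cols=(0, 3))
    rec = integrate(state, p, stimuli=[stim], duration=80.0,
                    probes={"a": (mid, ja), "b": (mid, jb)},
                    frame_interval=10.0, ionic=ionic)

    def activation(trace):
        idx = np.nonzero((trace[1:] >= upstroke_mv) & (trace[:-1] < upstroke_mv))[0]
        if len(idx) == 0:
            return None
        return rec.probe_times[idx[0] + 1]

    ta, tb = activation(rec.probes["a"]), activation(rec.probes["b"])
    if ta is None or tb is None or tb <= ta:
        raise PropagationFailureError("wave failed to reach both probes")
    dist_cm = (jb - ja) * p.dx
    return float(dist_cm / (tb - ta) * 1000.0)


def init_spiral(
    params: TissueParams | None = None,
    settle_time: float = 500.0,
    s1_transit: float = 34.0,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
    check: bool = True,
) -> TissueState:
    """Create a single stable spiral by cross-field (broken-wave) initiation.

    An S1 plane wave is launched along a thin strip and integrated for
    ``s1_transit`` ms, until its front reaches mid-domain; the resulting 1D
    pulse profile is then transplanted into the lower half-plane of the full
    sheet, which is equivalent to an S2 half-field stimulus timed into the S1
    repolarization tail: the free wave end at mid-domain curls into a single
    spiral.  The state is settled for ``settle_time`` ms and verified to
    carry exactly one phase singularity.  Raises :class:`SpiralInitError`
    otherwise (advice: adjust ``s1_transit``, the S1–S2 timing equivalent).
    """
    p = params or TissueParams()
    strip = TissueParams(nx=p.nx, ny=7, dx=p.dx, d_coeff=p.d_coeff,
                         c_m=p.c_m, dt=p.dt)
    s1_state = TissueState.resting(strip, ionic)
    s1 = Stimulus(amp=80.0, t_on=1.0, duration=1.0, rows=(0, 7), cols=(0, 3))
    integrate(s1_state, strip, stimuli=[s1], duration=s1_transit,
              frame_interval=s1_transit, ionic=ionic, chr2=chr2)

    state = TissueState.resting(p, ionic)
    half = p.ny // 2
    mid = strip.ny // 2
    state.vm[:half, :] = s1_state.vm[mid][None, :]
    state.v[:half, :] = s1_state.v[mid][None, :]
    state.w[:half, :] = s1_state.w[mid][None, :]

    rec = integrate(state, p, duration=settle_time, frame_interval=5.0,
                    ionic=ionic, chr2=chr2)
    if check:
        if rec.frames[-1].max() < -60.0:
            raise SpiralInitError(
                "spiral self-terminated during settling; adjust s1_transit")
        from .analysis import tip_trajectory

        probe = integrate(state.copy(), p, duration=40.0, frame_interval=1.0,
                          ionic=ionic, chr2=chr2)
        tips = tip_trajectory(probe)
        frames_with_tip = {t for t, _, _ in tips}
        if len(frames_with_tip) < 30:
            raise SpiralInitError(
                "no persistent phase singularity after settling; adjust s1_transit")
    return state


def spiral_period(
    state: TissueState,
    params: TissueParams,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
    window: float = 200.0,
) -> float:
    """Rotation period (ms) as the mean interval between probe-trace peaks.

    Runs a throwaway copy of ``state``; the input is not advanced.
    """
    from .analysis import arrhythmia_peaks

    rec = integrate(state.copy(), params, duration=window, frame_interval=5.0,
                    ionic=ionic, chr2=chr2)
    peaks = arrhythmia_peaks(rec.probes["p0"], rec.probe_times)
    if len(peaks) < 3:
        raise PropagationFailureError("too few activations to estimate a period")
    return float(np.mean(np.diff(peaks)))


def make_ensemble(
    base: TissueState,
    params: TissueParams,
    n: int = 25,
    period: float | None = None,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> list[TissueState]:
    """``n`` snapshots at times j·T_s/n along one rotation of the base spiral.

    The members are the same rotor caught at n equally spaced phases, which
    is the initial-condition ensemble used for dose–response statistics.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if n == 1:
        return [base.copy()]
    ts = period if period is not None else spiral_period(base, params, ionic, chr2)
    members = []
    run = base.copy()
    step = ts / n
    for j in range(n):
        members.append(run.copy())
        if j < n - 1:
            integrate(run, params, duration=step, frame_interval=step,
                      ionic=ionic, chr2=chr2)
    return members
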