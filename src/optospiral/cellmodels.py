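"""Single-cell electrophysiology: mouse-ventricular ionic kinetics and the ChR2 photocycle.

The ionic membrane model is a reduced three-current formulation (fast inward,
slow outward, slow inward) in physical voltage units, with two recovery gates
integrated by Rush–Larsen exponential updates.  Its parameters are calibrated
to adult mouse ventricle at tissue level: resting potential near -80 mV, a
short triangular action potential, a plane-wave conduction velocity of
43.9 cm/s at the standard diffusion coefficient, and a single rigidly
rotating spiral with a sub-millimetre core.  The calibrated set ships as the
frozen default configuration.

Light sensitivity comes from a four-state channelrhodopsin-2 photocycle
(closed C1 -> open O1 <-> open O2 -> closed C2 -> C1) whose activation rates
are linear in irradiance.  The photocurrent uses the empirical inward
rectification

    I_ChR2 = g_ChR2 * (O1 + gamma*O2) * [10.6408 - 14.6408*exp(-V/42.7671)]

where the bracket is the analytic product G(V)*(V - E_ChR2) with
E_ChR2 = 0 mV, finite for every voltage including V = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import InvalidStateError, IntegrationError

# Rectification constants (mV-scale empirical fit for ChR2).
RECT_A = 10.6408
RECT_B = 14.6408
RECT_TAU = 42.7671

#: Voltage at which the ChR2 photocurrent reverses sign (mV).
CHR2_ZERO_CROSSING_MV = RECT_TAU * math.log(RECT_B / RECT_A)

# Reaction-kinetics stability bound for the explicit cell update (ms).
DT_MAX_MS = 0.2


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicParams:
    """Reduced mouse-ventricular membrane kinetics.

    Voltages in mV, times in ms, rates per ms.  ``v_rest``/``v_amp`` map the
    internal normalized activation variable u onto physical voltage:
    V = v_rest + v_amp * u.
    """

    v_rest: float = -80.0       # resting potential (mV)
    v_amp: float = 120.0        # AP amplitude scale (mV)
    u_c: float = 0.065          # activation threshold (normalized)
    u_v: float = 0.04           # fast-gate recovery switch (normalized)
    u_csi: float = 2.0          # slow-inward activation midpoint (suppressed in the murine set)
    k_si: float = 10.0          # slow-inward activation steepness
    tau_d: float = 0.004        # fast-inward (depolarization) time constant (ms)
    tau_v_plus: float = 1.5     # fast-gate inactivation (ms)
    tau_v1_minus: float = 10.0  # fast-gate recovery, u > u_v (ms)
    tau_v2_minus: float = 10.0  # fast-gate recovery, u < u_v (ms)
    tau_w_plus: float = 10.0   # slow-gate inactivation (ms)
    tau_w_minus: float = 40.0   # slow-gate recovery (ms)
    tau_0: float = 0.1          # sub-threshold leak (ms)
    tau_r: float = 8.0          # repolarization (ms)
    tau_si: float = 20.0        # slow-inward current scale (ms)
    c_m: float = 1.0            # specific membrane capacitance (uF/cm^2)
    u_h: float = 0.025          # steady-state inactivation midpoint (normalized)
    k_h: float = 0.015          # steady-state inactivation slope (normalized)
    q_vc: float = 0.12          # threshold rise per unit lost availability (normalized)
    u_k: float = 0.04           # inward-rectifier knee (normalized); leak fades above it
    leak_act: float = 0.7       # activity-dependent fraction of the diastolic leak

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v_rest, self.v_amp, self.u_c, self.u_v, self.u_csi,
             self.k_si, self.tau_d, self.tau_v_plus, self.tau_v1_minus,
             self.tau_v2_minus, self.tau_w_plus, self.tau_w_minus,
             self.tau_0, self.tau_r, self.tau_si, self.c_m,
             self.u_h, self.k_h, self.q_vc, self.u_k, self.leak_act],
            dtype=np.float64,
        )

    def v_inf(self, u: float) -> float:
        """Steady-state availability of the fast gate at sub-threshold u."""
        return 1.0 / (1.0 + math.exp((u - self.u_h) / self.k_h))


@dataclass(frozen=True)
class ChR2Params:
    """Four-state ChR2 photocycle parameters.

    Irradiance is accepted in µW/mm² at the API surface and converted to
    mW/mm² internally (1 mW/mm² = 1000 µW/mm²); activation rates are linear
    in irradiance at the intensities used here.
    """

    g_chr2: float = 0.6503       # maximal conductance (mS/cm^2), calibrated
    gamma: float = 0.1          # O2/O1 conductance ratio
    e_chr2: float = 0.0         # reversal potential (mV); fixed at 0
    k_a1: float = 0.8           # C1->O1 activation (per ms per mW/mm^2)
    k_a2: float = 0.2           # C2->O2 activation (per ms per mW/mm^2)
    g_d1: float = 0.10          # O1->C1 closing (per ms)
    g_d2: float = 0.05          # O2->C2 closing (per ms)
    g_r: float = 0.00033        # C2->C1 dark recovery (per ms)
    e_12: float = 0.053         # O1->O2 (per ms)
    e_21: float = 0.023         # O2->O1 (per ms)

    def __post_init__(self):
        if self.e_chr2 != 0.0:
            raise ValueError("e_chr2 must be exactly 0 mV for this channel")
        for name in ("k_a1", "k_a2", "g_d1", "g_d2", "g_r", "e_12", "e_21"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.g_chr2, self.gamma, self.k_a1, self.k_a2, self.g_d1,
             self.g_d2, self.g_r, self.e_12, self.e_21],
            dtype=np.float64,
        )

    def rate_matrix(self, irradiance_uw_mm2: float) -> np.ndarray:
        """Generator matrix Q of the photocycle at fixed irradiance.

        State order (c1, o1, o2, c2); d/dt p = Q p.  Columns sum to zero, so
        total occupancy is conserved exactly.
        """
        e_mw = irradiance_uw_mm2 * 1e-3
        ga1 = self.k_a1 * e_mw
        ga2 = self.k_a2 * e_mw
        q = np.array([
            [-ga1, self.g_d1, 0.0, self.g_r],
            [ga1, -(self.g_d1 + self.e_12), self.e_21, 0.0],
            [0.0, self.e_12, -(self.e_21 + self.g_d2), ga2],
            [0.0, 0.0, self.g_d2, -(ga2 + self.g_r)],
        ])
        return q


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class ChR2State:
    """Photocycle occupancies; dark-adapted default is all probability in C1."""

    o1: float = 0.0
    o2: float = 0.0
    c1: float = 1.0
    c2: float = 0.0

    def occupancies(self) -> np.ndarray:
        return np.array([self.c1, self.o1, self.o2, self.c2])

    def validate(self, atol: float = 1e-9) -> None:
        occ = self.occupancies()
        if not np.all(np.isfinite(occ)):
            raise InvalidStateError("non-finite ChR2 occupancy")
        if occ.min() < -atol or occ.max() > 1 + atol:
            raise InvalidStateError(f"ChR2 occupancy out of [0, 1]: {occ}")
        if abs(occ.sum() - 1.0) > atol:
            raise InvalidStateError(f"ChR2 occupancies sum to {occ.sum():.12f}, not 1")


@dataclass
class IonicState:
    """Full per-cell electrophysiological state.

    ``gates`` are Hodgkin–Huxley-style recovery variables in [0, 1];
    ``markov`` holds Markov-chain occupancy sets (empty for the reduced
    membrane model — the ChR2 photocycle is carried separately as
    :class:`ChR2State`); ``concentrations`` likewise (the reduced model
    clamps ionic concentrations).
    """

    vm: float = -80.0
    gates: dict = field(default_factory=lambda: {"v": 1.0, "w": 1.0})
    markov: dict = field(default_factory=dict)
    concentrations: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not np.isfinite(self.vm):
            raise InvalidStateError("non-finite membrane voltage")
        for name, g in self.gates.items():
            if not np.isfinite(g) or g < 0.0 or g > 1.0:
                raise InvalidStateError(f"gate {name} = {g} outside [0, 1]")
        for name, c in self.concentrations.items():
            if c <= 0:
                raise InvalidStateError(f"concentration {name} = {c} not positive")


def resting_state(params: IonicParams | None = None) -> IonicState:
    """Quiescent fixed point of the membrane model (both gates fully recovered)."""
    p = params or IonicParams()
    return IonicState(vm=p.v_rest, gates={"v": p.v_inf(0.0), "w": 1.0})


# ---------------------------------------------------------------------------
# Numba kernels (scalar; inlined into the tissue integrator)
# ---------------------------------------------------------------------------

# index constants matching IonicParams.as_array()
_I_VREST, _I_VAMP, _I_UC, _I_UV, _I_UCSI, _I_KSI, _I_TD, _I_TVP, _I_TV1M, \
    _I_TV2M, _I_TWP, _I_TWM, _I_T0, _I_TR, _I_TSI, _I_CM, _I_UH, _I_KH, \
    _I_QVC, _I_UK, _I_LACT = range(21)

# index constants matching ChR2Params.as_array()
_C_G, _C_GAMMA, _C_KA1, _C_KA2, _C_GD1, _C_GD2, _C_GR, _C_E12, _C_E21 = range(9)


@njit(cache=True, fastmath=True)
def _ionic_currents(vm, v, w, ip):
    """Total ionic current density I_ion (µA/cm²); positive = outward."""
    u = (vm - ip[_I_VREST]) / ip[_I_VAMP]
    # the effective threshold rises as fast-channel availability drops, so
    # sustained sub-threshold depolarization makes tissue harder to excite
    u_thr = ip[_I_UC] + ip[_I_QVC] * (1.0 - v)
    if u > u_thr:
        j_fi = -(v / ip[_I_TD]) * (1.0 - u) * (u - u_thr)
        # conductance-like outward current: weak at the front foot, fast at
        # the plateau, giving the triangular mouse-type repolarization
        j_so = u / ip[_I_TR]
    else:
        j_fi = 0.0
        # inward-rectifier-like leak: stiff near rest, fading above its knee
        # u_k, so sustained inward current produces only a bounded diastolic
        # elevation until it exceeds the knee current and fires the cell.
        # The (1 - w) weighting makes recently active tissue leak harder
        # (activity-dependent outward balance of murine diastolic membrane).
        j_so = (u / ip[_I_T0]) * math.exp(-u / ip[_I_UK]) * (
            (1.0 - ip[_I_LACT]) + ip[_I_LACT] * (1.0 - w))
    if ip[_I_UCSI] <= 1.0:
        j_si = -(w / (2.0 * ip[_I_TSI])) * (1.0 + math.tanh(ip[_I_KSI] * (u - ip[_I_UCSI])))
    else:
        # slow-inward (dome) current suppressed: activation midpoint outside
        # the physical voltage range, as in the murine calibration
        j_si = 0.0
    return ip[_I_CM] * ip[_I_VAMP] * (j_fi + j_so + j_si)


@njit(cache=True, fastmath=True)
def _gate_step(vm, v, w, dt, ip):
    """Rush–Larsen exponential update of the two recovery gates.

    Below threshold the fast gate relaxes toward its voltage-dependent
    steady state v_inf(u) (partial inactivation at depolarized diastolic
    potentials, full availability at rest), so sustained sub-threshold
    depolarization — e.g. weak illumination — reduces excitability and slows
    conduction instead of accelerating it.
    """
    u = (vm - ip[_I_VREST]) / ip[_I_VAMP]
    if u > ip[_I_UC] + ip[_I_QVC] * (1.0 - v):
        v = v * math.exp(-dt / ip[_I_TVP])
        w = w * math.exp(-dt / ip[_I_TWP])
    else:
        v_inf = 1.0 / (1.0 + math.exp((u - ip[_I_UH]) / ip[_I_KH]))
        tau_v = ip[_I_TV1M] if u > ip[_I_UV] else ip[_I_TV2M]
        v = v_inf + (v - v_inf) * math.exp(-dt / tau_v)
        w = 1.0 + (w - 1.0) * math.exp(-dt / ip[_I_TWM])
    return v, w


@njit(cache=True, fastmath=True)
def _chr2_current(vm, o1, o2, cp):
    """ChR2 photocurrent density (µA/cm²); negative = inward."""
    return cp[_C_G] * (o1 + cp[_C_GAMMA] * o2) * (RECT_A - RECT_B * math.exp(-vm / RECT_TAU))


@njit(cache=True, fastmath=True)
def _chr2_step(o1, o2, c1, c2, e_mw, dt, cp):
    """Forward-Euler photocycle update; conserves total occupancy to roundoff."""
    ga1 = cp[_C_KA1] * e_mw
    ga2 = cp[_C_KA2] * e_mw
    do1 = ga1 * c1 - (cp[_C_GD1] + cp[_C_E12]) * o1 + cp[_C_E21] * o2
    do2 = cp[_C_E12] * o1 - (cp[_C_E21] + cp[_C_GD2]) * o2 + ga2 * c2
    dc2 = cp[_C_GD2] * o2 - (ga2 + cp[_C_GR]) * c2
    o1n = o1 + dt * do1
    o2n = o2 + dt * do2
    c2n = c2 + dt * dc2
    c1n = c1 - dt * (do1 + do2 + dc2)
    return o1n, o2n, c1n, c2n


@njit(cache=True, fastmath=True)
def _cell_step(vm, v, w, o1, o2, c1, c2, e_mw, i_ext, dt, ip, cp):
    """One explicit step of the full cell (membrane + gates + photocycle).

    ``i_ext`` (µA/cm²) is positive-depolarizing by convention.
    """
    i_ion = _ionic_currents(vm, v, w, ip)
    i_chr2 = _chr2_current(vm, o1, o2, cp)
    vm_n = vm + dt * (-(i_ion + i_chr2) + i_ext) / ip[_I_CM]
    v_n, w_n = _gate_step(vm, v, w, dt, ip)
    o1n, o2n, c1n, c2n = _chr2_step(o1, o2, c1, c2, e_mw, dt, cp)
    return vm_n, v_n, w_n, o1n, o2n, c1n, c2n


# ---------------------------------------------------------------------------
# Public single-cell API
# ---------------------------------------------------------------------------

def chr2_photocurrent(vm: float, chr2: ChR2State, params: ChR2Params) -> float:
    """ChR2 current density (µA/cm²) at voltage ``vm`` (mV).

    Negative values are inward (depolarizing).  The V = 0 singularity of the
    rectification ratio G(V) cancels in the product G(V)·(V − E_ChR2), which
    is what is evaluated here, so the result is finite everywhere.
    """
    if not np.isfinite(vm):
        raise InvalidStateError("non-finite membrane voltage")
    chr2.validate(atol=1e-6)
    return float(_chr2_current(vm, chr2.o1, chr2.o2, params.as_array()))


def chr2_step(chr2: ChR2State, irradiance: float, dt: float, params: ChR2Params) -> ChR2State:
    """Advance the photocycle by ``dt`` ms under ``irradiance`` µW/mm²."""
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    o1, o2, c1, c2 = _chr2_step(
        chr2.o1, chr2.o2, chr2.c1, chr2.c2, irradiance * 1e-3, dt, params.as_array()
    )
    return ChR2State(o1=o1, o2=o2, c1=c1, c2=c2)


def chr2_equilibrium(irradiance: float, params: ChR2Params) -> np.ndarray:
    """Steady-state occupancies (c1, o1, o2, c2) at fixed irradiance (µW/mm²).

    Null-space solution of the photocycle generator matrix; serves as the
    independent oracle for the time-stepped kinetics.
    """
    q = params.rate_matrix(irradiance)
    # replace one balance row with the conservation constraint
    a = q.copy()
    a[0, :] = 1.0
    b = np.zeros(4)
    b[0] = 1.0
    return np.linalg.solve(a, b)


def ionic_step(
    state: IonicState,
    i_ext: float,
    dt: float,
    params: IonicParams | None = None,
) -> IonicState:
    """Advance the membrane model one step (no light; see :func:`cell_step`).

    ``i_ext`` in µA/cm², positive depolarizing.  ``dt`` must satisfy the
    documented reaction stability bound ``DT_MAX_MS``.
    """
    p = params or IonicParams()
    if dt <= 0 or dt > DT_MAX_MS:
        raise ValueError(f"dt must lie in (0, {DT_MAX_MS}] ms")
    state.validate()
    ip = p.as_array()
    i_ion = _ionic_currents(state.vm, state.gates["v"], state.gates["w"], ip)
    vm = state.vm + dt * (-i_ion + i_ext) / p.c_m
    v, w = _gate_step(state.vm, state.gates["v"], state.gates["w"], dt, ip)
    if not np.isfinite(vm):
        raise IntegrationError("membrane voltage diverged", variable="vm")
    return IonicState(vm=vm, gates={"v": v, "w": w},
                      markov=dict(state.markov), concentrations=dict(state.concentrations))


def simulate_cell(
    duration: float,
    dt: float = 0.01,
    irradiance: float = 0.0,
    light_window: tuple[float, float] | None = None,
    i_ext_fn=None,
    ionic: IonicParams | None = None,
    chr2: ChR2Params | None = None,
    record_every: float = 0.1,
):
    """Integrate a single isolated cell and return (t, vm, i_chr2, open_fraction).

    ``light_window`` = (t_on, t_off) in ms restricts illumination; otherwise
    light (if any) is on for the whole run.  ``i_ext_fn(t) -> µA/cm²`` adds an
    injected current.  Used for threshold calibration and the light-response
    examples.
    """
    ip = (ionic or IonicParams()).as_array()
    cp = (chr2 or ChR2Params()).as_array()
    n = int(round(duration / dt))
    stride = max(1, int(round(record_every / dt)))
    vm, v, w = ip[_I_VREST], 1.0, 1.0
    o1, o2, c1, c2 = 0.0, 0.0, 1.0, 0.0
    ts, vms, ichs, opens = [], [], [], []
    for k in range(n + 1):
        t = k * dt
        if k % stride == 0:
            ts.append(t)
            vms.append(vm)
            ichs.append(_chr2_current(vm, o1, o2, cp))
            opens.append(o1 + cp[_C_GAMMA] * o2)
        if k == n:
            break
        if light_window is None:
            e = irradiance
        else:
            e = irradiance if light_window[0] <= t < light_window[1] else 0.0
        i_ext = i_ext_fn(t) if i_ext_fn is not None else 0.0
        vm, v, w, o1, o2, c1, c2 = _cell_step(
            vm, v, w, o1, o2, c1, c2, e * 1e-3, i_ext, dt, ip, cp
        )
    return (np.asarray(ts), np.asarray(vms), np.asarray(ichs), np.asarray(opens))


def optical_threshold(
    pl: float = 500.0,
    lo: float = 5.0,
    hi: float = 200.0,
    tol: float = 0.5,
    ionic: IonicParams | None = None,
    chr2: ChR2Params | None = None,
) -> float:
    """Bisect the minimal irradiance (µW/mm²) whose ``pl``-ms pulse fires an AP.

    An action potential is counted when vm exceeds 0 mV.  This is the
    calibration constraint used to fix g_chr2 so the single-cell threshold
    falls between 20 and 25 µW/mm², matching the sub-/supra-threshold régime
    boundary of the tissue model.
    """

    def fires(li):
        _, vm, _, _ = simulate_cell(pl + 100.0, irradiance=li,
                                    light_window=(0.0, pl), ionic=ionic, chr2=chr2)
        return vm.max() > 0.0

    if fires(lo):
        return lo
    if not fires(hi):
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def calibrate_g_chr2(
    target_lo: float = 20.0,
    target_hi: float = 25.0,
    pl: float = 500.0,
    ionic: IonicParams | None = None,
    chr2: ChR2Params | None = None,
) -> float:
    """Bisect g_chr2 so the 500-ms single-cell optical threshold lies in (lo, hi]."""
    base = chr2 or ChR2Params()
    target = 0.5 * (target_lo + target_hi)

    def thr(g):
        return optical_threshold(pl=pl, ionic=ionic, chr2=replace(base, g_chr2=g))

    g_lo, g_hi = 0.005, 2.0
    for _ in range(40):
        g = math.sqrt(g_lo * g_hi)
        t = thr(g)
        if target_lo < t <= target_hi:
            return g
        if t > target:
            g_lo = g
        else:
            g_hi = g
    raise RuntimeError("g_chr2 calibration did not converge")
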