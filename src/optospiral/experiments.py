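"""Protocol drivers for the in-silico illumination campaigns.

Each driver composes the tissue solver with the termination analysis:
excitation-threshold mapping on the irradiance grid, critical-pulse-length
search, termination-time curves, and the LI × PL dose–response over an
ensemble of spiral phases.  All drivers are deterministic: rerunning a
campaign with the same configuration reproduces the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cellmodels as cm
from .analysis import detect_termination
from .tissue import LightPulse, TissueParams, TissueState, integrate


@dataclass(frozen=True)
class DoseResponsePoint:
    li: float            # µW/mm²
    pl: float            # ms
    n_trials: int
    n_terminated: int

    @property
    def rate(self) -> float:
        return self.n_terminated / self.n_trials

    @property
    def sem(self) -> float:
        """Standard error of the per-trial binary outcome (as plotted mean ± SEM)."""
        p = self.rate
        return float(np.sqrt(p * (1.0 - p) / self.n_trials))


@dataclass(frozen=True)
class PlCriticalResult:
    li: float              # µW/mm²
    pl_critical: float | None   # ms; None when not terminable within the cap
    search_grid: float     # ms resolution of the search


RELAXATION_MS = 100.0      # light-off relaxation before the quiescence check
QUIESCENCE_MS = 100.0      # window that must stay quiescent


def _run_trial(
    state: TissueState,
    params: TissueParams,
    li: float,
    pl: float,
    t_on: float = 20.0,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
):
    """One illumination trial on a copy of ``state``; returns (TerminationResult, Recording)."""
    run = state.copy()
    pulse = LightPulse(li=li, pl=pl, t_on=run.t + t_on)
    duration = t_on + pl + RELAXATION_MS + QUIESCENCE_MS
    rec = integrate(run, params, pulses=[pulse], duration=duration,
                    frame_interval=1.0, ionic=ionic, chr2=chr2)
    return detect_termination(rec, pulse, relaxation=RELAXATION_MS,
                              quiescence_window=QUIESCENCE_MS), rec


def excitation_threshold(
    state: TissueState,
    params: TissueParams,
    grid_step: float = 5.0,
    pl: float = 500.0,
    li_max: float = 60.0,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> float:
    """Lowest irradiance on the grid whose global pulse triggers a new
    excitation wave in the spiral-bearing domain.

    A triggered wave is recognized by the domain becoming uniformly
    depolarized at some instant during the pulse: the core and the excitable
    gap — the only regions near rest under sub-threshold light — are then
    excited, so the spatial minimum of V rises above the detection level,
    set midway between rest (−80 mV) and the light-driven elevated plateau
    (about −30 mV).
    """
    lis = np.arange(grid_step, li_max + grid_step / 2, grid_step)
    for li in lis:
        run = state.copy()
        pulse = LightPulse(li=float(li), pl=pl, t_on=run.t + 10.0)
        rec = integrate(run, params, pulses=[pulse], duration=pl + 30.0,
                        frame_interval=2.0, ionic=ionic, chr2=chr2)
        spatial_min = rec.frames.min(axis=(1, 2))
        if spatial_min.max() > -55.0:
            return float(li)
    raise ValueError(f"no excitation up to {li_max} µW/mm²; widen the scan range")


def pl_critical(
    state: TissueState,
    params: TissueParams,
    li: float,
    grid: float = 2.0,
    pl_cap: float = 1000.0,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> PlCriticalResult:
    """Minimum pulse length that terminates the spiral at irradiance ``li``.

    Bisection on PL between a non-terminating lower bound and a terminating
    upper bound (500 ms, escalated to ``pl_cap``), refined to ``grid`` ms;
    every probe is a fresh run from the same initial state.  The result
    satisfies: terminates at pl_critical, does not at pl_critical − grid.
    """
    def terminates(pl):
        res, _ = _run_trial(state, params, li, pl, ionic=ionic, chr2=chr2)
        return res.terminated

    hi = 500.0
    while not terminates(hi):
        if hi >= pl_cap:
            return PlCriticalResult(li=li, pl_critical=None, search_grid=grid)
        hi = min(2 * hi, pl_cap)
    lo = 0.0
    while hi - lo > grid:
        mid = round((lo + hi) / 2 / grid) * grid
        if mid <= lo or mid >= hi:
            break
        if terminates(mid):
            hi = mid
        else:
            lo = mid
    return PlCriticalResult(li=li, pl_critical=float(hi), search_grid=grid)


def dose_response(
    lis: list[float],
    pls: list[float],
    ensemble: list[TissueState],
    params: TissueParams,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> pd.DataFrame:
    """Termination rate ± SEM over the ensemble for every (LI, PL) pair."""
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    rows = []
    for li in lis:
        for pl in pls:
            n_term = 0
            for member in ensemble:
                res, _ = _run_trial(member, params, li, pl, ionic=ionic, chr2=chr2)
                n_term += int(res.terminated)
            pt = DoseResponsePoint(li=li, pl=pl, n_trials=len(ensemble), n_terminated=n_term)
            rows.append({"li": li, "pl": pl, "n_trials": pt.n_trials,
                         "n_terminated": pt.n_terminated, "rate": pt.rate, "sem": pt.sem})
    return pd.DataFrame(rows)


def termination_time_curve(
    lis: list[float],
    pl: float,
    ensemble: list[TissueState],
    params: TissueParams,
    ionic: cm.IonicParams | None = None,
    chr2: cm.ChR2Params | None = None,
) -> pd.DataFrame:
    """Termination time of each terminating trial, per irradiance."""
    rows = []
    for li in lis:
        for j, member in enumerate(ensemble):
            res, _ = _run_trial(member, params, li, pl, ionic=ionic, chr2=chr2)
            rows.append({"li": li, "trial": j, "terminated": res.terminated,
                         "t_term": res.t_term if res.terminated else np.nan})
    return pd.DataFrame(rows)
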