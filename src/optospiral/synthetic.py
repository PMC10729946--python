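"""Synthetic optical-mapping movies with known ground truth.

Emulates the camera geometry of murine panoramic voltage imaging (64 × 64
pixels, 133 µm per pixel, 1 kHz) with an Archimedean-spiral phase map passed
through a stylized action-potential waveform, a central unexcited core whose
radius follows a configurable trajectory, additive Gaussian noise, linear
baseline drift, and a uniform blue-light crosstalk step during the "light
pulse".  Because the rotation frequency, core-radius trajectory, last
arrhythmia peak and crosstalk amplitude are all planted, every analysis
operation can be validated closed-loop without the PDE solver.

Movies are generated in fluorescence units (baseline 1.0, fractional AP
amplitude) and mapped to the calibrated voltage scale after crosstalk
renormalization, which mirrors how real optical-mapping data are processed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tissue import Recording

REST_MV = -80.0
PEAK_MV = 20.0


@dataclass(frozen=True)
class MovieSpec:
    """Specification of one synthetic movie; the seed fully determines the output."""

    shape: tuple[int, int] = (64, 64)      # (ny, nx) pixels
    px_size_mm: float = 0.133              # camera pixel pitch
    frame_rate_hz: float = 1000.0
    duration_ms: float = 1000.0
    rotation_hz: float = 18.75             # spiral frequency during illumination
    wavelength_mm: float = 6.0             # spatial period of the spiral arms
    core_center_mm: tuple[float, float] | None = None   # default: domain centre
    core_radius0_mm: float = 0.3           # planted core radius at light onset
    core_growth_mm_per_ms: float = 0.0     # linear radius growth during light
    apd_fraction: float = 0.45             # excited fraction of each cycle
    amplitude: float = 0.25                # fractional fluorescence amplitude
    noise_sigma: float = 0.0               # Gaussian noise, fraction of amplitude range
    baseline_drift_per_s: float = 0.0      # linear drift, fraction of baseline
    crosstalk: tuple[float, float, float] = (0.0, 0.0, 0.0)  # onset ms, duration ms, amplitude
    terminate_at_ms: float | None = None   # rotation stops; plateau until light-off
    t0_ms: float = 0.0                     # time origin of the rotation phase
    seed: int = 0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("movie duration must be positive")
        if self.px_size_mm <= 0 or self.frame_rate_hz <= 0 or self.rotation_hz < 0:
            raise ValueError("physical fields must be positive")


def _ap_waveform(phase: np.ndarray, apd_fraction: float) -> np.ndarray:
    """Normalized fluorescence vs cycle phase in [0, 1): sharp upstroke,
    brief plateau, exponential repolarization, diastole at 0."""
    out = np.zeros_like(phase)
    up = 0.03
    rise = phase < up
    out[rise] = phase[rise] / up
    decay = (phase >= up) & (phase < apd_fraction + 0.2)
    tau = 0.45 * apd_fraction
    out[decay] = np.exp(-(phase[decay] - up) / tau)
    return out


def generate_movie(spec: MovieSpec) -> tuple[np.ndarray, dict]:
    """Render the movie and its ground-truth record.

    Returns ``(frames, truth)``: frames are float64 fluorescence images of
    shape (n_frames, ny, nx); ``truth`` carries the planted rotation
    frequency, per-frame core radii, the light-intensity trace for crosstalk
    renormalization, the clean probe trace, and the last-arrhythmia-peak time
    computed from the noiseless probe signal.
    """
    ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.frame_rate_hz
    n = int(round(spec.duration_ms / dt))
    times = np.arange(n) * dt

    cx, cy = spec.core_center_mm or (nx * spec.px_size_mm / 2, ny * spec.px_size_mm / 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    xm = xx * spec.px_size_mm
    ym = yy * spec.px_size_mm
    r = np.hypot(xm - cx, ym - cy)
    theta = np.arctan2(ym - cy, xm - cx)

    on, dur, amp_ct = spec.crosstalk
    t_off = on + dur
    probe_rc = (ny // 4, 3 * nx // 4)

    clean = np.empty((n, ny, nx))
    radii = np.full(n, np.nan)
    f_rot = spec.rotation_hz
    for k, t in enumerate(times):
        if spec.terminate_at_ms is not None and t >= spec.terminate_at_ms:
            if t < t_off or dur == 0.0:
                level = 0.75  # uniformly excited, elevated plateau
            else:
                level = 0.75 * np.exp(-(t - t_off) / 30.0)
            frame = np.full((ny, nx), level)
        else:
            phase = (f_rot * (t - spec.t0_ms) / 1000.0 - theta / (2 * np.pi) - r / spec.wavelength_mm) % 1.0
            frame = _ap_waveform(phase, spec.apd_fraction)
        # unexcited core: sub-threshold interior, planted radius; gone once
        # the spiral has terminated
        spiral_active = spec.terminate_at_ms is None or t < spec.terminate_at_ms
        if spiral_active:
            if on <= t < t_off:
                radius = spec.core_radius0_mm + spec.core_growth_mm_per_ms * (t - on)
            else:
                radius = spec.core_radius0_mm if spec.core_growth_mm_per_ms == 0 else np.nan
        else:
            radius = np.nan
        if np.isfinite(radius):
            # refractory gap just outside the dissolving boundary, then the
            # depolarized interior: the arm is pushed outward as the core grows
            frame = np.where((r > radius) & (r <= radius + 0.45), 0.0, frame)
            frame = np.where(r <= radius, 0.72, frame)
            radii[k] = radius
        clean[k] = frame

    probe_clean = clean[:, probe_rc[0], probe_rc[1]].copy()

    # fluorescence scale: baseline 1 + amplitude * activity, drift, crosstalk
    light = np.ones(n)
    light[(times >= on) & (times < t_off)] += amp_ct
    frames = 1.0 + spec.amplitude * clean
    frames += (spec.baseline_drift_per_s * times[:, None, None] / 1000.0)
    frames *= light[:, None, None]
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma * spec.amplitude, frames.shape)

    last_peak = _last_peak_time(probe_clean, times)
    truth = {
        "rotation_hz": f_rot,
        "times_ms": times,
        "core_radii_mm": radii,
        "light_signal": light,
        "probe_rc": probe_rc,
        "probe_clean": probe_clean,
        "last_peak_ms": last_peak,
        "spec": asdict(spec),
    }
    return frames, truth


def _last_peak_time(trace: np.ndarray, times: np.ndarray) -> float | None:
    """Last arrhythmia peak of the (noise-free) generator trace.

    Same definition the analysis stage uses: a strict local maximum of the
    activity followed by a genuine downstroke (activity below 0.4 within
    60 ms), which excludes the sustained light-driven plateau.
    """
    dt = float(times[1] - times[0])
    nwin = int(round(60.0 / dt))
    interior = (trace[1:-1] > trace[:-2]) & (trace[1:-1] > trace[2:]) & (trace[1:-1] > 0.5)
    idx = np.nonzero(interior)[0] + 1
    good = [i for i in idx if np.min(trace[i:i + nwin]) < 0.4]
    return float(times[good[-1]]) if good else None


def renormalize_crosstalk(signal: np.ndarray, light_signal: np.ndarray) -> np.ndarray:
    """Divide the optical signal by the recorded stimulation-light signal.

    Removes the uniform fluorescence offset caused by crosstalk between the
    blue stimulation light and the voltage dye.  ``signal`` is a trace (T,)
    or movie (T, ny, nx); ``light_signal`` a strictly positive trace (T,).
    """
    signal = np.asarray(signal, dtype=float)
    light_signal = np.asarray(light_signal, dtype=float)
    if light_signal.ndim != 1 or light_signal.shape[0] != signal.shape[0]:
        raise ValueError("light signal must be a trace time-aligned with the signal")
    if np.any(light_signal <= 0):
        raise ValueError("light signal must be strictly positive everywhere")
    if signal.ndim == 1:
        return signal / light_signal
    return signal / light_signal[:, None, None]


def fluorescence_to_mv(frames: np.ndarray, amplitude: float = 0.25) -> np.ndarray:
    """Map renormalized fluorescence (baseline 1.0) onto the calibrated
    voltage scale (rest −80 mV, full amplitude +20 mV)."""
    return REST_MV + (np.asarray(frames, dtype=float) - 1.0) / amplitude * (PEAK_MV - REST_MV)


def movie_recording(frames: np.ndarray, truth: dict, renormalize: bool = True) -> Recording:
    """Package a synthetic movie as a :class:`~optospiral.tissue.Recording`.

    Applies crosstalk renormalization (unless disabled), converts to the mV
    scale, and wires the generator's probe pixel so the full analysis
    pipeline runs unchanged on synthetic data.
    """
    spec = truth["spec"]
    if renormalize:
        frames = renormalize_crosstalk(frames, truth["light_signal"])
    mv = fluorescence_to_mv(frames, spec["amplitude"])
    times = np.asarray(truth["times_ms"], dtype=float)
    pr, pc = truth["probe_rc"]
    on, dur, _ = spec["crosstalk"]
    log = [{"li": np.nan, "pl": dur, "t_on": on, "spatial_mode": "global-uniform"}] if dur else []
    meta = {
        "params": {"dx": spec["px_size_mm"] / 10.0},  # cm, for the analysis ops
        "synthetic": True,
        "spec": spec,
    }
    return Recording(frames=mv, frame_times=times,
                     probes={"p0": mv[:, pr, pc]}, probe_times=times,
                     light_log=log, meta=meta)


def write_movie(frames: np.ndarray, truth: dict, directory: str | Path, stem: str = "movie") -> Path:
    """Write the movie as a multi-page TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif = directory / f"{stem}.tif"
    tifffile.imwrite(tif, frames.astype(np.float32))
    sidecar = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in truth.items()}
    (directory / f"{stem}.truth.json").write_text(json.dumps(sidecar, indent=1))
    return tif
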