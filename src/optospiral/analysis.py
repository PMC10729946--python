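"""Measurement procedures on voltage movies.

Implements the quantitative pipeline used to characterize spiral-wave
dynamics and their optogenetic termination: space–time plots, spiral-tip
(phase-singularity) tracking, core measurement by Canny edge detection plus
circular Hough transform, core-growth regression, termination detection and
timing, and dominant-frequency estimation.  All operations run identically
on solver recordings and on synthetic optical-mapping movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, periodogram
from shapely import MultiPoint, minimum_bounding_radius
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import InsufficientDataError, NoCoreError, NoPeakError
from .tissue import LightPulse, Recording


@dataclass
class CoreTrack:
    """Per-frame fitted core circles at a 10-ms cadence."""

    times: np.ndarray          # ms
    centers: np.ndarray        # (n, 2) in mm, (x, y)
    radii: np.ndarray          # mm
    fit_quality: np.ndarray    # mean radial residual, px


@dataclass
class CoreGrowthFit:
    """Ordinary-least-squares line through (time, core radius)."""

    slope: float               # mm/ms
    intercept: float           # mm
    r_squared: float


@dataclass
class TerminationResult:
    terminated: bool
    t_term: float | None = None          # ms from light-on to last arrhythmia peak
    n_rotations_during_light: int = 0
    peak_times: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------

def space_time_plot(rec: Recording, row_y_mm: float, dx_mm: float | None = None) -> np.ndarray:
    """V(x, t) along the horizontal row nearest to ``row_y_mm``.

    Returns an (nx, n_frames) matrix (space × time, mV).
    """
    if dx_mm is None:
        dx_mm = rec.meta.get("params", {}).get("dx", 0.025) * 10.0
    ny = rec.frames.shape[1]
    row = int(round(row_y_mm / dx_mm))
    if row < 0 or row >= ny:
        raise ValueError(f"row_y = {row_y_mm} mm outside the domain")
    return rec.frames[:, row, :].T.copy()


def _plaquette_singularities(f, g, dx_mm):
    """Intersections of the zero contours of f and g, one per 2x2 plaquette.

    On each plaquette whose corners straddle zero in both fields, the two
    bilinear interpolants f(r,s) = a0 + a1 r + a2 s + a3 rs and likewise g
    are solved exactly: eliminating r yields a quadratic in s, and only real
    intersections inside the unit cell are accepted.  Sub-node accuracy is
    adequate for tip tracking (< 1 node error on rigid rotors).
    """
    fs = np.signbit(f)
    gs = np.signbit(g)
    out = []
    cand_f = (fs[:-1, :-1] != fs[:-1, 1:]) | (fs[:-1, :-1] != fs[1:, :-1]) | (fs[:-1, :-1] != fs[1:, 1:])
    cand_g = (gs[:-1, :-1] != gs[:-1, 1:]) | (gs[:-1, :-1] != gs[1:, :-1]) | (gs[:-1, :-1] != gs[1:, 1:])
    eps = 1e-4
    for i, j in zip(*np.nonzero(cand_f & cand_g)):
        a0 = f[i, j]
        a1 = f[i, j + 1] - a0
        a2 = f[i + 1, j] - a0
        a3 = f[i + 1, j + 1] - f[i + 1, j] - f[i, j + 1] + a0
        b0 = g[i, j]
        b1 = g[i, j + 1] - b0
        b2 = g[i + 1, j] - b0
        b3 = g[i + 1, j + 1] - g[i + 1, j] - g[i, j + 1] + b0
        # r = -(a0 + a2 s)/(a1 + a3 s); substitute into g = 0:
        # (b1 + b3 s)(-(a0 + a2 s)) + (b0 + b2 s)(a1 + a3 s) = 0
        qa = b2 * a3 - b3 * a2
        qb = b0 * a3 + b2 * a1 - b1 * a2 - b3 * a0
        qc = b0 * a1 - b1 * a0
        roots = []
        if abs(qa) < 1e-14:
            if abs(qb) > 1e-14:
                roots = [-qc / qb]
        else:
            disc = qb * qb - 4 * qa * qc
            if disc >= 0:
                sq = np.sqrt(disc)
                roots = [(-qb + sq) / (2 * qa), (-qb - sq) / (2 * qa)]
        for s in roots:
            if not (-eps <= s <= 1 + eps):
                continue
            den = a1 + a3 * s
            if abs(den) < 1e-14:
                continue
            r = -(a0 + a2 * s) / den
            if -eps <= r <= 1 + eps:
                out.append(((j + r) * dx_mm, (i + s) * dx_mm))
    return out


def tip_trajectory(
    rec: Recording,
    v_iso: float = -50.0,
    merge_radius_mm: float = 0.5,
) -> list[tuple[float, float, float]]:
    """Phase-singularity (spiral tip) locations per frame.

    The tip is the intersection of the V = ``v_iso`` isoline with its own
    dV/dt = 0 line, evaluated between consecutive frames.  Detections closer
    than ``merge_radius_mm`` within a frame are duplicate hits of one
    singularity in adjacent plaquettes and are merged to their centroid.
    Returns a list of (t, x_mm, y_mm); frames without a singularity
    contribute nothing (an empty result is a valid outcome, e.g. for plane
    waves).
    """
    dx_mm = rec.meta.get("params", {}).get("dx", 0.025) * 10.0
    out = []
    for k in range(rec.frames.shape[0] - 1):
        f = rec.frames[k] - v_iso
        g = rec.frames[k + 1] - rec.frames[k]
        pts = _plaquette_singularities(f, g, dx_mm)
        for x, y in _merge_points(pts, merge_radius_mm):
            out.append((float(rec.frame_times[k]), x, y))
    return out


def _merge_points(pts, radius):
    """Greedy centroid merge of detections closer than ``radius``."""
    clusters: list[list] = []
    for x, y in pts:
        for c in clusters:
            cx = np.mean([p[0] for p in c])
            cy = np.mean([p[1] for p in c])
            if np.hypot(cx - x, cy - y) < radius:
                c.append((x, y))
                break
        else:
            clusters.append([(x, y)])
    return [(float(np.mean([p[0] for p in c])), float(np.mean([p[1] for p in c])))
            for c in clusters]


def trajectory_diameter(tips: list[tuple[float, float, float]]) -> float:
    """Diameter (mm) of the smallest circle enclosing the tip positions."""
    if len(tips) < 2:
        raise InsufficientDataError("need at least two tip positions")
    pts = MultiPoint([(x, y) for _, x, y in tips])
    return 2.0 * float(minimum_bounding_radius(pts))


def core_trough_width(rec: Recording, row_y_mm: float, v_threshold: float = -50.0) -> float:
    """Width (mm) of the never-above-threshold voltage trough along a row.

    Cross-check for the tip-trajectory core size: the unexcited core shows up
    as a contiguous run of nodes whose voltage never crosses ``v_threshold``
    over the recording.
    """
    st = space_time_plot(rec, row_y_mm)
    dx_mm = rec.meta.get("params", {}).get("dx", 0.025) * 10.0
    never = (st.max(axis=1) < v_threshold).astype(int)
    # longest run of quiescent nodes excluding the boundaries
    best = cur = 0
    for k in range(1, len(never) - 1):
        cur = cur + 1 if never[k] else 0
        best = max(best, cur)
    return best * dx_mm


# ---------------------------------------------------------------------------
# Core measurement (Canny + circular Hough)
# ---------------------------------------------------------------------------

def _core_candidates(frame, v_threshold, px_size_mm, radius_range=(3, 45),
                     canny_sigma=1.0, min_accum=0.5, n_peaks=5):
    """Strong circular-Hough candidates (x_mm, y_mm, r_mm, accum) for one frame."""
    from scipy.ndimage import binary_closing, binary_opening

    binary = np.asarray(frame, dtype=float) > v_threshold
    # remove speckle noise and pinholes before edge detection
    binary = binary_closing(binary_opening(binary, np.ones((2, 2))), np.ones((2, 2)))
    binary = binary.astype(float)
    if binary.sum() < 4 or binary.mean() > 0.97:
        raise NoCoreError("no bounded depolarized region in frame")
    edges = canny(binary, sigma=canny_sigma, low_threshold=0.1, high_threshold=0.3)
    if edges.sum() < 6:
        raise NoCoreError("no edge structure in frame")
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=n_peaks)
    cands = [(float(cx[k]) * px_size_mm, float(cy[k]) * px_size_mm,
              float(rad[k]) * px_size_mm, float(accums[k]))
             for k in range(len(accums)) if accums[k] >= min_accum]
    if not cands:
        raise NoCoreError("Hough accumulator below floor; no circular core")
    return cands, edges


def _radial_residual(edges, cx_mm, cy_mm, r_mm, px_size_mm):
    ey, ex = np.nonzero(edges)
    d = np.hypot(ex - cx_mm / px_size_mm, ey - cy_mm / px_size_mm)
    r_px = r_mm / px_size_mm
    near = d[np.abs(d - r_px) < max(3.0, 0.5 * r_px)]
    return float(np.mean(np.abs(near - r_px))) if len(near) else float("nan")


def core_radius(
    frame: np.ndarray,
    v_threshold: float = -50.0,
    px_size_mm: float = 0.25,
    radius_range: tuple[int, int] = (3, 45),
    canny_sigma: float = 1.0,
    min_accum: float = 0.5,
    near: tuple[float, float] | None = None,
) -> tuple[tuple[float, float], float, float]:
    """Fit a circle to the depolarized core region of one voltage frame.

    The frame is binarized at ``v_threshold`` (with light morphological
    cleanup), edges are detected with the Canny filter, and a circle is
    fitted with the circular Hough transform over ``radius_range`` (pixels).
    When ``near`` is given, the strongest candidate closest to that centre
    (mm) is preferred — used for temporal consistency when tracking a
    dissolving core.  Returns ((x, y) mm, radius mm, mean radial residual
    px).  Raises :class:`NoCoreError` when no candidate clears the Hough
    accumulator floor — which is also how completed dissolution is detected.
    """
    cands, edges = _core_candidates(frame, v_threshold, px_size_mm,
                                    radius_range, canny_sigma, min_accum)
    if near is not None:
        cx, cy, r, _ = min(cands, key=lambda c: np.hypot(c[0] - near[0], c[1] - near[1]))
    else:
        cx, cy, r, _ = cands[0]
    quality = _radial_residual(edges, cx, cy, r, px_size_mm)
    return ((cx, cy), r, quality)


def core_growth(
    rec: Recording,
    pulse: LightPulse,
    v_threshold: float = -50.0,
    interval: float = 10.0,
    consensus_mm: float = 1.5,
    **core_kwargs,
) -> tuple[CoreTrack, CoreGrowthFit]:
    """Track the dissolving core every ``interval`` ms during the light pulse
    and fit radius-vs-time by ordinary least squares.

    Tracking starts at light onset and stops at light-off or when no circular
    core can be fitted any more (dissolution reached the boundary).  Circle
    candidates are selected by centre consensus: a first pass fixes the
    robust (median) core centre, and each frame then contributes the strong
    candidate nearest that centre; frames whose best candidate lies further
    than ``consensus_mm`` from the consensus are treated as detection
    failures and skipped.
    """
    dx_mm = rec.meta.get("params", {}).get("dx", 0.025) * 10.0
    t_end = min(pulse.t_on + pulse.pl, rec.frame_times[-1])
    if pulse.t_on > rec.frame_times[-1]:
        raise ValueError("pulse does not overlap the recording")
    sample_times = np.arange(pulse.t_on, t_end + 1e-9, interval)
    per_frame = []
    for t in sample_times:
        k = int(np.argmin(np.abs(rec.frame_times - t)))
        try:
            cands, edges = _core_candidates(rec.frames[k], v_threshold, dx_mm,
                                            **core_kwargs)
        except NoCoreError:
            per_frame.append((float(rec.frame_times[k]), None, None))
            continue
        per_frame.append((float(rec.frame_times[k]), cands, edges))
    # consensus centre from the strongest candidate of each usable frame
    tops = [c[0] for _, c, _ in per_frame if c]
    if not tops:
        raise InsufficientDataError("no core candidates in any sampled frame")
    cx0 = float(np.median([c[0] for c in tops]))
    cy0 = float(np.median([c[1] for c in tops]))

    times, centers, radii, quality = [], [], [], []
    for t, cands, edges in per_frame:
        if cands is None:
            if times:
                break
            continue
        near = [c for c in cands if np.hypot(c[0] - cx0, c[1] - cy0) <= consensus_mm]
        if not near:
            continue
        # strongest accumulator among centre-consistent candidates
        cx, cy, r, _ = max(near, key=lambda c: c[3])
        times.append(t)
        centers.append((cx, cy))
        radii.append(r)
        quality.append(_radial_residual(edges, cx, cy, r, dx_mm))
    if len(radii) < 3:
        raise InsufficientDataError(
            f"only {len(radii)} valid core radii; need >= 3 for a growth fit")
    times = np.asarray(times)
    radii = np.asarray(radii)
    centers = np.asarray(centers)
    quality = np.asarray(quality)
    # ordinary least squares with residual trimming: isolated mis-fits (the
    # spiral-arm curvature caught instead of the core boundary) are dropped
    keep = np.ones(len(radii), dtype=bool)
    for _ in range(2):
        slope, intercept = np.polyfit(times[keep] - times[0], radii[keep], 1)
        resid = radii - (slope * (times - times[0]) + intercept)
        tol = max(2.5 * float(np.sqrt(np.mean(resid[keep] ** 2))), 0.15)
        new_keep = np.abs(resid) <= tol
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    slope, intercept = np.polyfit(times[keep] - times[0], radii[keep], 1)
    pred = slope * (times[keep] - times[0]) + intercept
    ss_res = float(np.sum((radii[keep] - pred) ** 2))
    ss_tot = float(np.sum((radii[keep] - radii[keep].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    track = CoreTrack(times=times[keep], centers=centers[keep],
                      radii=radii[keep], fit_quality=quality[keep])
    return track, CoreGrowthFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


# ---------------------------------------------------------------------------
# Termination
# ---------------------------------------------------------------------------

def arrhythmia_peaks(
    trace: np.ndarray,
    times: np.ndarray,
    prominence: float = 20.0,
    min_separation: float = 10.0,
    downstroke_mv: float = -40.0,
    downstroke_window: float = 60.0,
) -> np.ndarray:
    """Times of counted arrhythmia peaks in a probe trace.

    A peak is a local maximum with the stated prominence and separation that
    is followed by a genuine downstroke (the trace falls below
    ``downstroke_mv`` within ``downstroke_window`` ms); the sustained
    light-driven elevated phase therefore contributes no peaks.
    """
    dt = float(times[1] - times[0])
    idx, _ = find_peaks(trace, prominence=prominence,
                        distance=max(1, int(round(min_separation / dt))))
    keep = []
    nwin = int(round(downstroke_window / dt))
    for i in idx:
        seg = trace[i:i + nwin]
        if seg.size and seg.min() < downstroke_mv:
            keep.append(i)
    return times[np.asarray(keep, dtype=int)] if keep else np.array([])


def detect_termination(
    rec: Recording,
    pulse: LightPulse,
    probe: str | None = None,
    quiescent_mv: float = -70.0,
    quiescence_window: float = 100.0,
    relaxation: float = 100.0,
) -> TerminationResult:
    """Decide whether the pulse terminated the arrhythmia and time it.

    Terminated means: after light-off plus a ``relaxation`` window, the whole
    domain stays below ``quiescent_mv`` for ``quiescence_window`` ms (no
    activity, hence no remaining phase singularity).  The termination time is
    the interval from light onset to the last counted arrhythmia peak of the
    probe trace (the light-driven elevated plateau is excluded by the
    downstroke rule in :func:`arrhythmia_peaks`).
    """
    t_off = pulse.t_on + pulse.pl
    if rec.frame_times[-1] < t_off + relaxation + quiescence_window - 1e-6:
        raise ValueError("recording too short: need pulse + relaxation "
                         f"+ {quiescence_window} ms of frames")
    name = probe or next(iter(rec.probes))
    trace = rec.probes[name]
    times = rec.probe_times

    tail = rec.frame_times >= (rec.frame_times[-1] - quiescence_window)
    quiet = bool(rec.frames[tail].max() < quiescent_mv)

    peaks = arrhythmia_peaks(trace, times)
    peaks_after_on = peaks[peaks >= pulse.t_on] if peaks.size else peaks
    if not quiet:
        return TerminationResult(terminated=False, peak_times=peaks)
    if peaks_after_on.size == 0:
        # terminated with no counted peak after onset: immediate annihilation
        return TerminationResult(terminated=True, t_term=0.0,
                                 n_rotations_during_light=0, peak_times=peaks)
    t_last = float(peaks_after_on[-1])
    n_rot = int(np.sum((peaks_after_on >= pulse.t_on) & (peaks_after_on < t_off)))
    return TerminationResult(terminated=True, t_term=t_last - pulse.t_on,
                             n_rotations_during_light=n_rot, peak_times=peaks)


def dominant_frequency(
    trace: np.ndarray,
    times: np.ndarray,
    dc_floor_hz: float = 2.0,
) -> tuple[float, float]:
    """Peak of the power spectrum above a DC-exclusion floor.

    Returns (frequency Hz, spectral resolution Hz).  Raises
    :class:`NoPeakError` for traces without oscillatory content.
    """
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) < 1e-9:
        raise NoPeakError("constant trace has no spectral peak")
    dt_s = float(times[1] - times[0]) * 1e-3
    f, p = periodogram(trace - trace.mean(), fs=1.0 / dt_s)
    resolution = f[1] - f[0]
    sel = f >= dc_floor_hz
    if not np.any(sel) or p[sel].max() <= 0:
        raise NoPeakError("no spectral peak above the DC floor")
    return float(f[sel][np.argmax(p[sel])]), float(resolution)
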