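"""Accelerations, behavioral phase segmentation, and joint angles.

The four jump phases are recovered from the hindpaw acceleration trace,
whose canonical shape is: quiet baseline through preparation, a fast rise
through propulsion, a sudden drop when the paw leaves the platform, a low
plateau through ballistic flight, and a sharp rise again at touch-down.
Boundary detection is threshold-based and scale-free (thresholds are
multiples of a baseline spread), so multiplying the trace by any positive
constant leaves the segmentation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .errors import SegmentationError
from .records import PHASES, TrialRecording
from .synth import JOINT_TRIPLETS

DEFAULT_SMOOTH_WINDOW = 11
DEFAULT_SMOOTH_ORDER = 3


def smoothing_halfwidth(frame_rate: float,
                        smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> int:
    """Frames contaminated on each side of a discontinuity by the smoother."""
    return smooth_window // 2


@dataclass
class PhaseSegmentation:
    """Frame boundaries of the four phases.

    ``boundaries`` holds (preparation->propulsion, propulsion->flight i.e.
    takeoff, flight->landing); phases are half-open frame intervals.
    """

    boundaries: tuple[int, int, int]
    n_frames: int
    labels: tuple[str, ...] = PHASES
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b1, b2, b3 = self.boundaries
        if not (0 < b1 < b2 < b3 < self.n_frames):
            raise SegmentationError(
                f"non-monotone phase boundaries {self.boundaries}"
            )

    @property
    def takeoff_frame(self) -> int:
        return self.boundaries[1]

    def phase_of_frame(self, frame: int) -> str:
        b1, b2, b3 = self.boundaries
        if frame < b1:
            return "preparation"
        if frame < b2:
            return "propulsion"
        if frame < b3:
            return "flight"
        return "landing"

    def phase_slice(self, phase: str) -> slice:
        b1, b2, b3 = self.boundaries
        return {
            "preparation": slice(0, b1), "propulsion": slice(b1, b2),
            "flight": slice(b2, b3), "landing": slice(b3, self.n_frames),
        }[phase]


@dataclass
class JointAngleSeries:
    joint: str
    triplet: tuple[str, str, str]
    angle_deg: np.ndarray  # NaN where undefined

    @property
    def n_frames(self) -> int:
        return self.angle_deg.size


def compute_acceleration(
    trial: TrialRecording,
    landmark: str = "hindpaw",
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
    per_axis: bool = False,
) -> np.ndarray:
    """Savitzky-Golay second derivative of a landmark trajectory, mm/s^2.

    Returns the acceleration magnitude (norm over x/y) by default, or the
    (T, 2) per-axis components with ``per_axis=True``.  Edges are handled
    by the filter's polynomial fit on truncated windows.
    """
    if smooth_window % 2 == 0 or smooth_window <= smooth_order:
        raise ValueError("smooth_window must be odd and > smooth_order")
    pos = trial.landmark(landmark)
    if pos.shape[0] < smooth_window:
        raise ValueError(
            f"trial has {pos.shape[0]} frames < smooth_window {smooth_window}"
        )
    acc = savgol_filter(
        pos, smooth_window, smooth_order, deriv=2,
        delta=1.0 / trial.frame_rate, axis=0, mode="interp",
    )
    if per_axis:
        return acc
    return np.linalg.norm(acc, axis=1)


def segment_phases(
    accel: np.ndarray,
    frame_rate: float,
    rise_k: float = 3.0,
    fall_k: float = 3.0,
    min_phase_ms: float = 20.0,
    baseline_ms: float = 100.0,
    prop_search_ms: float = 100.0,
    sigma_floor_frac: float = 0.02,
    _relaxed: bool = False,
) -> PhaseSegmentation:
    """Detect the four jump phases from an acceleration-magnitude trace.

    Steps: (1) baseline level and robust spread (median/MAD of a lightly
    averaged trace) from the initial ``baseline_ms`` window, with the
    spread floored at ``sigma_floor_frac`` of the dynamic range so
    noiseless traces are well-posed; (2) propulsion onset = first
    sustained run above ``mu + rise_k*sigma``; (3) takeoff = the steepest
    sustained drop within ``prop_search_ms`` of onset, scored as the
    difference of short means before/after each candidate frame; (4)
    landing onset = first sustained run above the flight plateau level
    (estimated just past the takeoff transient) plus ``rise_k*sigma``.
    Phases shorter than ``min_phase_ms`` trigger one re-search with a
    relaxed rise threshold, then failure.
    """
    a = np.asarray(accel, dtype=float)
    t = a.size
    fpm = frame_rate / 1000.0
    nb = max(3, int(round(baseline_ms * fpm)))
    if t < nb + 6:
        raise SegmentationError("series too short for baseline estimation")
    # short moving average for level/threshold decisions; the raw trace is
    # kept for the takeoff drop localization
    s = uniform_filter1d(a, size=5, mode="nearest")
    mu = float(np.median(s[:nb]))
    # robust spread (MAD) so outlier baseline frames do not inflate the
    # detection threshold
    sigma = float(1.4826 * np.median(np.abs(s[:nb] - mu)))
    dyn = float(s.max() - mu)
    if dyn <= 0:
        raise SegmentationError("flat acceleration trace; no jump detected")
    sigma_eff = max(sigma, sigma_floor_frac * dyn)
    thresh = mu + rise_k * sigma_eff

    run_len = max(3, int(round(min_phase_ms * fpm)) // 2)

    def first_sustained(start: int, stop: int, level: float, run: int = 3) -> int | None:
        above = s[start:stop] > level
        if above.size < run:
            return None
        ok = np.convolve(above.astype(int), np.ones(run, int), "valid") == run
        hits = np.flatnonzero(ok)
        return None if hits.size == 0 else start + int(hits[0])

    # (2) propulsion onset
    onset = first_sustained(nb // 2, t, thresh, run=run_len)
    if onset is None:
        raise SegmentationError(
            f"no sustained rise above baseline + {rise_k} sigma; "
            "cannot locate propulsion onset"
        )

    # (3) takeoff: steepest sustained drop within the propulsion search
    # window, scored as the difference of short means before/after each
    # candidate frame (robust to frame-to-frame noise)
    search_end = min(t - 1, onset + int(round(prop_search_ms * fpm)))
    if search_end <= onset + 4:
        raise SegmentationError("no room after propulsion onset for takeoff search")
    span = 4
    best, takeoff = -np.inf, None
    for i in range(onset + 1, search_end):
        pre = a[max(0, i - span):i]
        post = a[i:min(t, i + span)]
        score = pre.mean() - post.mean()
        if score > best:
            best, takeoff = score, i
    if takeoff is None or best <= 0:
        raise SegmentationError("no acceleration drop found after propulsion onset")

    # (4) landing: sustained excursion above the flight level
    if t - takeoff < 8:
        raise SegmentationError("no frames after takeoff")
    # flight level from a short window past the takeoff transient (the
    # smoothing window smears the takeoff drop over halfwidth + averaging
    # frames, which must not leak into the level estimate or the search)
    skip = smoothing_halfwidth(frame_rate) + 2
    win = max(3, int(round(min_phase_ms * fpm)))
    flo = min(takeoff + skip, t - win - 1)
    flight_level = float(np.median(s[flo:flo + win]))
    search_start = min(takeoff + max(skip + 2, int(round(min_phase_ms * fpm))),
                       t - run_len)
    landing = first_sustained(
        search_start, t, flight_level + rise_k * sigma_eff, run=run_len
    )
    if landing is None:
        raise SegmentationError("no landing rise found after flight minimum")

    boundaries = (int(onset), int(takeoff), int(landing))
    params = {
        "rise_k": rise_k, "fall_k": fall_k, "min_phase_ms": min_phase_ms,
        "baseline_mu": mu, "baseline_sigma": sigma_eff,
        "flight_level": flight_level, "relaxed": _relaxed,
    }
    try:
        seg = PhaseSegmentation(boundaries=boundaries, n_frames=t, parameters=params)
    except SegmentationError:
        seg = None
    min_frames = min_phase_ms * fpm
    ok = seg is not None and all(
        (seg.phase_slice(p).stop - seg.phase_slice(p).start) >= min_frames
        for p in PHASES
    )
    if not ok:
        if not _relaxed:
            return segment_phases(
                accel, frame_rate, rise_k=max(1.5, rise_k / 2),
                fall_k=fall_k, min_phase_ms=min_phase_ms,
                baseline_ms=baseline_ms, prop_search_ms=prop_search_ms,
                sigma_floor_frac=sigma_floor_frac, _relaxed=True,
            )
        raise SegmentationError(
            f"segmentation produced degenerate phases at boundaries {boundaries}"
        )
    return seg


def compute_joint_angles(
    trial: TrialRecording,
    triplets: dict[str, tuple[str, str, str]] | None = None,
) -> list[JointAngleSeries]:
    """Interior angle at each joint vertex, degrees, NaN where undefined.

    angle = arccos(<a-v, b-v> / (|a-v| |b-v|)) for triplet (a, v, b);
    zero-length segments (or gap-propagated NaNs) yield NaN for that frame.
    """
    triplets = triplets or JOINT_TRIPLETS
    out = []
    for joint, (a_name, v_name, b_name) in triplets.items():
        a = trial.landmark(a_name)
        v = trial.landmark(v_name)
        b = trial.landmark(b_name)
        u1, u2 = a - v, b - v
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (u1 * u2).sum(axis=1) / (n1 * n2)
        bad = (n1 == 0) | (n2 == 0) | ~np.isfinite(cosang)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ang[bad] = np.nan
        out.append(JointAngleSeries(joint=joint, triplet=(a_name, v_name, b_name),
                                    angle_deg=ang))
    return out


def phase_durations(seg: PhaseSegmentation, frame_rate: float) -> dict[str, float]:
    """Duration of each phase in ms (half-open frame intervals)."""
    b1, b2, b3 = seg.boundaries
    to_ms = 1000.0 / frame_rate
    return {
        "preparation": b1 * to_ms,
        "propulsion": (b2 - b1) * to_ms,
        "flight": (b3 - b2) * to_ms,
        "landing": (seg.n_frames - b3) * to_ms,
    }
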