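"""Reading, writing, cleaning and takeoff-aligning tracked trials.

Two pose-table dialects are supported:

* ``dlc3row`` — the pose-estimation CSV convention with a three-row header
  (scorer / bodyparts / coords) and x, y, likelihood columns per landmark;
* ``widecsv`` — a plain wide table with ``<landmark>_x, <landmark>_y``
  (and optional ``<landmark>_likelihood``) columns.

Cells whose likelihood falls below a confidence threshold become explicit
gaps (NaN positions) that downstream cleaning may interpolate.  All tables
are UTF-8, comma-separated, '.' decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .records import EMGRecording, StimEpoch, TrialRecording

DEFAULT_CONFIDENCE_MIN = 0.5
DEFAULT_MAX_GAP = 5


# ---------------------------------------------------------------------------
# pose tables


def write_pose_table(trial: TrialRecording, path: str | Path,
                     dialect: str = "dlc3row", scorer: str = "gapcross") -> None:
    path = Path(path)
    t, names = trial.n_frames, trial.landmarks
    if dialect == "dlc3row":
        cols = pd.MultiIndex.from_tuples(
            [(scorer, n, c) for n in names for c in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.empty((t, len(names) * 3))
        for j, n in enumerate(names):
            data[:, 3 * j] = trial.positions[:, j, 0]
            data[:, 3 * j + 1] = trial.positions[:, j, 1]
            data[:, 3 * j + 2] = trial.confidence[:, j]
        pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame", float_format="%.17g")
    elif dialect == "widecsv":
        out = {"frame": np.arange(t)}
        for j, n in enumerate(names):
            out[f"{n}_x"] = trial.positions[:, j, 0]
            out[f"{n}_y"] = trial.positions[:, j, 1]
            out[f"{n}_likelihood"] = trial.confidence[:, j]
        pd.DataFrame(out).to_csv(path, index=False, float_format="%.17g")
    else:
        raise FormatError(f"unknown pose dialect {dialect!r}")
    sidecar = {
        "trial_id": trial.trial_id,
        "animal_id": trial.animal_id,
        "frame_rate": trial.frame_rate,
        "takeoff_frame": trial.takeoff_frame,
        "gap_distance": trial.gap_distance,
        "condition": trial.condition,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def _read_dlc3row(path: Path) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as err:
        raise FormatError(f"{path}: not a 3-row-header pose table ({err})") from err
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected scorer/bodyparts/coords header rows")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    t = len(df)
    pos = np.full((t, len(bodyparts), 2), np.nan)
    conf = np.ones((t, len(bodyparts)))
    for j, bp in enumerate(bodyparts):
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        missing = {"x", "y"} - set(sub.columns)
        if missing:
            raise FormatError(
                f"{path}: landmark {bp!r} header row lacks columns {sorted(missing)}"
            )
        pos[:, j, 0] = pd.to_numeric(sub["x"], errors="coerce")
        pos[:, j, 1] = pd.to_numeric(sub["y"], errors="coerce")
        if "likelihood" in sub.columns:
            conf[:, j] = pd.to_numeric(sub["likelihood"], errors="coerce")
    return tuple(bodyparts), pos, conf


def _read_widecsv(path: Path) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    names = []
    for c in df.columns:
        if c.endswith("_x"):
            names.append(c[:-2])
    if not names:
        raise FormatError(f"{path}: header row has no '<landmark>_x' columns")
    t = len(df)
    pos = np.full((t, len(names), 2), np.nan)
    conf = np.ones((t, len(names)))
    for j, n in enumerate(names):
        if f"{n}_y" not in df.columns:
            raise FormatError(f"{path}: column {n}_y missing (mixed landmark columns)")
        pos[:, j, 0] = pd.to_numeric(df[f"{n}_x"], errors="coerce")
        pos[:, j, 1] = pd.to_numeric(df[f"{n}_y"], errors="coerce")
        lk = f"{n}_likelihood"
        if lk in df.columns:
            conf[:, j] = pd.to_numeric(df[lk], errors="coerce")
    return tuple(names), pos, conf


def read_pose_table(
    path: str | Path,
    dialect: str = "dlc3row",
    confidence_min: float = DEFAULT_CONFIDENCE_MIN,
    flip_y: bool = False,
    frame_rate: float | None = None,
) -> TrialRecording:
    """Read a pose table; low-confidence cells become explicit gaps.

    ``flip_y`` converts image-convention coordinates (y down) to the
    package's y-up convention.  Metadata is taken from a ``.json`` sidecar
    when present; ``frame_rate`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dlc3row":
        names, pos, conf = _read_dlc3row(path)
    elif dialect == "widecsv":
        names, pos, conf = _read_widecsv(path)
    else:
        raise FormatError(f"unknown pose dialect {dialect!r}")
    if flip_y:
        pos[:, :, 1] = -pos[:, :, 1]
    conf = np.nan_to_num(conf, nan=0.0)
    pos[conf < confidence_min] = np.nan

    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TrialRecording(
        trial_id=meta.get("trial_id", path.stem),
        animal_id=meta.get("animal_id", "unknown"),
        frame_rate=frame_rate or meta.get("frame_rate", 1.0),
        landmarks=names,
        positions=pos,
        confidence=np.clip(conf, 0.0, 1.0),
        takeoff_frame=meta.get("takeoff_frame"),
        gap_distance=meta.get("gap_distance"),
        condition=meta.get("condition", "control"),
        metadata={"source": str(path), "confidence_min": confidence_min},
    )


# ---------------------------------------------------------------------------
# cleaning


@dataclass
class GapReport:
    """Which gaps were filled, extended, or left alone."""

    filled: list[tuple[str, int, int]] = field(default_factory=list)
    edge_extended: list[tuple[str, int, int]] = field(default_factory=list)
    unfilled: list[tuple[str, int, int]] = field(default_factory=list)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def interpolate_gaps(
    trial: TrialRecording, max_gap: int = DEFAULT_MAX_GAP
) -> tuple[TrialRecording, GapReport]:
    """Fill NaN gaps of length <= max_gap by per-coordinate linear interpolation.

    Gaps touching a sequence edge are filled by nearest-value extension.
    Longer interior gaps are left in place and reported.  Frames outside
    flagged gaps are never altered.
    """
    pos = trial.positions.copy()
    report = GapReport()
    t = trial.n_frames
    for j, name in enumerate(trial.landmarks):
        gaps = np.isnan(pos[:, j, :]).any(axis=1)
        if not gaps.any():
            continue
        for start, end in _runs_of(gaps):
            length = end - start
            if start == 0 and end < t:
                pos[start:end, j, :] = pos[end, j, :]
                report.edge_extended.append((name, start, end))
            elif end == t and start > 0:
                pos[start:end, j, :] = pos[start - 1, j, :]
                report.edge_extended.append((name, start, end))
            elif start == 0 and end == t:
                report.unfilled.append((name, start, end))
            elif length <= max_gap:
                lo, hi = pos[start - 1, j, :], pos[end, j, :]
                frac = (np.arange(1, length + 1) / (length + 1))[:, None]
                pos[start:end, j, :] = lo + frac * (hi - lo)
                report.filled.append((name, start, end))
            else:
                report.unfilled.append((name, start, end))
    out = trial.copy(positions=pos)
    out.metadata["gap_report"] = report
    return out, report


def align_to_takeoff(trial: TrialRecording, takeoff_frame: int) -> TrialRecording:
    """Attach a ms-relative time axis with 0 at the takeoff frame."""
    if not 0 <= takeoff_frame < trial.n_frames:
        raise ValueError(
            f"takeoff_frame {takeoff_frame} outside [0, {trial.n_frames})"
        )
    return trial.copy(takeoff_frame=int(takeoff_frame))


# ---------------------------------------------------------------------------
# EMG and stimulation tables


def write_emg_table(recs: list[EMGRecording], path: str | Path) -> None:
    if not recs:
        raise ValueError("no EMG channels to write")
    t = recs[0].time_ms
    out = {"time_ms": t}
    for r in recs:
        if r.signal.size != t.size:
            raise ValueError("EMG channels differ in length")
        out[r.muscle] = r.signal
    pd.DataFrame(out).to_csv(Path(path), index=False, float_format="%.17g")


def read_emg_table(
    path: str | Path,
    sampling_rate: float | None = None,
    roles: dict[str, str] | None = None,
    trial_id: str = "",
) -> list[EMGRecording]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise FormatError(f"{path}: first column must be time_ms")
    t = df["time_ms"].to_numpy(float)
    if sampling_rate is None:
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0]):
            raise FormatError(f"{path}: non-uniform time axis; pass sampling_rate")
        sampling_rate = 1000.0 / dt[0]
    from .synth import MUSCLE_ROLES

    roles = roles or MUSCLE_ROLES
    return [
        EMGRecording(
            muscle=c,
            role=roles.get(c, "extensor"),
            signal=df[c].to_numpy(float),
            sampling_rate=sampling_rate,
            trial_id=trial_id,
            time_offset_ms=t[0],
        )
        for c in df.columns
        if c != "time_ms"
    ]


def write_stim_table(epochs: dict[str, StimEpoch], path: str | Path) -> None:
    rows = [
        {"trial_id": tid, "onset_ms": e.onset_ms, "duration_ms": e.duration_ms,
         "phase_label": e.phase_label}
        for tid, e in epochs.items()
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_stim_table(path: str | Path) -> dict[str, StimEpoch]:
    df = pd.read_csv(Path(path))
    need = {"trial_id", "onset_ms", "duration_ms", "phase_label"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(need)}")
    return {
        str(r.trial_id): StimEpoch(
            onset_ms=float(r.onset_ms), duration_ms=float(r.duration_ms),
            phase_label=str(r.phase_label),
        )
        for r in df.itertuples()
    }
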