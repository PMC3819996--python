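"""Landmark-trajectory data model and long-format CSV I/O.

A speaker recording is four 2-D landmark tracks sampled every few source
video frames: forehead, right shoulder, right hand, left hand. Coordinates
are image coordinates — origin at the upper-left corner, x to the right,
y increasing downward, units in pixels. Missing samples (where a tracker
lost the landmark) are carried as an explicit boolean mask, never as
sentinel coordinates, and may be filled by :func:`interpolate_gaps` up to
a configurable run length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LANDMARKS",
    "LandmarkTrajectory",
    "RecordingMetadata",
    "SpeakerRecording",
    "SchemaError",
    "ValidationError",
    "GapError",
    "read_recordings",
    "read_metadata",
    "write_recordings",
    "validate_recording",
    "interpolate_gaps",
]

#: The four tracked landmarks, in canonical order.
LANDMARKS = ("forehead", "right_shoulder", "right_hand", "left_hand")


class SchemaError(ValueError):
    """Input file does not conform to the long-format trajectory schema."""


class ValidationError(ValueError):
    """A recording violates one or more structural invariants."""


class GapError(ValueError):
    """A missing-sample run cannot be recovered by interpolation."""


@dataclass
class LandmarkTrajectory:
    """One landmark's track: an (T, 2) array of (x, y) pixels plus a missing mask."""

    landmark: str
    points: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARKS:
            raise SchemaError(
                f"unknown landmark {self.landmark!r}; valid names: {', '.join(LANDMARKS)}"
            )
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] == 0:
            raise ValidationError(
                f"{self.landmark}: points must be a non-empty (T, 2) array, "
                f"got shape {self.points.shape}"
            )
        if self.missing is None:
            self.missing = np.zeros(len(self.points), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (len(self.points),):
            raise ValidationError(f"{self.landmark}: mask length != number of points")
        observed = self.points[~self.missing]
        if not np.all(np.isfinite(observed)):
            raise ValidationError(f"{self.landmark}: non-finite coordinate in observed sample")
        if observed.size and observed.min() < 0:
            raise ValidationError(
                f"{self.landmark}: negative coordinate; image coordinates are non-negative"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class RecordingMetadata:
    """Clip-level metadata.

    ``lectern_y`` is the vertical pixel position of the lectern's upper edge,
    used as the lower reference of the body-height estimate; it must lie
    below (numerically above) the forehead track.
    """

    speaker_id: str
    lectern_y: float
    sampling_step: int = 3
    source_fps: float = 25.0
    clip_duration: float = 16.0

    def __post_init__(self) -> None:
        if self.sampling_step < 1:
            raise ValidationError("sampling_step must be >= 1")
        if self.clip_duration <= 0:
            raise ValidationError("clip_duration must be positive")

    @property
    def step_seconds(self) -> float:
        """Wall-clock time per sample step."""
        return self.sampling_step / self.source_fps


@dataclass
class SpeakerRecording:
    """Four landmark trajectories plus clip metadata for one speaker."""

    metadata: RecordingMetadata
    trajectories: dict[str, LandmarkTrajectory] = field(default_factory=dict)

    @property
    def speaker_id(self) -> str:
        return self.metadata.speaker_id

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.trajectories.values())))

    def __getitem__(self, landmark: str) -> LandmarkTrajectory:
        return self.trajectories[landmark]


def validate_recording(rec: SpeakerRecording) -> SpeakerRecording:
    """Check all structural invariants, raising ``ValidationError`` listing every violation."""
    problems: list[str] = []
    missing = [lm for lm in LANDMARKS if lm not in rec.trajectories]
    if missing:
        problems.append(f"missing landmarks: {', '.join(missing)}")
    extra = [lm for lm in rec.trajectories if lm not in LANDMARKS]
    if extra:
        problems.append(f"unknown landmarks: {', '.join(extra)}")
    lengths = {lm: len(tr) for lm, tr in rec.trajectories.items()}
    if len(set(lengths.values())) > 1:
        problems.append(f"ragged trajectory lengths: {lengths}")
    fh = rec.trajectories.get("forehead")
    if fh is not None:
        observed_y = fh.y[~fh.missing]
        if observed_y.size and rec.metadata.lectern_y <= observed_y.min():
            problems.append(
                f"lectern_y={rec.metadata.lectern_y} is not below the forehead track "
                f"(min forehead y={observed_y.min()})"
            )
    if problems:
        raise ValidationError(f"{rec.speaker_id}: " + "; ".join(problems))
    return rec


def _required_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_metadata(path: str | Path) -> dict[str, RecordingMetadata]:
    """Read the per-speaker metadata sidecar (YAML or JSON mapping speaker_id -> fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: metadata sidecar must map speaker_id to fields")
    out = {}
    for sid, fields in raw.items():
        out[str(sid)] = RecordingMetadata(
            speaker_id=str(sid),
            lectern_y=float(fields["lectern_y"]),
            sampling_step=int(fields.get("sampling_step", 3)),
            source_fps=float(fields.get("source_fps", 25.0)),
            clip_duration=float(fields.get("clip_duration_s", 16.0)),
        )
    return out


def read_recordings(
    path: str | Path,
    metadata: str | Path | Mapping[str, RecordingMetadata] | None = None,
) -> list[SpeakerRecording]:
    """Read a long-format trajectory CSV into one recording per speaker.

    The CSV has columns ``speaker_id,landmark,sample_index,x,y``; a missing
    sample is encoded by an absent row and becomes a masked entry. ``metadata``
    is a sidecar path, a mapping, or ``None`` (in which case a sibling file
    ``<stem>.meta.yaml`` is required).
    """
    path = Path(path)
    if metadata is None:
        metadata = path.with_suffix(".meta.yaml")
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)

    df = pd.read_csv(
        path, dtype={"speaker_id": str, "landmark": str}, float_precision="round_trip"
    )
    _required_columns(df, ("speaker_id", "landmark", "sample_index", "x", "y"), str(path))

    bad = df.loc[~df["landmark"].isin(LANDMARKS)]
    if not bad.empty:
        row = bad.iloc[0]
        raise SchemaError(
            f"{path}: unknown landmark {row['landmark']!r} "
            f"(speaker {row['speaker_id']}, sample {row['sample_index']})"
        )
    dup = df.duplicated(subset=["speaker_id", "landmark", "sample_index"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate sample for speaker {row['speaker_id']}, "
            f"landmark {row['landmark']}, index {row['sample_index']}"
        )
    for col in ("sample_index", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            i = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {i}")
        df[col] = coerced

    recordings = []
    for sid, group in df.groupby("speaker_id", sort=True):
        if sid not in metadata:
            raise SchemaError(f"{path}: speaker {sid!r} has no metadata entry")
        n = int(group["sample_index"].max()) + 1
        trajectories = {}
        for lm in LANDMARKS:
            sub = group.loc[group["landmark"] == lm]
            points = np.zeros((n, 2))
            mask = np.ones(n, dtype=bool)
            idx = sub["sample_index"].to_numpy(dtype=int)
            points[idx, 0] = sub["x"].to_numpy()
            points[idx, 1] = sub["y"].to_numpy()
            mask[idx] = False
            trajectories[lm] = LandmarkTrajectory(lm, points, mask)
        recordings.append(SpeakerRecording(metadata[sid], trajectories))
    return recordings


def write_recordings(
    recordings: Iterable[SpeakerRecording],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write recordings as a long-format CSV plus a YAML metadata sidecar.

    Masked samples are omitted (the on-disk encoding of missingness).
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta.yaml")
    rows = []
    meta: dict[str, dict] = {}
    for rec in recordings:
        for lm in LANDMARKS:
            tr = rec.trajectories[lm]
            for t in range(len(tr)):
                if tr.missing[t]:
                    continue
                rows.append((rec.speaker_id, lm, t, tr.points[t, 0], tr.points[t, 1]))
        meta[rec.speaker_id] = {
            "sampling_step": rec.metadata.sampling_step,
            "source_fps": rec.metadata.source_fps,
            "clip_duration_s": rec.metadata.clip_duration,
            "lectern_y": float(rec.metadata.lectern_y),
        }
    pd.DataFrame(rows, columns=["speaker_id", "landmark", "sample_index", "x", "y"]).to_csv(
        path, index=False
    )
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def interpolate_gaps(traj: LandmarkTrajectory, max_gap: int) -> LandmarkTrajectory:
    """Fill runs of at most ``max_gap`` missing samples by per-coordinate linear interpolation.

    Endpoints must be observed. Longer runs raise :class:`GapError` — they
    correspond to track losses that real pipelines fix by hand and that no
    automatic fill should hide. Observed samples pass through bit-identically
    and the operation is idempotent.
    """
    missing = traj.missing
    if not missing.any():
        return LandmarkTrajectory(traj.landmark, traj.points.copy(), missing.copy())
    if missing[0] or missing[-1]:
        raise GapError(f"{traj.landmark}: trajectory endpoint is missing; cannot interpolate")
    # run-length check on the missing mask
    run = 0
    for flag in missing:
        run = run + 1 if flag else 0
        if run > max_gap:
            raise GapError(
                f"{traj.landmark}: missing run longer than max_gap={max_gap} samples"
            )
    t = np.arange(len(traj))
    points = traj.points.copy()
    for c in range(2):
        points[missing, c] = np.interp(t[missing], t[~missing], traj.points[~missing, c])
    return LandmarkTrajectory(traj.landmark, points, np.zeros(len(traj), dtype=bool))


def interpolate_recording(rec: SpeakerRecording, max_gap: int = 5) -> SpeakerRecording:
    """Apply :func:`interpolate_gaps` to every landmark of a recording."""
    return SpeakerRecording(
        dataclasses.replace(rec.metadata),
        {lm: interpolate_gaps(tr, max_gap) for lm, tr in rec.trajectories.items()},
    )
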