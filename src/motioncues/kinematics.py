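"""Shoulder-referenced kinematics and the seven motion cues.

The right shoulder serves as the reference point: its own motion is taken
relative to the image origin, while forehead and hands are taken relative to
the same-step shoulder position (removing camera framing and gross torso
translation). Per-step displacements are decomposed into horizontal and
vertical amplitude series, summed across the four landmarks, and condensed
into seven per-clip cues:

``amp_horz``/``amp_vert``
    Sum of per-step aggregate amplitudes, divided by the body-height estimate
    (largest forehead-to-lectern distance) — overall activity, camera-scale
    free.
``turb_horz``/``turb_vert``
    Coefficient of variation (sd/mean) of the aggregate amplitude series —
    high when calm phases alternate with bursts.
``expr_horz``/``expr_vert``
    Mean absolute second difference of signed per-step displacement
    (a jerk index), corrected for overall activity either by a ratio to the
    mean aggregate amplitude or by regressing it out across a speaker sample.
``var_dir``
    Count of steps at which the dominant axis (larger of the horizontal vs
    vertical aggregate amplitude) flips.

Undefined values (zero-mean CV, zero-activity ratio) come back as NaN with a
logged warning and are excluded pairwise downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .recording import LANDMARKS, SpeakerRecording, ValidationError, validate_recording

__all__ = [
    "Axis",
    "CueConfig",
    "RelativeTrajectorySet",
    "AmplitudeSeries",
    "MotionCueProfile",
    "CUE_NAMES",
    "to_relative",
    "amplitude_series",
    "body_height",
    "sum_of_amplitudes",
    "turbulence",
    "raw_expressiveness",
    "expressiveness",
    "direction_switches",
    "cue_profile",
    "cue_table",
    "write_cue_table",
]

logger = logging.getLogger(__name__)

Axis = Literal["horizontal", "vertical"]
_AXIS_COL = {"horizontal": 0, "vertical": 1}

#: Cue columns in report order.
CUE_NAMES = (
    "amp_horz",
    "amp_vert",
    "turb_horz",
    "turb_vert",
    "expr_horz",
    "expr_vert",
    "var_dir",
)


@dataclass(frozen=True)
class CueConfig:
    """Tunable conventions of the cue computation.

    expressiveness_mode : 'ratio' divides the jerk index by the mean aggregate
        amplitude of the same clip (sample-independent, the default);
        'residual' removes activity by OLS across the speaker sample.
    sd_ddof : delta-degrees-of-freedom of the sd in the turbulence CV
        (1 = sample sd, the default).
    tie_rule : dominant-axis tie handling in the direction-switch count:
        'carry' keeps the previous dominant axis (first-step ties default to
        horizontal); 'horizontal'/'vertical' resolve every tie to that axis.
    """

    expressiveness_mode: Literal["ratio", "residual"] = "ratio"
    sd_ddof: int = 1
    tie_rule: Literal["carry", "horizontal", "vertical"] = "carry"


@dataclass
class RelativeTrajectorySet:
    """Per-landmark (T, 2) coordinate arrays after reference subtraction."""

    coords: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.coords.values())))

    def __getitem__(self, landmark: str) -> np.ndarray:
        return self.coords[landmark]


@dataclass
class AmplitudeSeries:
    """Per-landmark and aggregate |displacement| series, length T - 1."""

    per_landmark: dict[str, np.ndarray]  # each (T-1, 2): columns |dx|, |dy|

    @property
    def aggregate(self) -> np.ndarray:
        """(T-1, 2) cross-landmark sums: columns AH_t, AV_t."""
        return np.sum([a for a in self.per_landmark.values()], axis=0)

    def axis(self, axis: Axis) -> np.ndarray:
        return self.aggregate[:, _AXIS_COL[axis]]


@dataclass
class MotionCueProfile:
    """The seven per-speaker cue values."""

    speaker_id: str
    amp_horz: float
    amp_vert: float
    turb_horz: float
    turb_vert: float
    expr_horz: float
    expr_vert: float
    var_dir: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CUE_NAMES}


def to_relative(rec: SpeakerRecording) -> RelativeTrajectorySet:
    """Subtract the same-step shoulder position from forehead and hands.

    The shoulder itself is referenced to the image origin, i.e. kept as-is.
    Residual missing samples are an error: interpolate first.
    """
    for lm, tr in rec.trajectories.items():
        if tr.missing.any():
            raise ValidationError(f"{rec.speaker_id}/{lm}: residual missing samples")
    shoulder = rec["right_shoulder"].points
    coords = {}
    for lm in LANDMARKS:
        pts = rec[lm].points
        coords[lm] = pts.copy() if lm == "right_shoulder" else pts - shoulder
    return RelativeTrajectorySet(coords)


def amplitude_series(rel: RelativeTrajectorySet) -> AmplitudeSeries:
    """Absolute per-step displacement per landmark; aggregates are cross-landmark sums."""
    if rel.n_samples < 2:
        raise ValidationError("need at least 2 samples to form amplitudes")
    return AmplitudeSeries(
        {lm: np.abs(np.diff(xy, axis=0)) for lm, xy in rel.coords.items()}
    )


def body_height(rec: SpeakerRecording) -> float:
    """Largest forehead-to-lectern distance, in pixels (the body-height proxy)."""
    fy = rec["forehead"].y[~rec["forehead"].missing]
    bh = float(rec.metadata.lectern_y - fy.min())
    if bh <= 0:
        raise ValidationError(
            f"{rec.speaker_id}: lectern_y={rec.metadata.lectern_y} not below forehead "
            f"(min y={fy.min()}); body height undefined"
        )
    return bh


def sum_of_amplitudes(amp: AmplitudeSeries, axis: Axis, bh: float) -> float:
    """Total aggregate amplitude on one axis, normalized by body height."""
    if bh <= 0:
        raise ValidationError("body height must be positive")
    return float(amp.axis(axis).sum() / bh)


def turbulence(amp: AmplitudeSeries, axis: Axis, ddof: int = 1) -> float:
    """Coefficient of variation (sd/mean) of the aggregate amplitude series.

    Returns NaN (with a warning) when the mean is zero — a motionless clip
    has no defined dispersion ratio.
    """
    series = amp.axis(axis)
    if len(series) < 2:
        raise ValidationError("need at least 2 amplitudes for a CV")
    mean = series.mean()
    if mean == 0:
        logger.warning("turbulence undefined on %s axis: zero mean amplitude", axis)
        return float("nan")
    return float(series.std(ddof=ddof) / mean)


def raw_expressiveness(rel: RelativeTrajectorySet, axis: Axis) -> float:
    """Mean absolute second difference of signed per-step displacement (pixels/step^2).

    Zero for uniform drift (constant velocity), large for twitchy, jerky
    motion; averaged over the four landmarks and all steps.
    """
    if rel.n_samples < 3:
        raise ValidationError("need at least 3 samples for a velocity change")
    col = _AXIS_COL[axis]
    jerks = [np.abs(np.diff(xy[:, col], n=2)) for xy in rel.coords.values()]
    return float(np.mean(jerks))


def expressiveness(
    raw: float | np.ndarray,
    activity: float | np.ndarray,
    mode: Literal["ratio", "residual"] = "ratio",
    sample: Sequence[tuple[float, float]] | None = None,
) -> float | np.ndarray:
    """Correct the raw jerk index for overall activity.

    ratio mode: ``raw / activity`` where activity is the mean per-step
    aggregate amplitude on the same axis (NaN when activity is zero).
    residual mode: the OLS residual of raw on activity across ``sample``
    (pairs of (raw, activity) for >= 3 speakers); the result is exactly
    uncorrelated with activity across that sample.
    """
    if mode == "ratio":
        raw_arr, act = np.asarray(raw, dtype=float), np.asarray(activity, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(act > 0, raw_arr / np.where(act > 0, act, 1.0), np.nan)
        if np.isnan(out).any():
            logger.warning("expressiveness undefined: zero activity in ratio mode")
        return float(out) if out.ndim == 0 else out
    if mode == "residual":
        if sample is None or len(sample) < 3:
            raise ValidationError("residual mode needs a sample of >= 3 speakers")
        arr = np.asarray(sample, dtype=float)
        slope, intercept = np.polyfit(arr[:, 1], arr[:, 0], 1)
        return float(raw - (intercept + slope * activity))
    raise ValueError(f"unknown expressiveness mode {mode!r}")


def direction_switches(
    amp: AmplitudeSeries, tie_rule: Literal["carry", "horizontal", "vertical"] = "carry"
) -> int:
    """Count flips of the dominant axis along the aggregate amplitude series.

    At each step the dominant axis is the larger of AH_t and AV_t. Under the
    default 'carry' rule a tie keeps the previous step's dominant axis, and a
    tie on the very first step defaults to horizontal.
    """
    ah, av = amp.axis("horizontal"), amp.axis("vertical")
    if len(ah) < 2:
        raise ValidationError("need at least 2 amplitudes to count switches")
    dominant = np.empty(len(ah), dtype="<U1")
    prev = "h"
    for t in range(len(ah)):
        if ah[t] > av[t]:
            cur = "h"
        elif av[t] > ah[t]:
            cur = "v"
        elif tie_rule == "carry":
            cur = prev
        else:
            cur = tie_rule[0]
        dominant[t] = cur
        prev = cur
    return int(np.sum(dominant[1:] != dominant[:-1]))


def cue_profile(
    rec: SpeakerRecording,
    cfg: CueConfig = CueConfig(),
    residual_sample: dict[Axis, Sequence[tuple[float, float]]] | None = None,
) -> MotionCueProfile:
    """Assemble all seven cues for one validated, gap-free recording.

    Residual-mode expressiveness needs a cross-speaker sample of
    (raw, activity) pairs per axis; use :func:`cue_table` to supply it
    automatically for a collection.
    """
    validate_recording(rec)
    rel = to_relative(rec)
    amp = amplitude_series(rel)
    bh = body_height(rec)
    values: dict[str, float] = {}
    for axis, suffix in (("horizontal", "horz"), ("vertical", "vert")):
        values[f"amp_{suffix}"] = sum_of_amplitudes(amp, axis, bh)
        values[f"turb_{suffix}"] = turbulence(amp, axis, ddof=cfg.sd_ddof)
        raw = raw_expressiveness(rel, axis)
        activity = float(amp.axis(axis).mean())
        if cfg.expressiveness_mode == "residual":
            if residual_sample is None:
                raise ValidationError("residual expressiveness needs a speaker sample")
            values[f"expr_{suffix}"] = expressiveness(
                raw, activity, mode="residual", sample=residual_sample[axis]
            )
        else:
            values[f"expr_{suffix}"] = expressiveness(raw, activity, mode="ratio")
    return MotionCueProfile(
        speaker_id=rec.speaker_id,
        var_dir=direction_switches(amp, tie_rule=cfg.tie_rule),
        **values,
    )


def cue_table(
    recordings: Iterable[SpeakerRecording], cfg: CueConfig = CueConfig()
) -> pd.DataFrame:
    """Cue profiles for a speaker collection as a DataFrame (one row per speaker).

    In residual mode the activity correction is fitted across this collection.
    """
    recordings = list(recordings)
    residual_sample = None
    if cfg.expressiveness_mode == "residual":
        residual_sample = {}
        for axis in ("horizontal", "vertical"):
            pairs = []
            for rec in recordings:
                rel = to_relative(rec)
                amp = amplitude_series(rel)
                pairs.append((raw_expressiveness(rel, axis), float(amp.axis(axis).mean())))
            residual_sample[axis] = pairs
    rows = []
    for rec in recordings:
        prof = cue_profile(rec, cfg, residual_sample=residual_sample)
        rows.append({"speaker_id": prof.speaker_id, **prof.as_dict()})
    return pd.DataFrame(rows, columns=["speaker_id", *CUE_NAMES])


def write_cue_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the cue table CSV; undefined cues become empty fields."""
    table.to_csv(path, index=False, na_rep="")
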