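"""Synthetic speakers: motion-style recordings, rater responses, biographies.

The study's raw inputs (speech videos, rater sessions, public biographies)
are emulated by a latent-style model so that every pipeline stage can be
tested with known ground truth:

* Each speaker has a :class:`StyleParams` vector — overall ``activity``,
  ``jerkiness`` (share of high-frequency velocity change), ``burstiness``
  (fraction of the clip spent in a low-activity state), ``switch_rate``
  (expected dominant-axis alternations per clip) and ``vertical_bias``
  (share of motion energy on the vertical axis). Each parameter maps
  monotonically onto one of the motion cues.
* Hand motion is a shared scalar signal per hand — a smooth oscillation plus
  sign-randomized jerk — projected onto the two axes with weights that favor
  the currently dominant axis; the dominant axis flips at Poisson event
  times. A periodic on/off gate with duty cycle ``1 - burstiness`` modulates
  the signal; the on-level is rescaled so expected activity does not depend
  on burstiness (burstiness moves dispersion, not totals). The shoulder adds
  a slow, low-amplitude sway; the forehead rides on the shoulder.
* Raters respond to the speaker's true cue profile through a linear loading
  model: item value = 50 + loadings @ z(cues) + noise, clipped to [0, 100].
* Biographies are drawn around the study's published career-measure
  distributions, optionally linked to style parameters through configurable
  coefficients (zero by default: career independent of motion style).

Everything is a pure function of (parameters, seed); speakers get named
substreams so adding a speaker never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import CUE_NAMES, CueConfig, cue_table
from .ratings import DIMENSIONS, ItemKey, default_item_key
from .recording import (
    LandmarkTrajectory,
    RecordingMetadata,
    SpeakerRecording,
    write_recordings,
)

__all__ = [
    "StyleParams",
    "StylePrior",
    "RaterModel",
    "BioModel",
    "ScenarioConfig",
    "ScenarioData",
    "GenerationError",
    "default_loadings",
    "sample_styles",
    "generate_recording",
    "generate_ratings",
    "generate_biodata",
    "generate_scenario",
    "write_scenario",
]

#: Latent style parameter names, each matched to the cue family it drives.
STYLE_PARAMS = ("activity", "jerkiness", "burstiness", "switch_rate", "vertical_bias")

# substream codes so each (stage, speaker) pair has its own random stream
_STAGE = {"styles": 0, "recording": 1, "ratings": 2, "bio": 3}


class GenerationError(RuntimeError):
    """A parameter combination produced coordinates outside the image frame."""


def _rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE[stage], int(index)))
    )


@dataclass
class StyleParams:
    """Latent motion style of one speaker."""

    activity: float = 1.0
    jerkiness: float = 0.5
    burstiness: float = 0.2
    switch_rate: float = 6.0
    vertical_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.activity < 0 or self.jerkiness < 0 or self.switch_rate < 0:
            raise ValueError("activity, jerkiness and switch_rate must be >= 0")
        if not 0 <= self.burstiness <= 1:
            raise ValueError("burstiness must lie in [0, 1]")
        if not 0 <= self.vertical_bias <= 1:
            raise ValueError("vertical_bias must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in STYLE_PARAMS}


@dataclass
class StylePrior:
    """Independent uniform ranges for each style parameter.

    Defaults span clearly distinguishable speakers: a 5x activity range,
    near-smooth to very twitchy, up to 60% pausing, up to ~20 dominance
    alternations per 16 s clip, and a moderate axis-preference band (extreme
    vertical_bias would override the planted dominance switching).
    """

    activity: tuple[float, float] = (0.5, 2.5)
    jerkiness: tuple[float, float] = (0.1, 1.5)
    burstiness: tuple[float, float] = (0.0, 0.6)
    switch_rate: tuple[float, float] = (0.0, 20.0)
    vertical_bias: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        for p in STYLE_PARAMS:
            lo, hi = getattr(self, p)
            if hi < lo:
                raise ValueError(f"empty prior range for {p}: ({lo}, {hi})")


@dataclass
class RaterModel:
    """Linear rater model: item value = 50 + loadings @ z(cues) + noise."""

    loadings: np.ndarray = None  # type: ignore[assignment]  # (20 items, 7 cues)
    rater_noise_sd: float = 12.0
    raters_per_speaker: tuple[int, int] = (14, 19)

    def __post_init__(self) -> None:
        if self.loadings is None:
            self.loadings = default_loadings()
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (20, len(CUE_NAMES)):
            raise ValueError(f"loadings must be (20, {len(CUE_NAMES)})")
        lo, hi = self.raters_per_speaker
        if not (1 <= lo <= hi <= 100):
            raise ValueError("raters_per_speaker must be within [1, 100]")


def default_loadings() -> np.ndarray:
    """Item loadings planting the study's headline cue-impression pattern.

    High activity reads as extraverted, jerky motion as emotionally unstable,
    frequent direction changes as open, bursty/low vertical motion as
    agreeable; units are rating points per cue standard deviation.
    """
    L = np.zeros((20, len(CUE_NAMES)))
    col = {c: i for i, c in enumerate(CUE_NAMES)}
    blocks = {
        "openness": {"var_dir": 8.0},
        "conscientiousness": {"turb_horz": 6.0},
        "agreeableness": {"amp_vert": -8.0, "turb_horz": 4.0, "turb_vert": 4.0},
        "emotional_stability": {"amp_horz": 4.0, "expr_horz": -5.0, "expr_vert": -8.0},
        "extraversion": {"amp_horz": 7.0, "amp_vert": 7.0, "turb_horz": -4.0},
    }
    for d, dim in enumerate(DIMENSIONS):
        for cue, w in blocks[dim].items():
            L[4 * d : 4 * d + 4, col[cue]] = w
    return L


@dataclass
class BioModel:
    """Career-measure distributions, optionally linked to style parameters.

    Location/scale defaults follow the published sample moments (16.9 +/- 9.2
    years to parliament, 0.36 +/- 0.14 memberships per year of age,
    0.09 +/- 0.05 leadership positions per year). The ``*_links`` map a style
    parameter name to the shift (in the measure's own units) per style
    standard deviation; all empty by default.
    """

    entry_mean: float = 16.9
    entry_sd: float = 9.2
    membership_rate: float = 0.36
    membership_rate_sd: float = 0.14
    leadership_rate: float = 0.09
    leadership_rate_sd: float = 0.05
    age_range: tuple[int, int] = (35, 65)
    entry_links: dict[str, float] = field(default_factory=dict)
    membership_links: dict[str, float] = field(default_factory=dict)
    leadership_links: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    """A full study scenario: 40 speakers, 16 s clips sampled every 3 frames at 25 fps."""

    n_speakers: int = 40
    n_samples: int = 133
    seed: int = 0
    style_prior: StylePrior = field(default_factory=StylePrior)
    rater_model: RaterModel = field(default_factory=RaterModel)
    bio_model: BioModel = field(default_factory=BioModel)
    cue_config: CueConfig = field(default_factory=CueConfig)
    frame: tuple[int, int] = (640, 480)
    lectern_frac: float = 0.9
    hand_freq_hz: float = 0.45
    gate_period: int = 33
    gate_floor: float = 0.15
    sampling_step: int = 3
    source_fps: float = 25.0

    def __post_init__(self) -> None:
        if self.n_speakers < 3:
            raise ValueError("need at least 3 speakers")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples per clip")

    @property
    def lectern_y(self) -> float:
        return self.lectern_frac * self.frame[1]

    @property
    def clip_duration(self) -> float:
        return self.n_samples * self.sampling_step / self.source_fps

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "style_prior" in kwargs:
            kwargs["style_prior"] = StylePrior(
                **{k: tuple(v) for k, v in kwargs["style_prior"].items()}
            )
        if "rater_model" in kwargs:
            rm = dict(kwargs["rater_model"])
            if "loadings" in rm:
                rm["loadings"] = np.asarray(rm["loadings"], dtype=float)
            if "raters_per_speaker" in rm:
                rm["raters_per_speaker"] = tuple(rm["raters_per_speaker"])
            kwargs["rater_model"] = RaterModel(**rm)
        if "bio_model" in kwargs:
            bm = dict(kwargs["bio_model"])
            if "age_range" in bm:
                bm["age_range"] = tuple(bm["age_range"])
            kwargs["bio_model"] = BioModel(**bm)
        if "cue_config" in kwargs:
            kwargs["cue_config"] = CueConfig(**kwargs["cue_config"])
        if "frame" in kwargs:
            kwargs["frame"] = tuple(kwargs["frame"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["rater_model"]["loadings"] = self.rater_model.loadings.tolist()
        raw["rater_model"]["raters_per_speaker"] = list(self.rater_model.raters_per_speaker)
        raw["bio_model"]["age_range"] = list(self.bio_model.age_range)
        raw["style_prior"] = {p: list(getattr(self.style_prior, p)) for p in STYLE_PARAMS}
        raw["frame"] = list(self.frame)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def sample_styles(n: int, prior: StylePrior, seed: int) -> list[StyleParams]:
    """Independent uniform style draws, one named substream per speaker."""
    styles = []
    for i in range(n):
        rng = _rng(seed, "styles", i)
        styles.append(
            StyleParams(
                **{p: float(rng.uniform(*getattr(prior, p))) for p in STYLE_PARAMS}
            )
        )
    return styles


def _dominance_track(rng: np.random.Generator, T: int, switch_rate: float) -> np.ndarray:
    """0/1 track of the planted dominant axis (1 = vertical), Poisson event flips."""
    state = np.empty(T, dtype=int)
    cur = int(rng.integers(0, 2))
    n_events = int(rng.poisson(switch_rate))
    events = set(np.sort(rng.choice(np.arange(1, T), size=min(n_events, T - 1), replace=False)))
    for t in range(T):
        if t in events:
            cur = 1 - cur
        state[t] = cur
    return state


def generate_recording(
    style: StyleParams, cfg: ScenarioConfig, seed: int, speaker_index: int = 0
) -> SpeakerRecording:
    """Synthesize one speaker's four landmark tracks from a style vector."""
    rng = _rng(seed, "recording", speaker_index)
    T = cfg.n_samples
    dt = cfg.sampling_step / cfg.source_fps
    t = np.arange(T) * dt
    act, jerk, burst = style.activity, style.jerkiness, style.burstiness
    vb = style.vertical_bias

    # shoulder: slow low-amplitude sway, mostly horizontal; forehead rides on it
    def sway(amp_x, amp_y, f):
        ph = rng.uniform(0, 2 * np.pi, size=2)
        return np.column_stack(
            [amp_x * np.sin(2 * np.pi * f * t + ph[0]), amp_y * np.sin(2 * np.pi * f * t + ph[1])]
        )

    shoulder = np.array([360.0, 220.0]) + act * sway(0.5, 0.2, 0.10)
    forehead = shoulder + np.array([-30.0, -100.0]) + act * sway(0.3, 0.1, 0.15)

    # shared dominance and gate tracks for both hands (T-1 displacement steps)
    dom = _dominance_track(rng, T - 1, style.switch_rate)
    phase = int(rng.integers(0, cfg.gate_period))
    pos_in_period = (np.arange(T - 1) + phase) % cfg.gate_period
    off = pos_in_period < round(burst * cfg.gate_period)
    eps = cfg.gate_floor
    burst_eff = off.mean()
    # on-level compensation: expected |displacement| independent of burstiness
    on_level = (1.0 - eps * burst_eff) / (1.0 - burst_eff) if burst_eff < 1 else eps
    gate = np.where(off, eps, on_level)

    # dominance-dependent axis weights, normalized to unit sum
    kappa = 4.0
    w_h = (1 - vb) * np.where(dom == 0, kappa, 1.0)
    w_v = vb * np.where(dom == 1, kappa, 1.0)
    norm = w_h + w_v
    w_h, w_v = w_h / norm, w_v / norm

    a_smooth = 3.0 * act
    a_jerk = 0.8 * jerk * act
    rho = 0.95  # leak on the shared scalar signal keeps tracks inside the frame

    def hand(base_x: float, base_y: float) -> np.ndarray:
        # One scalar motion signal per hand, projected on the axes through the
        # dominance weights; weight flips are absorbed into a continuity
        # offset, so every step's h/v displacement ratio equals the weight
        # ratio and the measured dominance track reproduces the planted one.
        phi = rng.uniform(0, 2 * np.pi)
        env = np.sin(2 * np.pi * cfg.hand_freq_hz * t[1:] + phi)
        mag = np.abs(rng.standard_normal(T - 1))
        sign = rng.choice([-1.0, 1.0], size=T - 1)
        core = gate * (a_smooth * env + a_jerk * mag * sign)
        pos = np.empty((T, 2))
        pos[0] = 0.0
        S = 0.0
        offset = np.zeros(2)
        for k in range(T - 1):
            w = np.array([w_h[k], w_v[k]])
            if k > 0 and (w_h[k] != w_h[k - 1] or w_v[k] != w_v[k - 1]):
                offset += (np.array([w_h[k - 1], w_v[k - 1]]) - w) * S
            S = rho * S + core[k]
            pos[k + 1] = w * S + offset
        return np.array([base_x, base_y]) + pos

    right_hand = hand(410.0, 300.0)
    left_hand = hand(270.0, 300.0)

    tracks = {
        "forehead": forehead,
        "right_shoulder": shoulder,
        "right_hand": right_hand,
        "left_hand": left_hand,
    }
    fw, fh_px = cfg.frame
    for name, pts in tracks.items():
        if pts[:, 0].min() < 0 or pts[:, 0].max() > fw or pts[:, 1].min() < 0 or pts[:, 1].max() > fh_px:
            raise GenerationError(
                f"{name} leaves the {fw}x{fh_px} frame; reduce activity/jerkiness scales"
            )
    meta = RecordingMetadata(
        speaker_id=f"S{speaker_index:03d}",
        lectern_y=cfg.lectern_y,
        sampling_step=cfg.sampling_step,
        source_fps=cfg.source_fps,
        clip_duration=cfg.clip_duration,
    )
    return SpeakerRecording(meta, {k: LandmarkTrajectory(k, v) for k, v in tracks.items()})


def _zscore_cues(cues: pd.DataFrame) -> np.ndarray:
    """Z-score cue columns across speakers; degenerate or undefined cells become 0."""
    z = np.zeros((len(cues), len(CUE_NAMES)))
    for j, cue in enumerate(CUE_NAMES):
        col = cues[cue].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        if ok.sum() >= 2 and np.nanstd(col, ddof=1) > 0:
            z[ok, j] = (col[ok] - col[ok].mean()) / col[ok].std(ddof=1)
    return z


def generate_ratings(
    cues: pd.DataFrame, model: RaterModel, seed: int
) -> tuple[pd.DataFrame, ItemKey]:
    """Simulate the rating experiment on a speakers x cues table.

    Returns the long-format responses plus the (non-reversed) item key the
    responses are keyed to.
    """
    z = _zscore_cues(cues)
    lo, hi = model.raters_per_speaker
    rows = []
    for i, sid in enumerate(cues["speaker_id"]):
        rng = _rng(seed, "ratings", i)
        signal = 50.0 + model.loadings @ z[i]
        for j in range(int(rng.integers(lo, hi + 1))):
            values = np.clip(
                signal + model.rater_noise_sd * rng.standard_normal(20), 0.0, 100.0
            )
            for item in range(20):
                rows.append((f"r{sid}_{j:02d}", sid, item + 1, values[item]))
    return (
        pd.DataFrame(rows, columns=["rater_id", "speaker_id", "item_id", "value"]),
        default_item_key(),
    )


def generate_biodata(
    styles: Sequence[StyleParams],
    model: BioModel,
    seed: int,
    speaker_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw style-linked biographies in the biography CSV schema."""
    if speaker_ids is None:
        speaker_ids = [f"S{i:03d}" for i in range(len(styles))]
    mat = np.array([[getattr(s, p) for p in STYLE_PARAMS] for s in styles], dtype=float)
    sd = mat.std(axis=0, ddof=1) if len(styles) > 1 else np.ones(mat.shape[1])
    sd[sd == 0] = 1.0
    z = (mat - mat.mean(axis=0)) / sd
    zof = {p: z[:, k] for k, p in enumerate(STYLE_PARAMS)}

    def shift(links: Mapping[str, float], i: int) -> float:
        return sum(coef * zof[p][i] for p, coef in links.items())

    rows = []
    for i, sid in enumerate(speaker_ids):
        rng = _rng(seed, "bio", i)
        age = int(rng.integers(model.age_range[0], model.age_range[1] + 1))
        entry = max(
            0.0,
            rng.normal(model.entry_mean, model.entry_sd) + shift(model.entry_links, i),
        )
        year_party = int(rng.integers(1965, 1996))
        mem_rate = max(
            0.005,
            rng.normal(model.membership_rate, model.membership_rate_sd)
            + shift(model.membership_links, i),
        )
        lead_rate = max(
            0.0,
            rng.normal(model.leadership_rate, model.leadership_rate_sd)
            + shift(model.leadership_links, i),
        )
        rows.append(
            (
                sid,
                year_party,
                year_party + int(round(entry)),
                int(rng.poisson(mem_rate * age)),
                int(rng.poisson(lead_rate * age)),
                age,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "speaker_id",
            "year_party_entry",
            "year_parliament_entry",
            "memberships",
            "leadership_positions",
            "age",
        ],
    )


@dataclass
class ScenarioData:
    """Everything one simulated study produces, plus its latent ground truth."""

    config: ScenarioConfig
    styles: list[StyleParams]
    recordings: list[SpeakerRecording]
    true_cues: pd.DataFrame
    ratings: pd.DataFrame
    item_key: ItemKey
    biographies: pd.DataFrame

    @property
    def style_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"speaker_id": r.speaker_id, **s.as_dict()} for r, s in zip(self.recordings, self.styles)]
        )


def generate_scenario(cfg: ScenarioConfig, seed: int | None = None) -> ScenarioData:
    """Run the whole generator: styles -> recordings -> cues -> ratings + biographies."""
    seed = cfg.seed if seed is None else seed
    styles = sample_styles(cfg.n_speakers, cfg.style_prior, seed)
    recordings = [
        generate_recording(s, cfg, seed, speaker_index=i) for i, s in enumerate(styles)
    ]
    cues = cue_table(recordings, cfg.cue_config)
    ratings, key = generate_ratings(cues, cfg.rater_model, seed)
    bios = generate_biodata(styles, cfg.bio_model, seed, [r.speaker_id for r in recordings])
    return ScenarioData(cfg, styles, recordings, cues, ratings, key, bios)


def write_scenario(data: ScenarioData, directory: str | Path) -> dict[str, Path]:
    """Write all scenario files (trajectories, metadata, ratings, key, biographies, config)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": directory / "trajectories.csv",
        "metadata": directory / "trajectories.meta.yaml",
        "ratings": directory / "ratings.csv",
        "item_key": directory / "item_key.csv",
        "biography": directory / "biography.csv",
        "scenario": directory / "scenario.yaml",
    }
    write_recordings(data.recordings, paths["trajectories"], paths["metadata"])
    data.ratings.to_csv(paths["ratings"], index=False)
    data.item_key.to_csv(paths["item_key"])
    data.biographies.to_csv(paths["biography"], index=False)
    data.config.to_yaml(paths["scenario"])
    return paths
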