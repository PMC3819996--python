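"""Rater aggregation into Big Five profiles, internal consistency, and career metrics.

Observers judge each speaker on 20 bipolar adjective items (sliders from 0 to
100, 50 neutral), four items per Big Five dimension. Aggregation follows the
median-then-sum convention: reversed items are reflected (100 - value), each
item is reduced to its median across raters, and a dimension score is the sum
of its four item medians (range 0-400). Internal consistency per dimension is
Cronbach's alpha over the speaker-level item medians.

Career progress is summarized by three biographical measures: years from
party entry to parliament entry, and memberships / leadership positions per
year of age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "ItemKey",
    "default_item_key",
    "BiographicalRecord",
    "CareerMetrics",
    "aggregate_ratings",
    "item_median_matrix",
    "cronbach_alpha",
    "dimension_alphas",
    "career_metrics",
    "career_table",
]

logger = logging.getLogger(__name__)

#: The Big Five dimensions, in report order.
DIMENSIONS = (
    "openness",
    "conscientiousness",
    "agreeableness",
    "emotional_stability",
    "extraversion",
)

CAREER_METRICS = ("entry_years", "membership_rate", "leadership_rate")


class ItemKey:
    """Maps the 20 item ids to their Big Five dimension and polarity.

    Built from a DataFrame with columns ``item_id, dimension, reversed``;
    exactly 20 items, 4 per dimension.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"item_id", "dimension", "reversed"}
        if not required.issubset(table.columns):
            raise KeyError(f"item key needs columns {sorted(required)}")
        table = table.copy()
        table["reversed"] = table["reversed"].astype(bool)
        if len(table) != 20 or table["item_id"].nunique() != 20:
            raise ValueError("item key must define exactly 20 distinct items")
        counts = table["dimension"].value_counts()
        if set(counts.index) != set(DIMENSIONS) or not (counts == 4).all():
            raise ValueError("item key must assign exactly 4 items to each dimension")
        self.table = table.set_index("item_id", drop=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ItemKey":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def items_for(self, dimension: str) -> list[int]:
        return sorted(self.table.loc[self.table["dimension"] == dimension, "item_id"])


def default_item_key() -> ItemKey:
    """Items 1-20 assigned blockwise to the five dimensions, no reversals.

    The study instrument's adjective pairs and polarities are not public, so
    the default marks nothing as reversed; supply a real key for real data.
    """
    return ItemKey(
        pd.DataFrame(
            {
                "item_id": np.arange(1, 21),
                "dimension": np.repeat(DIMENSIONS, 4),
                "reversed": False,
            }
        )
    )


def _oriented(responses: pd.DataFrame, key: ItemKey) -> pd.DataFrame:
    required = {"rater_id", "speaker_id", "item_id", "value"}
    if not required.issubset(responses.columns):
        raise KeyError(f"ratings need columns {sorted(required)}")
    values = responses["value"].astype(float)
    if ((values < 0) | (values > 100)).any():
        raise ValueError("rating values must lie in [0, 100]")
    unknown = set(responses["item_id"]) - set(key.table["item_id"])
    if unknown:
        raise KeyError(f"responses reference items missing from the key: {sorted(unknown)}")
    out = responses.copy()
    out["value"] = values
    rev = out["item_id"].map(key.table["reversed"])
    out.loc[rev, "value"] = 100.0 - out.loc[rev, "value"]
    return out


def item_median_matrix(responses: pd.DataFrame, key: ItemKey) -> pd.DataFrame:
    """Speakers x items matrix of per-item medians across raters (reversals applied)."""
    oriented = _oriented(responses, key)
    return oriented.pivot_table(
        index="speaker_id", columns="item_id", values="value", aggfunc="median"
    )


def aggregate_ratings(responses: pd.DataFrame, key: ItemKey | None = None) -> pd.DataFrame:
    """Reduce rater responses to one Big Five profile per speaker.

    Returns a DataFrame indexed by speaker_id with one column per dimension
    (sum of its four item medians, range 0-400) plus ``n_raters`` (distinct
    raters for that speaker). Speakers missing some of the 20 items raise;
    the median-then-sum order matters and a partial sum would silently
    deflate the score.
    """
    key = key or default_item_key()
    medians = item_median_matrix(responses, key)
    incomplete = medians.index[medians.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"speakers with unrated items: {incomplete}")
    profile = pd.DataFrame(index=medians.index)
    for dim in DIMENSIONS:
        profile[dim] = medians[key.items_for(dim)].sum(axis=1)
    profile["n_raters"] = (
        responses.groupby("speaker_id")["rater_id"].nunique().reindex(medians.index)
    )
    return profile


def cronbach_alpha(item_scores: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a speakers x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (n-1) variances; can be negative; NaN (with a warning) when
    the item sums do not vary at all.
    """
    m = np.asarray(item_scores, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("alpha needs >= 3 speakers and >= 2 items")
    if np.isnan(m).any():
        raise ValueError("alpha input must have no missing cells")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        logger.warning("Cronbach's alpha undefined: item sums have zero variance")
        return float("nan")
    return float(k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / total_var))


def dimension_alphas(responses: pd.DataFrame, key: ItemKey | None = None) -> pd.Series:
    """Cronbach's alpha per dimension, over speaker-level item medians."""
    key = key or default_item_key()
    medians = item_median_matrix(responses, key)
    return pd.Series(
        {dim: cronbach_alpha(medians[key.items_for(dim)]) for dim in DIMENSIONS},
        name="alpha",
    )


@dataclass
class BiographicalRecord:
    """One speaker's career facts from a public biography."""

    speaker_id: str
    year_party_entry: int
    year_parliament_entry: int
    memberships: int
    leadership_positions: int
    age: float

    def __post_init__(self) -> None:
        problems = []
        if self.year_parliament_entry < self.year_party_entry:
            problems.append("parliament entry precedes party entry")
        if self.age <= 0:
            problems.append("age must be positive")
        if self.memberships < 0 or self.leadership_positions < 0:
            problems.append("counts must be non-negative")
        if problems:
            raise ValueError(f"{self.speaker_id}: " + "; ".join(problems))


@dataclass
class CareerMetrics:
    """Career-progress summaries: slower entry = larger entry_years."""

    speaker_id: str
    entry_years: float
    membership_rate: float
    leadership_rate: float


def career_metrics(bio: BiographicalRecord) -> CareerMetrics:
    """Years to parliament plus age-normalized membership and leadership counts."""
    return CareerMetrics(
        speaker_id=bio.speaker_id,
        entry_years=float(bio.year_parliament_entry - bio.year_party_entry),
        membership_rate=bio.memberships / bio.age,
        leadership_rate=bio.leadership_positions / bio.age,
    )


def career_table(biographies: pd.DataFrame | Iterable[BiographicalRecord]) -> pd.DataFrame:
    """Career metrics for a collection, indexed by speaker_id.

    Accepts a DataFrame with the biography CSV columns or an iterable of
    :class:`BiographicalRecord`.
    """
    if isinstance(biographies, pd.DataFrame):
        biographies = [
            BiographicalRecord(
                speaker_id=str(r.speaker_id),
                year_party_entry=int(r.year_party_entry),
                year_parliament_entry=int(r.year_parliament_entry),
                memberships=int(r.memberships),
                leadership_positions=int(r.leadership_positions),
                age=float(r.age),
            )
            for r in biographies.itertuples(index=False)
        ]
    rows = [career_metrics(b) for b in biographies]
    return pd.DataFrame(
        [(m.speaker_id, m.entry_years, m.membership_rate, m.leadership_rate) for m in rows],
        columns=["speaker_id", *CAREER_METRICS],
    ).set_index("speaker_id")
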