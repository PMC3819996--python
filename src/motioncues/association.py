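"""Statistical layer: rank correlations, standardized regressions, structure coefficients.

The study design relates seven strongly intercorrelated motion cues to five
impression dimensions and three career measures across a modest speaker
sample. Bivariate relations are Spearman rank correlations (robust to the
skewed cue distributions); each criterion is additionally regressed on all
seven cues after z-scoring, reporting standardized betas, the multiple
correlation R, and variance inflation factors. Because collinearity makes
betas hard to read, every predictor also gets a structure coefficient —
its bivariate correlation with the criterion divided by R — which estimates
the predictor's relation to the fitted criterion ignoring the other
predictors.

The modelling surface follows the Model/Results convention:

>>> model = CueAssociationModel(cues, big5, careers)   # doctest: +SKIP
>>> res = model.fit()                                  # doctest: +SKIP
>>> print(res.summary())                               # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .kinematics import CUE_NAMES
from .ratings import CAREER_METRICS, DIMENSIONS

__all__ = [
    "spearman",
    "spearman_matrix",
    "standardized_ols",
    "structure_coefficients",
    "vif",
    "RegressionResult",
    "CueAssociationModel",
    "AssociationResults",
    "build_reports",
]

logger = logging.getLogger(__name__)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks on ties) after pairwise NaN deletion."""
    r, _ = spearman_test(x, y)
    return r


def spearman_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman r_s and its two-sided p-value (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("spearman undefined: zero rank variance")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation matrix plus per-cell n after pairwise deletion."""
    cols = table.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        n.loc[a, a] = int(table[a].notna().sum())
        for b in cols[i + 1 :]:
            keep = table[a].notna() & table[b].notna()
            n.loc[a, b] = n.loc[b, a] = int(keep.sum())
            r.loc[a, b] = r.loc[b, a] = spearman(table[a], table[b])
    return r, n


@dataclass
class RegressionResult:
    """One standardized multiple regression: criterion on all predictors.

    ``structure`` holds bivariate correlations divided by ``r_mult``; the
    bivariate convention (Spearman by default) is recorded in
    ``structure_corr``.
    """

    criterion: str
    predictors: list[str]
    beta: pd.Series
    r_mult: float
    r_squared: float
    f_pvalue: float
    n: int
    vif: pd.Series
    bivariate: pd.Series
    structure: pd.Series
    structure_corr: str

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "structure": self.structure,
                "bivariate": self.bivariate,
                "vif": self.vif,
            }
        )


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def standardized_ols(
    y: Sequence[float],
    X: pd.DataFrame,
    criterion: str = "y",
    structure_corr: Literal["spearman", "pearson"] = "spearman",
) -> RegressionResult:
    """OLS of a z-scored criterion on z-scored predictors, with listwise deletion.

    Returns standardized betas, R_mult (positive root of R^2), the model F
    test, VIFs, and structure coefficients computed from the configured
    bivariate correlation divided by R_mult.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=criterion)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X.loc[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"{criterion}: need n > p + 1 ({n} rows, {p} predictors)")
    Xz = _zscore(X.to_numpy())
    if np.linalg.matrix_rank(Xz) < p:
        # name columns that are linear combinations of the preceding ones
        bad = [
            X.columns[j]
            for j in range(p)
            if np.linalg.matrix_rank(Xz[:, : j + 1]) <= np.linalg.matrix_rank(Xz[:, :j])
        ]
        raise np.linalg.LinAlgError(f"{criterion}: collinear predictors {bad}")
    yz = _zscore(y.to_numpy())
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    beta = pd.Series(fit.params[1:], index=X.columns, name="beta")
    r_mult = float(np.sqrt(max(fit.rsquared, 0.0)))
    corr_fn = spearman if structure_corr == "spearman" else _pearson
    bivariate = pd.Series(
        {c: corr_fn(X[c].to_numpy(), y.to_numpy()) for c in X.columns}, name="bivariate"
    )
    return RegressionResult(
        criterion=criterion,
        predictors=list(X.columns),
        beta=beta,
        r_mult=r_mult,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=n,
        vif=vif(X),
        bivariate=bivariate,
        structure=pd.Series(
            structure_coefficients(bivariate.to_numpy(), r_mult), index=X.columns, name="structure"
        ),
        structure_corr=structure_corr,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    keep = ~(np.isnan(x) | np.isnan(y))
    return float(stats.pearsonr(x[keep], y[keep]).statistic)


def structure_coefficients(bivariate, r_mult: float):
    """Bivariate correlation(s) divided by the multiple correlation R.

    Scalar in, scalar out; NaN (with a warning) when R is zero.
    """
    arr = np.asarray(bivariate, dtype=float)
    if r_mult == 0:
        logger.warning("structure coefficients undefined: R_mult is zero")
        out = np.full_like(arr, np.nan)
    else:
        out = arr / r_mult
    return float(out) if out.ndim == 0 else out


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R_j^2).

    R_j is the multiple correlation of predictor j regressed on the others
    (with intercept). Perfectly collinear columns get +inf with a warning.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"VIF needs n > p ({n} rows, {p} predictors)")
    if (X.std(ddof=1) == 0).any():
        raise ValueError("VIF undefined for constant predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        if r2 >= 1 - 1e-12:
            logger.warning("predictor %s is perfectly collinear; VIF = inf", col)
            out[col] = float("inf")
        else:
            out[col] = float(1.0 / (1.0 - r2))
    return pd.Series(out, name="vif")


@dataclass
class AssociationResults:
    """Fitted association tables.

    Attributes mirror the study's report layout:

    trait_summary : per-dimension mean, sd, and Cronbach's alpha (when
        rater-level responses were supplied).
    trait_correlations : Big Five intercorrelations stacked with the
        career-metric x trait correlations.
    cue_correlations : 7 x 7 motion-cue intercorrelation matrix.
    cue_outcome_correlations : (traits + careers) x cues Spearman matrix.
    regressions : per-criterion :class:`RegressionResult`, criterion on the
        seven cues.
    """

    trait_summary: pd.DataFrame
    trait_correlations: pd.DataFrame
    trait_correlations_n: pd.DataFrame
    cue_correlations: pd.DataFrame
    cue_correlations_n: pd.DataFrame
    cue_outcome_correlations: pd.DataFrame
    regressions: dict[str, RegressionResult]
    n_speakers: int

    @property
    def regression_table(self) -> pd.DataFrame:
        """Long-form regression report: one row per criterion x predictor."""
        rows = []
        for crit, res in self.regressions.items():
            for pred in res.predictors:
                rows.append(
                    {
                        "criterion": crit,
                        "predictor": pred,
                        "beta": res.beta[pred],
                        "structure": res.structure[pred],
                        "vif": res.vif[pred],
                        "r_mult": res.r_mult,
                        "f_pvalue": res.f_pvalue,
                        "n": res.n,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text rendering, two decimals (stored values keep full precision)."""

        def fmt(df: pd.DataFrame) -> str:
            return df.round(2).to_string(na_rep="")

        lines = [
            f"Cue association report ({self.n_speakers} speakers)",
            "",
            "Trait summary (score mean/sd over speakers; alpha = internal consistency)",
            fmt(self.trait_summary),
            "",
            "Trait intercorrelations and career relations (Spearman r_s)",
            fmt(self.trait_correlations),
            "",
            "Motion-cue intercorrelations (Spearman r_s)",
            fmt(self.cue_correlations),
            "",
            "Cue x outcome correlations (Spearman r_s)",
            fmt(self.cue_outcome_correlations),
            "",
            "Multiple regressions of each outcome on the seven cues",
            "beta (structure coefficient in parentheses); * p<.05, ** p<.01 for the model F",
        ]
        for crit, res in self.regressions.items():
            stars = "**" if res.f_pvalue < 0.01 else "*" if res.f_pvalue < 0.05 else ""
            cells = "  ".join(
                f"{pred}: {res.beta[pred]:.2f}({res.structure[pred]:.2f})"
                for pred in res.predictors
            )
            lines.append(f"  {crit}: R = {res.r_mult:.2f}{stars}  {cells}")
            lines.append(
                "    VIF: "
                + "  ".join(f"{pred}: {res.vif[pred]:.2f}" for pred in res.predictors)
            )
        return "\n".join(lines)

    def to_csv(self, directory: str | Path, tables: Sequence[int] = (1, 2, 3, 4)) -> list[Path]:
        """Write report tables as CSVs (table1..table4) into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        mapping = {
            1: ("table1_traits.csv", self.trait_correlations),
            2: ("table2_cue_intercorrelations.csv", self.cue_correlations),
            3: ("table3_cue_outcome_correlations.csv", self.cue_outcome_correlations),
            4: ("table4_regressions.csv", self.regression_table),
        }
        for t in tables:
            name, df = mapping[t]
            p = directory / name
            df.to_csv(p, index=t != 4)
            written.append(p)
        if 1 in tables:
            p = directory / "table1_trait_summary.csv"
            self.trait_summary.to_csv(p)
            written.append(p)
        return written


class CueAssociationModel:
    """Relates per-speaker motion cues to impression scores and career metrics.

    Parameters
    ----------
    cues : DataFrame with ``speaker_id`` plus the seven cue columns.
    big5 : DataFrame indexed by speaker_id (or with a speaker_id column)
        with the five dimension columns.
    careers : like ``big5`` with the three career-metric columns; optional.
    alphas : optional per-dimension Cronbach's alpha to carry into the
        trait summary.
    structure_corr : bivariate convention for structure coefficients;
        'spearman' (default, matching the rank-based bivariate tables) or
        'pearson'.
    """

    def __init__(
        self,
        cues: pd.DataFrame,
        big5: pd.DataFrame,
        careers: pd.DataFrame | None = None,
        alphas: pd.Series | None = None,
        structure_corr: Literal["spearman", "pearson"] = "spearman",
    ):
        self.alphas = alphas
        self.structure_corr = structure_corr
        cues = cues.set_index("speaker_id") if "speaker_id" in cues.columns else cues
        big5 = big5.set_index("speaker_id") if "speaker_id" in big5.columns else big5
        frames = [cues[list(CUE_NAMES)], big5[list(DIMENSIONS)]]
        self.outcomes: list[str] = list(DIMENSIONS)
        if careers is not None:
            if "speaker_id" in careers.columns:
                careers = careers.set_index("speaker_id")
            frames.append(careers[list(CAREER_METRICS)])
            self.outcomes += list(CAREER_METRICS)
        joined = pd.concat(frames, axis=1, join="outer")
        unmatched = joined.index[joined[list(CUE_NAMES)].isna().all(axis=1)].tolist()
        unmatched += joined.index[joined[list(DIMENSIONS)].isna().all(axis=1)].tolist()
        if unmatched:
            raise ValueError(f"speakers missing from some input table: {sorted(set(unmatched))}")
        if len(joined) < 10:
            raise ValueError(f"need at least 10 joined speakers, got {len(joined)}")
        self.data = joined

    def fit(self) -> AssociationResults:
        """Compute all correlation matrices and per-outcome regressions."""
        data = self.data
        trait_cols = list(DIMENSIONS)
        career_cols = [c for c in CAREER_METRICS if c in data.columns]
        tc, tc_n = spearman_matrix(data[trait_cols + career_cols])
        trait_corr = tc.loc[trait_cols + career_cols, trait_cols]
        cue_corr, cue_n = spearman_matrix(data[list(CUE_NAMES)])
        outcome_corr = pd.DataFrame(
            {
                cue: {out: spearman(data[cue], data[out]) for out in self.outcomes}
                for cue in CUE_NAMES
            }
        ).loc[self.outcomes, list(CUE_NAMES)]
        summary = pd.DataFrame(
            {
                "mean": data[trait_cols].mean(),
                "sd": data[trait_cols].std(ddof=1),
            }
        )
        if self.alphas is not None:
            summary["alpha"] = self.alphas
        regressions = {
            out: standardized_ols(
                data[out],
                data[list(CUE_NAMES)],
                criterion=out,
                structure_corr=self.structure_corr,
            )
            for out in self.outcomes
        }
        return AssociationResults(
            trait_summary=summary,
            trait_correlations=trait_corr,
            trait_correlations_n=tc_n.loc[trait_cols + career_cols, trait_cols],
            cue_correlations=cue_corr,
            cue_correlations_n=cue_n,
            cue_outcome_correlations=outcome_corr,
            regressions=regressions,
            n_speakers=len(data),
        )


def build_reports(
    cues: pd.DataFrame,
    big5: pd.DataFrame,
    careers: pd.DataFrame | None = None,
    **kwargs,
) -> AssociationResults:
    """Functional shorthand for ``CueAssociationModel(...).fit()``."""
    return CueAssociationModel(cues, big5, careers, **kwargs).fit()
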