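"""Water-year ENSO covariates, the log-linear density model, and LMG.

Event mean density is modelled as

    log(mean density) = b0 + b1 * MEI_wy + b2 * year_index + eps

with the natural log (printed intercepts ~3.3-3.8 match ln of mean
densities 29-39 per 0.1 m^2), MEI_wy the mean monthly MEI over the
water-year window preceding the sample (September-October for fall
samples; September of the previous calendar year through April for
spring), and year_index a 0-based integer from the first survey year.

The model R^2 is decomposed per predictor with the LMG relative-importance
metric: each predictor's contribution is its sequential R^2 increment
averaged over all p! predictor orderings, computed here by exact
enumeration of all 2^p subset regressions.  Contributions sum exactly to
the full-model R^2 by construction; expressed as percents of total
variance they combine with the unexplained percent to 100.  The
environmental share of the long-term temporal CV is then the summed
predictor percents times the temporal CV.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import EnsoSeries, SurveyDataset, ValidationError
from .variability import CVPartition, partition_cv

#: (month, calendar-year offset relative to the sampling year) per season.
DEFAULT_WINDOWS: Dict[str, Tuple[Tuple[int, int], ...]] = {
    "fall": ((9, 0), (10, 0)),
    "spring": ((9, -1), (10, -1), (11, -1), (12, -1), (1, 0), (2, 0), (3, 0), (4, 0)),
}


@dataclass
class WaterYearWindow:
    season: str
    months: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.months:
            raise ValidationError("water-year window must be nonempty")
        for month, _ in self.months:
            if not (1 <= month <= 12):
                raise ValidationError(f"month {month} out of range")


def water_year_mei(
    enso: EnsoSeries,
    year: int,
    season: str,
    windows: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> float:
    """Mean monthly MEI over the season's water-year window before sampling."""
    windows = windows or DEFAULT_WINDOWS
    if season not in windows:
        raise ValidationError(f"no water-year window for season {season!r}")
    table = enso.as_dict()
    values = []
    for month, offset in windows[season]:
        key = (year + offset, month)
        if key not in table:
            raise ValidationError(
                f"MEI value missing for {key[0]}-{key[1]:02d} "
                f"({season} {year} water-year window)"
            )
        values.append(table[key])
    return float(np.mean(values))


@dataclass
class RegressionFit:
    b0: float
    b1_enso: float
    b2_year: Optional[float]
    r2: float
    f_statistic: float
    df: int
    residuals: np.ndarray
    n: int
    p_value: float
    collinear: bool = False


def event_covariates(
    dataset: SurveyDataset,
    enso: EnsoSeries,
    stream: Optional[str] = None,
    windows: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> pd.DataFrame:
    """Per-event table of mean density, water-year MEI and year index."""
    events = dataset.events_for(stream)
    if not events:
        raise ValidationError(f"no events for stream {stream!r}")
    year0 = min(ev.year for ev in events)
    rows = []
    for ev in events:
        rows.append(
            {
                "stream": ev.stream,
                "year": ev.year,
                "season": ev.season,
                "density": ev.mean_density,
                "mei": water_year_mei(enso, ev.year, ev.season, windows),
                "year_index": ev.year - year0,
            }
        )
    return pd.DataFrame(rows)


def fit_density_model(
    events: pd.DataFrame, predictors: Sequence[str] = ("mei", "year_index")
) -> RegressionFit:
    """OLS of ln(mean density) on the chosen predictors.

    ``events`` needs columns ``density`` plus the predictor columns.  The
    single-predictor MEI model is ``predictors=("mei",)``.
    """
    if len(events) < 4:
        raise ValidationError("need at least four events to fit")
    dens = events["density"].to_numpy(dtype=float)
    if (dens <= 0).any():
        raise ValidationError("densities must be positive for the log model")
    y = np.log(dens)
    X = sm.add_constant(events.loc[:, list(predictors)].to_numpy(dtype=float))
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    fit = sm.OLS(y, X).fit()
    coef = dict(zip(["const", *predictors], fit.params))
    return RegressionFit(
        b0=float(coef["const"]),
        b1_enso=float(coef.get("mei", math.nan)),
        b2_year=float(coef["year_index"]) if "year_index" in coef else None,
        r2=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=int(fit.df_resid),
        residuals=np.asarray(fit.resid),
        n=len(y),
        p_value=float(fit.f_pvalue),
        collinear=bool(collinear),
    )


@dataclass
class LMGResult:
    contributions: Dict[str, float]  # fraction of *total* variance, sums to r2
    model_r2: float
    percents: Dict[str, float]  # percent of total variance per predictor
    unexplained_percent: float


def _subset_r2(y: np.ndarray, X: np.ndarray, subset: Tuple[int, ...]) -> float:
    if not subset:
        return 0.0
    design = sm.add_constant(X[:, list(subset)])
    return float(sm.OLS(y, design).fit().rsquared)


def lmg_decomposition(
    response: Sequence[float],
    predictors: pd.DataFrame | np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> LMGResult:
    """LMG relative importance by exact enumeration of subset regressions.

    For predictor i the contribution is the average over all orderings of
    its sequential R^2 increment, i.e.
    ``sum over subsets S not containing i of w(|S|) (R^2(S+i) - R^2(S))``
    with ``w(s) = s! (p-1-s)! / p!``.  Exact for p <= 10.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise ValidationError("need at least one predictor")
    if p > 10:
        raise ValidationError("exact LMG enumeration is limited to 10 predictors")

    r2 = {
        subset: _subset_r2(y, X, subset)
        for size in range(p + 1)
        for subset in itertools.combinations(range(p), size)
    }
    full_r2 = r2[tuple(range(p))]
    fact = math.factorial
    contributions = {}
    for i in range(p):
        others = [j for j in range(p) if j != i]
        total = 0.0
        for size in range(p):
            w = fact(size) * fact(p - 1 - size) / fact(p)
            for S in itertools.combinations(others, size):
                with_i = tuple(sorted((*S, i)))
                total += w * (r2[with_i] - r2[S])
        contributions[names[i]] = total

    # enforce the sum identity exactly against float accumulation error
    drift = full_r2 - sum(contributions.values())
    if contributions:
        first = names[0]
        contributions[first] += drift
    percents = {k: 100.0 * v for k, v in contributions.items()}
    return LMGResult(
        contributions=contributions,
        model_r2=full_r2,
        percents=percents,
        unexplained_percent=100.0 * (1.0 - full_r2),
    )


def partition_temporal_cv(temporal_cv: float, lmg: LMGResult) -> CVPartition:
    """Environmental vs unexplained split of the long-term temporal CV.

    Each predictor's LMG percent of total variance times the temporal CV is
    its CV component; the remainder (100% minus the model R^2) is
    unexplained.
    """
    fractions = {k: v for k, v in lmg.contributions.items()}
    return partition_cv(temporal_cv, fractions)


def environmental_cv_component(temporal_cv: float, lmg: LMGResult) -> float:
    """Combined (all-predictor) environmental CV component."""
    return float(temporal_cv * sum(lmg.contributions.values()))
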