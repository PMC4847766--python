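"""Coefficient-of-variation estimation, partitioning and power analysis.

Three scales of variability in replicate-group survey data:

* **event** — CV of group-level densities within one sampling event;
* **within-reach** — the unweighted mean of event CVs at a stream;
* **temporal** — CV of event mean densities (or one family's event counts)
  across years.

A fraction of the within-reach CV attributable to a known source (e.g. the
mean taxon deviation due to subsampling) partitions it multiplicatively:
component CV = fraction x total CV, remainder unexplained.  Sample SD
(n - 1) is used throughout, as group counts are few (5-14 per event).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import SamplingEvent, SurveyDataset, ValidationError

CV_SCOPES = ("event", "stream_within_reach", "temporal", "taxon_temporal")


@dataclass
class CVResult:
    scope: str
    cv: float
    n: int
    range: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.scope not in CV_SCOPES:
            raise ValidationError(f"unknown CV scope {self.scope!r}")
        if self.cv < 0:
            raise ValidationError("cv must be nonnegative")


@dataclass
class CVPartition:
    total_cv: float
    components: Dict[str, Tuple[float, float]]  # label -> (fraction, cv part)
    unexplained: Tuple[float, float]


def _cv(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValidationError("CV needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError("CV undefined for nonpositive mean")
    return float(arr.std(ddof=1) / mean)


def group_density(group) -> float:
    """Group count expressed per 0.1 m^2 of subsampled substrate."""
    return group.total / (group.area_sampled / 0.1)


def event_cv(event: SamplingEvent) -> CVResult:
    """CV of group-level densities within one sampling event."""
    if len(event.groups) < 2:
        raise ValidationError(
            f"event {event.key} has {len(event.groups)} group(s); "
            "within-reach CV needs at least two"
        )
    dens = [group_density(g) for g in event.groups]
    return CVResult("event", _cv(dens), len(dens), (min(dens), max(dens)))


def within_reach_cv(
    dataset: SurveyDataset, stream: str, season: Optional[str] = None
) -> CVResult:
    """Unweighted mean of event CVs at a stream, with the range of event CVs.

    Events with fewer than two groups are skipped (their reach-level CV is
    not computable).
    """
    cvs = [
        event_cv(ev).cv
        for ev in dataset.events_for(stream, season)
        if len(ev.groups) >= 2
    ]
    if not cvs:
        raise ValidationError(f"no CV-eligible events at {stream!r}")
    return CVResult(
        "stream_within_reach", float(np.mean(cvs)), len(cvs), (min(cvs), max(cvs))
    )


def season_cv_comparison(dataset: SurveyDataset, stream: Optional[str] = None):
    """Two-sided two-sample t-test of event CVs, spring vs fall.

    Returns ``(t, df, p)`` pooling streams unless one is named.
    """
    by_season = {}
    for season in ("spring", "fall"):
        evs = [
            ev
            for ev in dataset.events
            if ev.season == season
            and (stream is None or ev.stream == stream)
            and len(ev.groups) >= 2
        ]
        by_season[season] = [event_cv(ev).cv for ev in evs]
    x, y = by_season["spring"], by_season["fall"]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 eligible events per season")
    res = stats.ttest_ind(x, y)
    return (float(res.statistic), len(x) + len(y) - 2, float(res.pvalue))


def temporal_cv(
    dataset: SurveyDataset,
    stream: str,
    season: Optional[str] = None,
    family: Optional[str] = None,
) -> CVResult:
    """CV across sampling events of mean density (or one family's counts)."""
    events = dataset.events_for(stream, season)
    if family is None:
        series = [ev.mean_density for ev in events]
        scope = "temporal"
    else:
        series = [float(ev.total_counts.get(family, 0)) for ev in events]
        scope = "taxon_temporal"
    if len(series) < 2:
        raise ValidationError(f"fewer than two events in scope at {stream!r}")
    return CVResult(scope, _cv(series), len(series), (min(series), max(series)))


def partition_cv(total_cv: float, fractions: Mapping[str, float]) -> CVPartition:
    """Split a CV into labelled components plus an unexplained remainder.

    Each component's CV is its fraction times the total; e.g. a 0.50
    within-reach CV with 62% due to subsampling yields a 0.31 subsampling
    component.
    """
    if total_cv < 0:
        raise ValidationError("total_cv must be nonnegative")
    for label, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ValidationError(f"fraction for {label!r} outside [0, 1]: {f}")
    s = float(sum(fractions.values()))
    if s > 1.0 + 1e-12:
        raise ValidationError(f"fractions sum to {s} > 1")
    components = {
        label: (float(f), float(f) * total_cv) for label, f in fractions.items()
    }
    rem = max(0.0, 1.0 - s)
    return CVPartition(
        total_cv=float(total_cv),
        components=components,
        unexplained=(rem, rem * total_cv),
    )


# ---------------------------------------------------------------------------
# Minimum detectable change (Monte-Carlo power analysis)

def power_of_change(
    cv: float,
    n_groups: int,
    change: float,
    alpha: float = 0.05,
    replicates: int = 1000,
    seed=None,
    _base: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Monte-Carlo power of a two-sided two-sample t-test on log densities.

    Group densities are lognormal with the given CV; the second arm's
    median is shifted by ``(1 + change)``.  ``change`` = 0 recovers the
    type-I error rate.
    """
    if cv <= 0:
        raise ValidationError("cv must be positive")
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    sigma = math.sqrt(math.log1p(cv * cv))
    if _base is None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        z1 = rng.normal(size=(replicates, n_groups))
        z2 = rng.normal(size=(replicates, n_groups))
    else:
        z1, z2 = _base
    logx = sigma * z1
    logy = sigma * z2 + math.log1p(change)
    t, p = stats.ttest_ind(logx, logy, axis=1)
    return float(np.mean(p < alpha))


def detectable_change(
    cv: float,
    n_groups: int,
    alpha: float = 0.05,
    power: float = 0.8,
    replicates: int = 1000,
    seed=None,
    max_change: float = 5.0,
    tol: float = 0.01,
) -> Optional[float]:
    """Smallest fractional density change detectable at the target power.

    Bisects the Monte-Carlo power curve (common random numbers across
    evaluations keep it monotone) between 0 and ``max_change`` (500%).
    Returns ``None`` when even the largest change is undetectable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = (
        rng.normal(size=(replicates, n_groups)),
        rng.normal(size=(replicates, n_groups)),
    )

    def pw(change: float) -> float:
        return power_of_change(cv, n_groups, change, alpha, replicates, _base=base)

    if pw(max_change) < power:
        return None
    lo, hi = 0.0, max_change
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pw(mid) >= power:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# Rank-based two-sample test

def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 16
) -> Tuple[float, float]:
    """Mann-Whitney rank-sum test with average ranks on ties.

    Returns ``(U, p)`` where U is the statistic for ``x``.  When the
    combined sample size is at most ``exact_threshold`` the two-sided p is
    computed by exhaustive enumeration of all C(n+m, n) labellings of the
    pooled (tied) ranks; otherwise the normal approximation with tie
    correction (and continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p = 1 by convention")
        return (u_obs, 1.0)
    if n + m <= exact_threshold:
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return (u_obs, hits / total)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return (float(res.statistic), float(res.pvalue))
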