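"""Family-level Index of Biotic Integrity (IBI).

Six metrics are computed from an event's summed counts — total, mayfly,
stonefly and caddisfly family richness (higher is better), percent Diptera
and percent dominance by the single most abundant family (lower is
better).  Each metric scores 1, 3 or 5 against two breakpoints, totals run
6-30, and the total maps to a stream-condition category: severely impaired
(<= 16), moderately impaired (17-23), unimpaired (> 23).

Breakpoints are region-specific calibration values and are therefore
mandatory configuration; the defaults shipped here are plausible
placeholders for a western-Oregon family-level IBI, not a published
calibration.  The boundary total of 16 (unassigned by the open-interval
category wording) is placed in the severely-impaired band so that the
category mapping is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .types import SamplingEvent, SurveyDataset, ValidationError

METRICS = (
    "total_richness",
    "mayfly_richness",
    "stonefly_richness",
    "caddisfly_richness",
    "pct_diptera",
    "pct_dominance",
)

#: Metrics where a *lower* raw value is better.
LOWER_IS_BETTER = ("pct_diptera", "pct_dominance")

CATEGORIES = ("severely impaired", "moderately impaired", "unimpaired")


@dataclass
class MetricBreakpoints:
    """Two thresholds mapping a raw metric to {1, 3, 5}.

    For higher-is-better metrics: >= ``high`` scores 5, >= ``low`` scores 3,
    else 1.  For lower-is-better metrics: <= ``low`` scores 5, <= ``high``
    scores 3, else 1.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError("breakpoints must satisfy low <= high")


DEFAULT_BREAKPOINTS: Dict[str, MetricBreakpoints] = {
    "total_richness": MetricBreakpoints(8, 13),
    "mayfly_richness": MetricBreakpoints(2, 4),
    "stonefly_richness": MetricBreakpoints(2, 4),
    "caddisfly_richness": MetricBreakpoints(2, 4),
    "pct_diptera": MetricBreakpoints(10, 25),
    "pct_dominance": MetricBreakpoints(25, 45),
}


@dataclass
class IBIConfig:
    breakpoints: Dict[str, MetricBreakpoints] = field(
        default_factory=lambda: dict(DEFAULT_BREAKPOINTS)
    )
    severe_max: int = 16  # totals <= this are severely impaired
    moderate_max: int = 23  # totals <= this (and > severe_max) are moderate

    def __post_init__(self) -> None:
        missing = set(METRICS) - set(self.breakpoints)
        if missing:
            raise ValidationError(f"missing breakpoints for {sorted(missing)}")
        if not (6 <= self.severe_max < self.moderate_max < 30):
            raise ValidationError("category bounds must cover totals 6..30")

    def category(self, total: int) -> str:
        if total <= self.severe_max:
            return "severely impaired"
        if total <= self.moderate_max:
            return "moderately impaired"
        return "unimpaired"


@dataclass
class IBIResult:
    stream: str
    year: int
    season: str
    metrics: Dict[str, float]
    scores: Dict[str, int]
    total: int
    category: str


def ibi_metrics(
    event: SamplingEvent, order_of: Mapping[str, str]
) -> Dict[str, float]:
    """The six raw IBI metrics from an event's summed counts.

    ``order_of`` maps each family to its order group (mayfly, stonefly,
    caddisfly, diptera, other).
    """
    counts = {f: c for f, c in event.total_counts.items() if c > 0}
    abundance = sum(counts.values())
    if abundance <= 0:
        raise ValidationError(f"event {event.key} has zero abundance")
    by_order: Dict[str, int] = {}
    for fam in counts:
        by_order[order_of[fam]] = by_order.get(order_of[fam], 0) + 1
    diptera_count = sum(
        c for f, c in counts.items() if order_of[f] == "diptera"
    )
    return {
        "total_richness": float(len(counts)),
        "mayfly_richness": float(by_order.get("mayfly", 0)),
        "stonefly_richness": float(by_order.get("stonefly", 0)),
        "caddisfly_richness": float(by_order.get("caddisfly", 0)),
        "pct_diptera": 100.0 * diptera_count / abundance,
        "pct_dominance": 100.0 * max(counts.values()) / abundance,
    }


def score_metric(name: str, value: float, bp: MetricBreakpoints) -> int:
    if name in LOWER_IS_BETTER:
        if not (0.0 <= value <= 100.0):
            raise ValidationError(f"{name} = {value} outside [0, 100]")
        if value <= bp.low:
            return 5
        return 3 if value <= bp.high else 1
    if value < 0:
        raise ValidationError(f"{name} = {value} must be nonnegative")
    if value >= bp.high:
        return 5
    return 3 if value >= bp.low else 1


def ibi_score(
    metrics: Mapping[str, float],
    config: Optional[IBIConfig] = None,
    stream: str = "",
    year: int = 0,
    season: str = "fall",
) -> IBIResult:
    """Score six raw metrics to an IBI total and condition category."""
    config = config or IBIConfig()
    missing = set(METRICS) - set(metrics)
    if missing:
        raise ValidationError(f"missing metric(s) {sorted(missing)}")
    scores = {
        m: score_metric(m, float(metrics[m]), config.breakpoints[m]) for m in METRICS
    }
    total = sum(scores.values())
    assert 6 <= total <= 30
    return IBIResult(
        stream=stream,
        year=year,
        season=season,
        metrics=dict(metrics),
        scores=scores,
        total=total,
        category=config.category(total),
    )


@dataclass
class IBISeries:
    results: List[IBIResult]
    median: float
    range: Tuple[int, int]
    category_proportions: Dict[str, float]


def ibi_series(
    dataset: SurveyDataset,
    stream: Optional[str] = None,
    season: Optional[str] = None,
    config: Optional[IBIConfig] = None,
) -> IBISeries:
    """Per-event IBI results for a stream plus median, range and category mix."""
    config = config or IBIConfig()
    order_of = {t.family_name: t.order_group for t in dataset.taxa}
    events = dataset.events_for(stream, season)
    if not events:
        raise ValidationError(f"no events in scope for stream={stream!r}")
    results = [
        ibi_score(
            ibi_metrics(ev, order_of),
            config,
            stream=ev.stream,
            year=ev.year,
            season=ev.season,
        )
        for ev in events
    ]
    totals = [r.total for r in results]
    props = {
        cat: sum(r.category == cat for r in results) / len(results)
        for cat in CATEGORIES
    }
    return IBISeries(
        results=results,
        median=float(median(totals)),
        range=(min(totals), max(totals)),
        category_proportions=props,
    )


def ibi_comparison(
    dataset: SurveyDataset,
    by: str = "stream",
    config: Optional[IBIConfig] = None,
) -> Tuple[float, float]:
    """Mann-Whitney comparison of IBI totals between streams or seasons."""
    from .variability import mann_whitney

    if by == "stream":
        levels = dataset.streams
        totals = [
            [r.total for r in ibi_series(dataset, stream=s, config=config).results]
            for s in levels
        ]
    elif by == "season":
        totals = [
            [r.total for r in ibi_series(dataset, season=s, config=config).results]
            for s in ("fall", "spring")
        ]
    else:
        raise ValidationError("by must be 'stream' or 'season'")
    if len(totals) != 2:
        raise ValidationError("comparison needs exactly two levels")
    return mann_whitney(totals[0], totals[1])
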