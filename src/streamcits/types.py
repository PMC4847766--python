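"""Core domain types for citizen-science stream macroinvertebrate surveys.

The sampling design these types describe: groups of 3-5 volunteers each
collect three D-net benthic samples from a riffle, composite them, and
field-subsample roughly one third of the composite (about 0.1 m^2 of
substrate).  A *sampling event* is the set of group-level samples taken at
one stream on one date; a *survey* is the collection of events across
streams, seasons and years.  Densities are expressed per 0.1 m^2 of
subsampled substrate throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import math

ORDER_GROUPS = ("mayfly", "stonefly", "caddisfly", "diptera", "other")
SEASONS = ("fall", "spring")
SIZE_CLASSES = ("small", "medium", "large")

#: Taxa dropped from analysis by default.  Mites are too small to see
#: reliably in the field, so they are excluded from all counts.
DEFAULT_EXCLUDED_TAXA = ("Hydracarina", "Acari")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


@dataclass(frozen=True)
class TaxonRecord:
    """A family-level taxon with its order group and a coarse body-size class.

    ``body_size_class`` only matters to the synthetic field-detection model
    (small animals are harder to spot in a tray under ambient light); real
    survey files need not supply it.
    """

    family_name: str
    order_group: str
    body_size_class: str = "medium"

    def __post_init__(self) -> None:
        if not self.family_name:
            raise ValidationError("family_name must be nonempty")
        if self.order_group not in ORDER_GROUPS:
            raise ValidationError(
                f"order_group {self.order_group!r} not in {ORDER_GROUPS}"
            )
        if self.body_size_class not in SIZE_CLASSES:
            raise ValidationError(
                f"body_size_class {self.body_size_class!r} not in {SIZE_CLASSES}"
            )


@dataclass
class GroupSample:
    """One volunteer group's subsample counts for a single sampling event.

    ``area_sampled`` is the subsampled substrate area in m^2 (0.1 m^2 for
    the standard protocol: five of eighteen tray cells from a 0.3 m^2
    composite).
    """

    stream: str
    year: int
    season: str
    group_id: str
    counts: Dict[str, int]
    area_sampled: float = 0.1

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(f"season {self.season!r} not in {SEASONS}")
        if self.area_sampled <= 0:
            raise ValidationError("area_sampled must be > 0")
        for fam, c in self.counts.items():
            if c < 0:
                raise ValidationError(f"negative count for {fam!r}: {c}")
            if int(c) != c:
                raise ValidationError(f"non-integer count for {fam!r}: {c}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class SamplingEvent:
    """All group samples collected at one stream in one (year, season).

    Derived quantities are computed from ``groups`` so they can never drift
    out of sync with the data:

    * ``event_abundance`` — total invertebrates over all groups;
    * ``mean_density`` — event abundance divided by the number of groups,
      i.e. mean count per 0.1 m^2 subsample;
    * ``total_area`` — summed subsampled area in m^2.
    """

    stream: str
    year: int
    season: str
    groups: List[GroupSample]

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValidationError("a sampling event needs at least one group")
        if self.season not in SEASONS:
            raise ValidationError(f"season {self.season!r} not in {SEASONS}")
        for g in self.groups:
            if (g.stream, g.year, g.season) != (self.stream, self.year, self.season):
                raise ValidationError(
                    f"group {g.group_id!r} labelled {(g.stream, g.year, g.season)} "
                    f"inside event {(self.stream, self.year, self.season)}"
                )

    @property
    def event_abundance(self) -> int:
        return sum(g.total for g in self.groups)

    @property
    def mean_density(self) -> float:
        return self.event_abundance / len(self.groups)

    @property
    def total_area(self) -> float:
        return sum(g.area_sampled for g in self.groups)

    @property
    def total_counts(self) -> Dict[str, int]:
        """Event-level summed counts per family."""
        out: Dict[str, int] = {}
        for g in self.groups:
            for fam, c in g.counts.items():
                out[fam] = out.get(fam, 0) + int(c)
        return out

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.stream, self.year, self.season)


def event_summary(event: SamplingEvent) -> Tuple[int, float, float]:
    """Return ``(event_abundance, mean_density, total_area)`` for an event.

    Example: four groups totalling 147 invertebrates give a mean density of
    36.75 per 0.1 m^2 over 0.4 m^2 of subsampled substrate.
    """
    if len(event.groups) < 1:
        raise ValidationError("a sampling event needs at least one group")
    return (event.event_abundance, event.mean_density, event.total_area)


@dataclass
class SurveyDataset:
    """A full survey: sampling events plus the taxon roster they draw on."""

    events: List[SamplingEvent]
    taxa: List[TaxonRecord]

    def __post_init__(self) -> None:
        known = {t.family_name for t in self.taxa}
        seen_keys = set()
        for ev in self.events:
            if ev.key in seen_keys:
                raise ValidationError(f"duplicate sampling event {ev.key}")
            seen_keys.add(ev.key)
            for g in ev.groups:
                unknown = set(g.counts) - known
                if unknown:
                    raise ValidationError(
                        f"families {sorted(unknown)} in event {ev.key} "
                        "missing from the taxon roster"
                    )

    @property
    def streams(self) -> List[str]:
        return sorted({ev.stream for ev in self.events})

    def events_for(
        self, stream: str | None = None, season: str | None = None
    ) -> List[SamplingEvent]:
        out = [
            ev
            for ev in self.events
            if (stream is None or ev.stream == stream)
            and (season is None or ev.season == season)
        ]
        return sorted(out, key=lambda e: (e.stream, e.year, e.season))

    def order_group_of(self, family: str) -> str:
        for t in self.taxa:
            if t.family_name == family:
                return t.order_group
        raise KeyError(family)


@dataclass
class EnsoSeries:
    """Monthly multivariate ENSO index (MEI) values.

    The MEI is a dimensionless signed climate signal: negative values mark
    La Nina conditions, positive values El Nino.
    """

    records: List[Tuple[int, int, float]]

    def __post_init__(self) -> None:
        seen = set()
        for year, month, value in self.records:
            if not (1 <= month <= 12):
                raise ValidationError(f"month {month} out of range for year {year}")
            if (year, month) in seen:
                raise ValidationError(f"duplicate MEI record for {year}-{month:02d}")
            if not math.isfinite(value):
                raise ValidationError(f"non-finite MEI value at {year}-{month:02d}")
            seen.add((year, month))

    def value(self, year: int, month: int) -> float:
        for y, m, v in self.records:
            if (y, m) == (year, month):
                return v
        raise KeyError(f"no MEI value for {year}-{month:02d}")

    def as_dict(self) -> Dict[Tuple[int, int], float]:
        return {(y, m): v for y, m, v in self.records}


@dataclass
class AnalysisConfig:
    """Run-wide knobs shared by the analysis stages."""

    resample_replicates: int = 1000
    permutations: int = 1000
    rng_seed: int = 0
    min_relative_abundance_filter: float = 0.05
    exclude_taxa: Tuple[str, ...] = DEFAULT_EXCLUDED_TAXA

    def __post_init__(self) -> None:
        if self.resample_replicates < 1:
            raise ValidationError("resample_replicates must be >= 1")
        if not (0 <= self.min_relative_abundance_filter < 1):
            raise ValidationError("min_relative_abundance_filter must be in [0, 1)")
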