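"""Validated CSV readers and writers for surveys and the monthly MEI table.

Surveys travel as long (tidy) tables — one row per (event, group, family)
with a positive count — because the taxon list varies across events and
streams.  A wide event-by-family export is provided as a convenience for
ordination work.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .types import (
    AnalysisConfig,
    EnsoSeries,
    FormatError,
    GroupSample,
    SamplingEvent,
    SurveyDataset,
    TaxonRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

SURVEY_COLUMNS = ["stream", "year", "season", "group_id", "family", "order_group", "count"]
ENSO_COLUMNS = ["year", "month", "value"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_survey(path, config: AnalysisConfig | None = None) -> SurveyDataset:
    """Read a long-format survey CSV into a validated :class:`SurveyDataset`.

    Rows whose family is in ``config.exclude_taxa`` (mites by default) are
    dropped; the number of dropped rows is logged.  Zero-count rows are
    permitted on read.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, path)

    bad = df.index[df["count"] < 0]
    if len(bad):
        # +2: header line plus 1-based row numbering
        raise ValidationError(f"{path}: negative count at row {bad[0] + 2}")

    excluded = df["family"].isin(set(config.exclude_taxa))
    if excluded.any():
        log.info("dropped %d excluded-taxon row(s) from %s", int(excluded.sum()), path)
        df = df[~excluded]

    taxa: Dict[str, TaxonRecord] = {}
    for fam, grp in df.groupby("family", sort=True):
        orders = grp["order_group"].unique()
        if len(orders) > 1:
            raise ValidationError(
                f"{path}: family {fam!r} mapped to multiple order groups {sorted(orders)}"
            )
        taxa[str(fam)] = TaxonRecord(str(fam), str(orders[0]))

    events: List[SamplingEvent] = []
    for (stream, year, season), ev_rows in df.groupby(
        ["stream", "year", "season"], sort=True
    ):
        groups = []
        for gid, g_rows in ev_rows.groupby("group_id", sort=True):
            counts = {
                str(r.family): int(r.count) for r in g_rows.itertuples(index=False)
            }
            groups.append(
                GroupSample(str(stream), int(year), str(season), str(gid), counts)
            )
        events.append(SamplingEvent(str(stream), int(year), str(season), groups))

    return SurveyDataset(events=events, taxa=sorted(taxa.values(), key=lambda t: t.family_name))


def survey_frame(dataset: SurveyDataset) -> pd.DataFrame:
    """Long-format frame in canonical column and row order, zero counts dropped."""
    order_of = {t.family_name: t.order_group for t in dataset.taxa}
    rows = []
    for ev in dataset.events:
        for g in ev.groups:
            for fam, c in g.counts.items():
                if c > 0:
                    rows.append(
                        (ev.stream, ev.year, ev.season, g.group_id, fam, order_of[fam], int(c))
                    )
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    return df.sort_values(
        ["stream", "year", "season", "group_id", "family"], kind="mergesort"
    ).reset_index(drop=True)


def write_survey(dataset: SurveyDataset, path) -> None:
    """Write a dataset as a canonical long CSV (read/write round-trips)."""
    survey_frame(dataset).to_csv(path, index=False)


def write_survey_wide(dataset: SurveyDataset, path) -> None:
    """Convenience wide export: one row per event, one column per family."""
    rows = []
    for ev in sorted(dataset.events, key=lambda e: e.key):
        row: Dict[str, object] = {
            "stream": ev.stream,
            "year": ev.year,
            "season": ev.season,
        }
        row.update(ev.total_counts)
        rows.append(row)
    fams = sorted(t.family_name for t in dataset.taxa)
    df = pd.DataFrame(rows, columns=["stream", "year", "season", *fams]).fillna(0)
    df[fams] = df[fams].astype(int)
    df.to_csv(path, index=False)


def read_enso(path) -> EnsoSeries:
    """Read a monthly MEI table (columns: year, month, value)."""
    df = pd.read_csv(path)
    _require_columns(df, ENSO_COLUMNS, path)
    records = [
        (int(r.year), int(r.month), float(r.value))
        for r in df.itertuples(index=False)
    ]
    return EnsoSeries(records=records)


def write_enso(series: EnsoSeries, path) -> None:
    df = pd.DataFrame(sorted(series.records), columns=ENSO_COLUMNS)
    df.to_csv(path, index=False)


def read_paired_samples(path):
    """Read paired field/lab/total counts from a long CSV.

    Expected columns: sample_id, stream, component (field|lab|total),
    family, count.  Returns a list of :class:`~streamcits.nullmodel.PairedSample`.
    """
    from .nullmodel import PairedSample

    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "stream", "component", "family", "count"], path)
    bad = set(df["component"]) - {"field", "lab", "total"}
    if bad:
        raise FormatError(f"{path}: unknown component value(s) {sorted(bad)}")
    out = []
    for (sid, stream), grp in df.groupby(["sample_id", "stream"], sort=True):
        parts: Dict[str, Dict[str, int]] = {"field": {}, "lab": {}, "total": {}}
        for r in grp.itertuples(index=False):
            if r.count < 0:
                raise ValidationError(f"{path}: negative count in sample {sid!r}")
            parts[r.component][str(r.family)] = int(r.count)
        out.append(
            PairedSample(
                sample_id=str(sid),
                stream=str(stream),
                field_counts=parts["field"],
                lab_counts=parts["lab"],
                total_counts=parts["total"],
            )
        )
    return out


def write_paired_samples(samples, path) -> None:
    rows = []
    for s in sorted(samples, key=lambda s: (s.stream, s.sample_id)):
        for component, counts in (
            ("field", s.field_counts),
            ("lab", s.lab_counts),
            ("total", s.total_counts),
        ):
            for fam in sorted(counts):
                if counts[fam] > 0:
                    rows.append((s.sample_id, s.stream, component, fam, int(counts[fam])))
    pd.DataFrame(
        rows, columns=["sample_id", "stream", "component", "family", "count"]
    ).to_csv(path, index=False)
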