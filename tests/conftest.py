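import numpy as np
import pytest

from streamcits.synthetic import (
    CommunitySpec,
    ReachSpec,
    TemporalSpec,
    default_community,
    default_seasonal_shift,
    simulate_survey,
    synthetic_enso,
)
from streamcits.types import GroupSample, SamplingEvent, SurveyDataset, TaxonRecord


@pytest.fixture
def community():
    return default_community()


@pytest.fixture
def reach():
    return ReachSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20160427)


def make_event(densities, stream="Balch", year=2007, season="fall", family="Baetidae"):
    """Event whose group totals are exactly the given densities."""
    groups = [
        GroupSample(stream, year, season, f"G{i}", {family: int(d)})
        for i, d in enumerate(densities)
    ]
    return SamplingEvent(stream, year, season, groups)


@pytest.fixture
def tiny_dataset():
    """Two streams x two seasons x two years of hand-built events."""
    events = []
    for stream, base in (("Balch", 20), ("Lookout", 40)):
        for year in (2005, 2006):
            for season, shift in (("fall", 0), ("spring", 5)):
                groups = [
                    GroupSample(
                        stream, year, season, f"G{i}",
                        {"Baetidae": base + shift + 2 * i, "Chironomidae": 5 + i},
                    )
                    for i in range(4)
                ]
                events.append(SamplingEvent(stream, year, season, groups))
    taxa = [
        TaxonRecord("Baetidae", "mayfly", "small"),
        TaxonRecord("Chironomidae", "diptera", "small"),
    ]
    return SurveyDataset(events=events, taxa=taxa)


@pytest.fixture(scope="session")
def simulated_survey():
    """One default-parameter simulated survey (11 years x 2 seasons)."""
    years = list(range(2005, 2016))
    enso = synthetic_enso(years, seed=7)
    temporal = TemporalSpec(seasonal_shift=default_seasonal_shift())
    dataset = simulate_survey(
        default_community(), ReachSpec(), temporal, enso, years, seed=11
    )
    return dataset, enso
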