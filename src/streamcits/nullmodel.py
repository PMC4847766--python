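"""Subsampling null model and the taxon-deviation statistic.

A fully enumerated *total* count vector for a physical sample defines the
null distribution of what any honest random subsample of m individuals can
look like: each of R replicates draws m individuals without replacement
from the pooled total (a multivariate hypergeometric draw — a physical
subsample cannot pick the same animal twice).  The mean relative abundance
over replicates is the null benchmark X_null, and a method's observed
relative abundance X_obs for each taxon is scored as the relative deviation

    deviation = (X_obs - X_null) / X_null.

The absolute deviation measures subsampling error; its sign measures bias.
The subsample size m is the median of the field and lab subsample counts,
rounded half-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import ValidationError


@dataclass
class PairedSample:
    """Field subsample, lab subsample and fully enumerated total counts."""

    sample_id: str
    stream: str
    field_counts: Dict[str, int]
    lab_counts: Dict[str, int]
    total_counts: Dict[str, int]

    def __post_init__(self) -> None:
        for name, counts in (
            ("field", self.field_counts),
            ("lab", self.lab_counts),
            ("total", self.total_counts),
        ):
            for fam, c in counts.items():
                if c < 0:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: negative {name} count for {fam!r}"
                    )
        tot = sum(self.total_counts.values())
        if tot < sum(self.field_counts.values()) or tot < sum(self.lab_counts.values()):
            raise ValidationError(
                f"sample {self.sample_id!r}: total count smaller than a subsample"
            )

    @property
    def field_total(self) -> int:
        return int(sum(self.field_counts.values()))

    @property
    def lab_total(self) -> int:
        return int(sum(self.lab_counts.values()))


@dataclass
class NullModel:
    """R re-subsampled count vectors and their mean relative abundance."""

    target_count: int
    replicates: int
    families: List[str]
    draws: np.ndarray  # shape (R, n_families), each row sums to target_count
    null_mean_rel_abundance: Dict[str, float]
    seed: int | None = None


@dataclass
class DeviationTable:
    """Per-taxon deviations of one observed subsample from its null mean."""

    sample_id: str
    signed_deviation: Dict[str, float]
    absolute_deviation: Dict[str, float]
    null_mean: Dict[str, float]
    missed_taxa: List[str]  # present in totals but never drawn by the null
    mean_abs_deviation: float
    sd_abs_deviation: float


def median_target(field_total: int, lab_total: int) -> int:
    """Subsample size for the null model: median of the two counts, half-up.

    E.g. field 183 and lab 179 give 181; (3, 4) gives 4.
    """
    if field_total <= 0 or lab_total <= 0:
        raise ValidationError("both subsample totals must be positive")
    return int(math.floor((field_total + lab_total) / 2.0 + 0.5))


def resample_null(
    total_counts: Mapping[str, int], m: int, R: int = 1000, seed=None
) -> NullModel:
    """Draw R subsamples of m individuals without replacement from the total.

    Each draw is multivariate hypergeometric on the pooled counts; the null
    mean relative abundance is the average of per-replicate relative
    abundances (each replicate sums to m exactly, so this equals the mean
    count vector divided by m).
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    families = sorted(f for f in total_counts if total_counts[f] > 0)
    pool = np.array([int(total_counts[f]) for f in families])
    if m > pool.sum():
        raise ValidationError(f"target count {m} exceeds pool size {pool.sum()}")
    if m <= 0:
        raise ValidationError("target count must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.vstack(
        [rng.multivariate_hypergeometric(pool, m) for _ in range(R)]
    )
    rel = draws / float(m)
    null_mean = {f: float(v) for f, v in zip(families, rel.mean(axis=0))}
    return NullModel(
        target_count=m,
        replicates=R,
        families=families,
        draws=draws,
        null_mean_rel_abundance=null_mean,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def taxon_deviation(observed_rel: float, null_mean: float) -> float:
    """Relative deviation (X_obs - X_null) / X_null; null mean must be > 0."""
    if null_mean <= 0:
        raise ValidationError("null mean relative abundance must be positive")
    return (observed_rel - null_mean) / null_mean


def deviation_table(
    observed_counts: Mapping[str, int], null: NullModel, sample_id: str = ""
) -> DeviationTable:
    """Score one observed subsample against a null model.

    Taxa with a null mean of zero (never drawn in any replicate) cannot be
    scored by the relative-deviation statistic; they are flagged in
    ``missed_taxa`` and excluded from the summaries.
    """
    obs_total = float(sum(observed_counts.values()))
    if obs_total <= 0:
        raise ValidationError("observed subsample is empty")
    signed: Dict[str, float] = {}
    missed: List[str] = []
    families = set(null.families) | set(observed_counts)
    for fam in sorted(families):
        nm = null.null_mean_rel_abundance.get(fam, 0.0)
        if nm <= 0:
            missed.append(fam)
            continue
        obs_rel = float(observed_counts.get(fam, 0)) / obs_total
        signed[fam] = taxon_deviation(obs_rel, nm)
    absdev = {f: abs(v) for f, v in signed.items()}
    vals = np.array(list(absdev.values()))
    return DeviationTable(
        sample_id=sample_id,
        signed_deviation=signed,
        absolute_deviation=absdev,
        null_mean={f: null.null_mean_rel_abundance.get(f, 0.0) for f in signed},
        missed_taxa=missed,
        mean_abs_deviation=float(vals.mean()) if len(vals) else float("nan"),
        sd_abs_deviation=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


def summarize_deviation(
    tables: Sequence[DeviationTable], min_rel_filter: float = 0.0
) -> Tuple[float, float, int]:
    """Pooled mean and SD of absolute deviations across all retained taxa.

    With ``min_rel_filter`` > 0 only taxa whose null mean relative abundance
    exceeds the filter are retained (e.g. 0.05 keeps taxa above 5% relative
    abundance).  Returns ``(mean, sd, n)`` over taxon-by-sample values.
    """
    if not tables:
        raise ValidationError("need at least one deviation table")
    vals: List[float] = []
    for t in tables:
        for fam, dev in t.absolute_deviation.items():
            if t.null_mean.get(fam, 0.0) > min_rel_filter:
                vals.append(dev)
    if not vals:
        raise ValidationError("no taxa retained after filtering")
    arr = np.sort(np.array(vals))  # deterministic summation order
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return (float(arr.mean()), sd, len(arr))


def per_sample_means(
    tables: Sequence[DeviationTable], min_rel_filter: float = 0.0
) -> List[float]:
    """Mean absolute deviation per sample (the t-test's unit of analysis)."""
    out = []
    for t in tables:
        vals = [
            d
            for fam, d in t.absolute_deviation.items()
            if t.null_mean.get(fam, 0.0) > min_rel_filter
        ]
        if vals:
            out.append(float(np.mean(vals)))
    return out


def paired_t_test(
    field_means: Sequence[float], lab_means: Sequence[float]
) -> Tuple[float, int, float]:
    """Two-tailed paired t-test on per-sample mean deviations.

    Returns ``(t, df, p)`` with df = n - 1.  Degenerate inputs (zero
    variance of the differences) are flagged with a warning: identical
    vectors give t = 0, p = 1; a constant nonzero difference gives an
    infinite t and p = 0.
    """
    x = np.asarray(field_means, dtype=float)
    y = np.asarray(lab_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("field and lab vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance of paired differences; p is degenerate")
        if np.allclose(d, 0):
            return (0.0, n - 1, 1.0)
        return (math.copysign(math.inf, d.mean()), n - 1, 0.0)
    res = stats.ttest_rel(x, y)
    return (float(res.statistic), n - 1, float(res.pvalue))


def deviation_vs_count_correlation(
    tables: Sequence[DeviationTable], counts: Sequence[int]
) -> float:
    """Pearson correlation of per-sample mean absolute deviation with
    subsample count (signed; reported as computed)."""
    means = [t.mean_abs_deviation for t in tables]
    if len(means) != len(counts) or len(means) < 3:
        raise ValidationError("need matching vectors of length >= 3")
    return float(np.corrcoef(means, counts)[0, 1])
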