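"""Community ordination: Bray-Curtis, NMDS, ANOSIM, Procrustes/PROTEST.

These are implemented from their definitions so every numerical choice is
explicit and testable:

* NMDS minimises Kruskal stress-1,
  ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)``, where the disparities
  ``dhat`` come from isotonic regression of configuration distances on the
  observed dissimilarities, via Guttman-transform (SMACOF) updates.  The
  first start is classical metric scaling of the dissimilarity matrix;
  the rest are random.  The returned configuration is the best over all
  starts and iterations, centred and rotated to principal axes.
* ANOSIM ranks all pairwise dissimilarities (average ranks on ties);
  ``R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)``,
  with a random-relabelling permutation p-value.
* Procrustes centres both configurations, scales each to unit total sum of
  squares and finds the orthogonal map (reflections allowed — ordination
  axes have arbitrary orientation) minimising the residual sum of squares
  m^2; the concordance statistic is ``sqrt(1 - m^2)``.  PROTEST permutes
  the row order of the second configuration.

Permutation p-values use the add-one convention, so p is never zero and
has resolution 1/(n_permutations + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .types import SurveyDataset, ValidationError


@dataclass
class AbundanceMatrix:
    """Samples x families relative abundances with per-sample labels."""

    data: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("relative abundances must be nonnegative")
        sums = self.data.sum(axis=1)
        bad = sums.index[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValidationError(f"rows do not sum to 1: {list(bad)[:3]}")
        if not self.data.index.equals(self.labels.index):
            raise ValidationError("data and labels must share an index")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: List[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValidationError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_restarts_used: int
    seed: Optional[int]
    converged: bool
    ids: List[str]


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


@dataclass
class ProcrustesResult:
    m2: float
    concordance: float
    p: Optional[float] = None
    n_permutations: Optional[int] = None


# ---------------------------------------------------------------------------

def relative_abundance_matrix(
    dataset: SurveyDataset, min_events: int = 0
) -> AbundanceMatrix:
    """Event-level relative abundance matrix from a survey's total counts."""
    rows, labels, ids = [], [], []
    fams = sorted(t.family_name for t in dataset.taxa)
    for ev in sorted(dataset.events, key=lambda e: e.key):
        counts = ev.total_counts
        total = sum(counts.values())
        if total <= 0:
            raise ValidationError(f"event {ev.key} has zero abundance")
        rows.append([counts.get(f, 0) / total for f in fams])
        labels.append({"stream": ev.stream, "season": ev.season, "year": ev.year})
        ids.append(f"{ev.stream}:{ev.year}:{ev.season}")
    data = pd.DataFrame(rows, index=ids, columns=fams)
    return AbundanceMatrix(data=data, labels=pd.DataFrame(labels, index=ids))


def counts_to_matrix(
    counts_by_sample: Dict[str, Dict[str, int]], labels: Optional[pd.DataFrame] = None
) -> AbundanceMatrix:
    """Relative abundance matrix from per-sample count dictionaries."""
    ids = sorted(counts_by_sample)
    fams = sorted({f for c in counts_by_sample.values() for f in c})
    rows = []
    for sid in ids:
        c = counts_by_sample[sid]
        total = sum(c.values())
        if total <= 0:
            raise ValidationError(f"sample {sid!r} has zero total count")
        rows.append([c.get(f, 0) / total for f in fams])
    data = pd.DataFrame(rows, index=ids, columns=fams)
    if labels is None:
        labels = pd.DataFrame(index=data.index)
    return AbundanceMatrix(data=data, labels=labels.loc[data.index])


def bray_curtis(matrix: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    X = matrix.data.values
    zero = np.where(X.sum(axis=1) == 0)[0]
    if len(zero):
        raise ValidationError(f"all-zero row for sample {matrix.sample_ids[zero[0]]!r}")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = d[i + 1 :, i] = num / den
    return DistanceMatrix(values=d, ids=matrix.sample_ids)


# ---------------------------------------------------------------------------
# NMDS

def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling: principal coordinates of the dissimilarity."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress_and_disparities(
    delta: np.ndarray, dist: np.ndarray, iso: IsotonicRegression
) -> Tuple[float, np.ndarray]:
    dhat = iso.fit(delta, dist).predict(delta)
    denom = float((dist**2).sum())
    if denom == 0:
        return float("inf"), dhat
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom)), dhat


def _principal_rotate(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt.T


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed=None,
) -> OrdinationResult:
    """Kruskal NMDS of a dissimilarity matrix into k dimensions.

    The best (lowest stress-1) configuration over all starts and all
    iterations is returned, so the result can never be worse than its
    metric-scaling initialisation.
    """
    n = d.n
    if n < 4:
        raise ValidationError("NMDS needs at least four samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delta = d.condensed
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best_stress, best_X, any_converged = np.inf, None, False
    starts = [_classical_scaling(d.values, k)]
    scale = max(delta.mean(), 1e-12)
    starts += [rng.normal(scale=scale, size=(n, k)) for _ in range(n_restarts - 1)]

    for X in starts:
        X = X.copy()
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            dist = pdist(X)
            stress, dhat = _stress_and_disparities(delta, dist, iso)
            if stress < best_stress:
                best_stress, best_X = stress, X.copy()
            if abs(prev - stress) < tol:
                converged = True
                break
            prev = stress
            # Guttman transform with the current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        any_converged = any_converged or converged

    return OrdinationResult(
        coordinates=_principal_rotate(best_X),
        stress=best_stress,
        n_restarts_used=len(starts),
        seed=None if isinstance(seed, np.random.Generator) else seed,
        converged=any_converged,
        ids=list(d.ids),
    )


def metric_scaling_stress(d: DistanceMatrix, k: int = 2) -> float:
    """Stress-1 of the classical-scaling configuration (the NMDS start)."""
    X = _classical_scaling(d.values, k)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    stress, _ = _stress_and_disparities(d.condensed, pdist(X), iso)
    return stress


def axis_variance(d: DistanceMatrix, ordination: OrdinationResult) -> np.ndarray:
    """Descriptive per-axis fractions of dissimilarity variance.

    The squared correlation between the original dissimilarities and the
    distances reconstructed from the first j principal-rotated axes,
    differenced over j.
    """
    delta = d.condensed
    k = ordination.coordinates.shape[1]
    cumulative = []
    for j in range(1, k + 1):
        dist_j = pdist(ordination.coordinates[:, :j])
        r = np.corrcoef(delta, dist_j)[0, 1]
        cumulative.append(r * r)
    return np.diff([0.0, *cumulative])


# ---------------------------------------------------------------------------
# ANOSIM

def _anosim_r(rank_matrix: np.ndarray, groups: np.ndarray) -> float:
    n = len(groups)
    within = groups[:, None] == groups[None, :]
    iu = np.triu_indices(n, 1)
    ranks = rank_matrix[iu]
    w = within[iu]
    return float((ranks[~w].mean() - ranks[w].mean()) / (n * (n - 1) / 4.0))


def anosim(
    d: DistanceMatrix,
    grouping: Sequence,
    n_permutations: int = 1000,
    seed=None,
    method: str = "random",
) -> AnosimResult:
    """Analysis of similarities with a relabelling permutation test.

    ``method="random"`` draws ``n_permutations`` random relabellings and
    uses the add-one p; ``method="exact"`` enumerates all n! label
    orderings (feasible for small n) and reports the exact tail fraction.
    """
    groups = np.asarray(grouping)
    if len(groups) != d.n:
        raise ValidationError("grouping length must match the distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        bad = labels[counts < 2][0]
        raise ValidationError(f"group {bad!r} has fewer than two members")
    rank_matrix = squareform(stats.rankdata(d.condensed), checks=False)
    r_obs = _anosim_r(rank_matrix, groups)
    if method == "exact":
        if d.n > 9:
            raise ValidationError("exact enumeration is limited to n <= 9")
        hits = total = 0
        for perm in itertools.permutations(range(d.n)):
            total += 1
            if _anosim_r(rank_matrix, groups[list(perm)]) >= r_obs - 1e-12:
                hits += 1
        return AnosimResult(R=r_obs, p=hits / total, n_permutations=total)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if _anosim_r(rank_matrix, perm) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Procrustes / PROTEST

def _normalize_configuration(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    ss = np.sqrt((Xc**2).sum())
    if ss == 0:
        raise ValidationError("zero-variance configuration")
    return Xc / ss


def _concordance(Xn: np.ndarray, Yn: np.ndarray) -> float:
    # trace of the singular-value matrix of X'Y = best-fit correlation;
    # reflections allowed, so no determinant sign correction.
    s = np.linalg.svd(Xn.T @ Yn, compute_uv=False)
    return float(np.clip(s.sum(), 0.0, 1.0))


def procrustes(X: np.ndarray, Y: np.ndarray) -> ProcrustesResult:
    """Symmetric orthogonal Procrustes residual m^2 and concordance.

    Both configurations are centred and scaled to unit total sum of
    squares; the minimised residual sum of squares is
    ``m^2 = 1 - (sum of singular values of X'Y)^2``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValidationError("configurations must have the same shape")
    c = _concordance(_normalize_configuration(X), _normalize_configuration(Y))
    return ProcrustesResult(m2=1.0 - c * c, concordance=c)


def protest(
    X: np.ndarray, Y: np.ndarray, n_permutations: int = 1000, seed=None,
    method: str = "random",
) -> ProcrustesResult:
    """Permutation significance of Procrustes concordance (rows of Y).

    ``method="exact"`` enumerates all n! row orders of Y (small n only).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    base = procrustes(X, Y)
    Xn, Yn = _normalize_configuration(X), _normalize_configuration(Y)
    if method == "exact":
        if X.shape[0] > 9:
            raise ValidationError("exact enumeration is limited to n <= 9")
        hits = total = 0
        for perm in itertools.permutations(range(Y.shape[0])):
            total += 1
            conc = _concordance(Xn, _normalize_configuration(Yn[list(perm)]))
            if conc >= base.concordance - 1e-12:
                hits += 1
        return ProcrustesResult(
            m2=base.m2, concordance=base.concordance, p=hits / total,
            n_permutations=total,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(Y.shape[0])
        if _concordance(Xn, _normalize_configuration(Yn[perm])) >= base.concordance - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return ProcrustesResult(
        m2=base.m2, concordance=base.concordance, p=p, n_permutations=n_permutations
    )
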