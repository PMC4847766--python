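"""Bray-Curtis, NMDS, ANOSIM and Procrustes/PROTEST behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from streamcits.ordination import (
    AbundanceMatrix,
    DistanceMatrix,
    anosim,
    axis_variance,
    bray_curtis,
    counts_to_matrix,
    metric_scaling_stress,
    nmds,
    procrustes,
    protest,
    relative_abundance_matrix,
)
from streamcits.types import ValidationError


def matrix_from_rows(rows):
    data = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
    return AbundanceMatrix(data=data, labels=pd.DataFrame(index=data.index))


def euclidean_dm(points):
    return DistanceMatrix(
        values=squareform(pdist(points)), ids=[f"s{i}" for i in range(len(points))]
    )


class TestBrayCurtis:
    def test_identical_rows_have_zero_distance(self):
        d = bray_curtis(matrix_from_rows([[0.5, 0.5], [0.5, 0.5]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        d = bray_curtis(matrix_from_rows([[1.0, 0.0], [0.0, 1.0]]))
        assert d.values[0, 1] == 1.0

    def test_worked_example(self):
        d = bray_curtis(matrix_from_rows([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        raw=st.lists(
            st.lists(st.integers(1, 50), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_symmetry_and_range_on_random_compositions(self, raw):
        rows = [np.array(r) / sum(r) for r in raw]
        d = bray_curtis(matrix_from_rows(rows)).values
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d), 0)


class TestNMDS:
    def test_embeddable_distances_reach_near_zero_stress(self, rng):
        points = rng.normal(size=(10, 2))
        res = nmds(euclidean_dm(points), n_restarts=4, seed=1)
        assert res.stress < 1e-3

    def test_never_worse_than_metric_scaling_start(self, rng):
        # a non-embeddable (random) dissimilarity structure
        raw = rng.uniform(0.1, 1.0, size=(8, 8))
        d = DistanceMatrix(
            values=np.triu(raw, 1) + np.triu(raw, 1).T, ids=[str(i) for i in range(8)]
        )
        res = nmds(d, n_restarts=3, seed=2)
        assert res.stress <= metric_scaling_stress(d) + 1e-12

    def test_stress_invariant_to_similarity_transforms_of_configuration(self, rng):
        """Stress is a function of configuration distances only, which are
        preserved up to scale by rotation+translation+scaling."""
        points = rng.normal(size=(8, 2))
        d = euclidean_dm(points)
        res = nmds(d, n_restarts=2, seed=3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        transformed = 2.5 * res.coordinates @ R + np.array([3.0, -1.0])
        # recompute stress-1 of the transformed configuration directly
        from sklearn.isotonic import IsotonicRegression

        for X in (res.coordinates, transformed):
            dist = pdist(X)
            iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
            dhat = iso.fit(d.condensed, dist).predict(d.condensed)
            stress = np.sqrt(((dist - dhat) ** 2).sum() / (dist**2).sum())
            assert stress == pytest.approx(res.stress, abs=1e-9)

    def test_distinct_simulated_assemblages_separate_on_axis_1(self, rng):
        counts = {}
        for i in range(6):
            counts[f"a{i}"] = {
                "Baetidae": int(60 + rng.integers(0, 15)),
                "Chironomidae": int(10 + rng.integers(0, 5)),
                "Heptageniidae": int(5 + rng.integers(0, 4)),
            }
            counts[f"b{i}"] = {
                "Baetidae": int(8 + rng.integers(0, 5)),
                "Chironomidae": int(50 + rng.integers(0, 15)),
                "Nemouridae": int(25 + rng.integers(0, 8)),
            }
        matrix = counts_to_matrix(counts)
        res = nmds(bray_curtis(matrix), n_restarts=8, seed=4)
        axis1 = {sid: res.coordinates[i, 0] for i, sid in enumerate(res.ids)}
        a = [axis1[k] for k in axis1 if k.startswith("a")]
        b = [axis1[k] for k in axis1 if k.startswith("b")]
        assert max(a) < min(b) or max(b) < min(a)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            nmds(euclidean_dm(np.zeros((3, 2))))


class TestAxisVariance:
    def test_one_dimensional_data_loads_axis_1(self, rng):
        x = np.sort(rng.uniform(size=12))
        points = np.column_stack([x, np.zeros_like(x)])
        d = euclidean_dm(points)
        res = nmds(d, n_restarts=2, seed=5)
        fractions = axis_variance(d, res)
        assert fractions[0] > 0.99
        assert fractions.sum() <= 1 + 1e-9

    def test_fractions_nonincreasing_after_principal_rotation(self, rng):
        points = rng.normal(size=(10, 2)) * np.array([3.0, 1.0])
        d = euclidean_dm(points)
        res = nmds(d, n_restarts=2, seed=6)
        fractions = axis_variance(d, res)
        assert fractions[0] >= fractions[1]


class TestAnosim:
    def test_all_distances_equal_gives_r_zero(self):
        d = DistanceMatrix(
            values=np.ones((6, 6)) - np.eye(6), ids=[str(i) for i in range(6)]
        )
        res = anosim(d, ["a", "a", "a", "b", "b", "b"], 99, seed=1)
        assert res.R == pytest.approx(0.0)

    def test_complete_separation_gives_r_one(self, rng):
        a = rng.normal(0, 0.1, size=(4, 2))
        b = rng.normal(10, 0.1, size=(4, 2))
        d = euclidean_dm(np.vstack([a, b]))
        res = anosim(d, ["a"] * 4 + ["b"] * 4, 99, seed=2)
        assert res.R == pytest.approx(1.0)

    def test_singleton_group_rejected(self, rng):
        d = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValidationError):
            anosim(d, ["a", "a", "a", "a", "b"], 99)

    def test_exact_p_matches_independent_enumeration(self, rng):
        """n = 6 (3+3): exact mode agrees with a from-scratch enumeration of
        all 20 distinct labelings."""
        points = rng.normal(size=(6, 2))
        d = euclidean_dm(points)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = anosim(d, groups, method="exact")

        # oracle: recompute R for every choice of which 3 samples are "a"
        ranks = squareform(rankdata(d.condensed), checks=False)
        iu = np.triu_indices(6, 1)

        def r_of(assign):
            w = np.array([[assign[i] == assign[j] for j in range(6)] for i in range(6)])
            rv = ranks[iu]
            wv = w[iu]
            return (rv[~wv].mean() - rv[wv].mean()) / (6 * 5 / 4)

        r_obs = r_of(groups)
        rs = []
        for combo in itertools.combinations(range(6), 3):
            assign = np.array(["b"] * 6)
            assign[list(combo)] = "a"
            rs.append(r_of(assign))
        expected_p = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert res.R == pytest.approx(r_obs)
        assert res.p == pytest.approx(expected_p)

    def test_r_invariant_under_monotone_distance_transform(self, rng):
        points = rng.normal(size=(8, 2))
        d = euclidean_dm(points)
        groups = ["a"] * 4 + ["b"] * 4
        r1 = anosim(d, groups, 9, seed=3).R
        d2 = DistanceMatrix(values=np.sqrt(d.values), ids=d.ids)
        r2 = anosim(d2, groups, 9, seed=3).R
        assert r1 == pytest.approx(r2)

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check of the R statistic against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        points = rng.normal(size=(8, 2))
        d = euclidean_dm(points)
        groups = ["a"] * 4 + ["b"] * 4
        ours = anosim(d, groups, 99, seed=4)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d.values, d.ids), grouping=list(groups),
            permutations=0,
        )
        assert ours.R == pytest.approx(float(ref["test statistic"]))


class TestProcrustes:
    def test_identity_gives_zero_residual(self, rng):
        X = rng.normal(size=(6, 2))
        res = procrustes(X, X)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.concordance == pytest.approx(1.0)

    def test_similarity_transform_gives_zero_residual(self, rng):
        X = rng.normal(size=(7, 2))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = 3.0 * X @ R + np.array([5.0, -2.0])
        assert procrustes(X, Y).m2 == pytest.approx(0.0, abs=1e-12)

    def test_reflection_allowed(self, rng):
        X = rng.normal(size=(6, 2))
        Y = X @ np.diag([1.0, -1.0])
        assert procrustes(X, Y).m2 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValidationError):
            procrustes(np.zeros((5, 2)), np.ones((5, 2)))

    def test_matches_scipy_disparity(self, rng):
        """scipy.spatial.procrustes reports the same residual disparity."""
        from scipy.spatial import procrustes as scipy_procrustes

        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        assert procrustes(X, Y).m2 == pytest.approx(disparity, rel=1e-9)


class TestProtest:
    def test_self_comparison_p_is_minimal(self, rng):
        X = rng.normal(size=(12, 2))
        res = protest(X, X, n_permutations=99, seed=1)
        assert res.p == pytest.approx(1 / 100)

    def test_exact_p_matches_independent_enumeration(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        X, Y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        res = protest(X, Y, method="exact")
        base = 1.0 - scipy_procrustes(X, Y)[2]
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            total += 1
            conc = np.sqrt(1.0 - scipy_procrustes(X, Y[list(perm)])[2])
            if conc >= np.sqrt(base) - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / total)

    def test_null_p_roughly_uniform(self, rng):
        """Independent random configurations: p is not concentrated near 0."""
        ps = []
        for _ in range(60):
            X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
            ps.append(protest(X, Y, n_permutations=59, seed=rng).p)
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.2).mean() < 0.5

    def test_paired_field_lab_ordinations_concordant(self, community, reach, rng):
        """Field and lab views of the same latent communities give highly
        concordant ordinations with a small PROTEST p."""
        from streamcits.synthetic import simulate_paired_sample

        field, lab = {}, {}
        # two contrasting latent communities to give the ordination structure
        from streamcits.synthetic import CommunitySpec

        rel2 = dict(community.true_relative_abundance)
        # swap dominance to build a second assemblage
        rel2["Baetidae"], rel2["Chironomidae"] = rel2["Chironomidae"], rel2["Baetidae"]
        rel2["Heptageniidae"], rel2["Nemouridae"] = (
            rel2["Nemouridae"],
            rel2["Heptageniidae"],
        )
        comm2 = CommunitySpec(taxa=community.taxa, true_relative_abundance=rel2)
        for i in range(6):
            s = simulate_paired_sample(community, reach, rng, f"A{i}")
            field[f"A{i}"], lab[f"A{i}"] = s.field_counts, s.lab_counts
            s2 = simulate_paired_sample(comm2, reach, rng, f"B{i}")
            field[f"B{i}"], lab[f"B{i}"] = s2.field_counts, s2.lab_counts
        mf, ml = counts_to_matrix(field), counts_to_matrix(lab)
        ml = AbundanceMatrix(
            data=ml.data.reindex(columns=mf.data.columns, fill_value=0.0),
            labels=ml.labels,
        )
        of = nmds(bray_curtis(mf), n_restarts=6, seed=1)
        ol = nmds(bray_curtis(ml), n_restarts=6, seed=2)
        res = protest(of.coordinates, ol.coordinates, n_permutations=199, seed=3)
        # abundance (not compositional) patchiness is simulated, so the
        # shared field/lab signal is weaker than real paired samples show;
        # concordance is still well above the permutation null
        assert res.concordance > 0.5
        assert res.p < 0.05


class TestRelativeAbundanceMatrix:
    def test_rows_sum_to_one(self, tiny_dataset):
        m = relative_abundance_matrix(tiny_dataset)
        assert np.allclose(m.data.sum(axis=1), 1.0)
        assert list(m.labels.columns) == ["stream", "season", "year"]
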