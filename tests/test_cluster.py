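"""Ward linkage, Jaccard/ARI, screening, and pattern extraction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from plasmapattern import (
    CohortTable,
    EffectSpec,
    Partition,
    PresenceMatrix,
    SimConfig,
    adjusted_rand_index,
    compare_cluster_bmi,
    cut_tree,
    default_group_specs,
    euclidean_distance_matrix,
    extract_discriminative_pattern,
    high_bmi_cluster,
    jaccard_distance,
    jaccard_distance_matrix,
    pca_scores,
    screen_parameters,
    simulate_cohort,
    simulate_proteome,
    ward_linkage,
    zscore_normalize,
)
from plasmapattern.errors import DataError
from tests.conftest import make_sample


class TestZscore:
    def test_simple_column(self):
        z = zscore_normalize(np.array([[1.0], [2.0], [3.0]]))
        assert z.ravel() == pytest.approx([-1.0, 0.0, 1.0])

    def test_hand_computed_column(self):
        z = zscore_normalize(np.array([[10.0], [20.0], [40.0], [50.0]]))
        sd = np.std([10, 20, 40, 50], ddof=1)  # ~18.257
        assert z.ravel() == pytest.approx((np.array([10, 20, 40, 50]) - 30) / sd)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 4))
        z = zscore_normalize(x)
        assert np.allclose(zscore_normalize(z), z, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_normalize(x)
        assert z.shape == (3, 1)

    def test_all_constant_is_error(self):
        with pytest.raises(DataError):
            zscore_normalize(np.ones((3, 2)))


class TestJaccard:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 0, 1), (1, 0, 1), 0.0),
            ((1, 1, 0, 0), (0, 0, 1, 1), 1.0),
            ((1, 1, 0, 0), (1, 0, 1, 0), 2 / 3),
            ((0, 0), (0, 0), 0.0),  # both-empty convention
        ],
    )
    def test_examples(self, x, y, expected):
        assert jaccard_distance(x, y) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            jaccard_distance([1, 0], [1, 0, 1])

    @given(st.lists(st.tuples(*[st.integers(0, 1)] * 8), min_size=3, max_size=3))
    @settings(max_examples=300, deadline=None)
    def test_metric_axioms(self, vecs):
        x, y, z = vecs
        dxy, dxz, dzy = (
            jaccard_distance(x, y),
            jaccard_distance(x, z),
            jaccard_distance(z, y),
        )
        assert dxy == pytest.approx(jaccard_distance(y, x))
        assert 0.0 <= dxy <= 1.0
        if x == y:
            assert dxy == 0.0
        assert dxy <= dxz + dzy + 1e-12  # triangle inequality

    def test_matrix_form_matches_pairwise(self):
        rng = np.random.default_rng(1)
        m = PresenceMatrix(
            [f"s{i}" for i in range(6)],
            [f"P{j:05d}" for j in range(10)],
            rng.integers(0, 2, size=(6, 10)).astype(np.int8),
        )
        D = jaccard_distance_matrix(m)
        for i, j in itertools.combinations(range(6), 2):
            assert D.d[i, j] == pytest.approx(
                jaccard_distance(m.values[i], m.values[j])
            )


def _ward_sse_oracle(points: np.ndarray):
    """Brute-force minimum-variance agglomeration on raw coordinates.

    At each step merge the pair of clusters whose union increases the total
    within-cluster sum of squares the least; report sqrt(2 * increase) as
    the merge height (the distance-scale Ward convention).
    """
    def sse(idx):
        pts = points[list(idx)]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    clusters = {i: (i,) for i in range(len(points))}
    merges = []
    nxt = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            cost = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        cost, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[nxt] = merged
        merges.append((a, b, np.sqrt(2 * cost), len(merged)))
        nxt += 1
    return np.array(merges)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        d = euclidean_distance_matrix(np.array([[0.0], [3.0]]), ["a", "b"])
        dend = ward_linkage(d)
        assert dend.merges[0].tolist() == [0, 1, 3.0, 2]

    def test_one_dimensional_example(self):
        pts = np.array([[0.0], [1.0], [4.0], [5.0]])
        dend = ward_linkage(euclidean_distance_matrix(pts, list("abcd")))
        first_two = {frozenset(dend.merges[0][:2].astype(int)),
                     frozenset(dend.merges[1][:2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert dend.merges[2][:2].tolist() == [4, 5]  # pairs merge last

    def test_equals_sse_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            pts = rng.normal(size=(n, 2))
            dend = ward_linkage(
                euclidean_distance_matrix(pts, [str(i) for i in range(n)])
            )
            oracle = _ward_sse_oracle(pts)
            assert np.array_equal(dend.merges[:, :2], oracle[:, :2])
            assert np.allclose(dend.merges[:, 2], oracle[:, 2], atol=1e-8)

    def test_heights_nondecreasing_on_jaccard_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = PresenceMatrix(
                [f"s{i}" for i in range(12)],
                [f"P{j:05d}" for j in range(15)],
                rng.integers(0, 2, size=(12, 15)).astype(np.int8),
            )
            for dialect in ("D2", "D"):
                dend = ward_linkage(jaccard_distance_matrix(m), dialect=dialect)
                assert np.all(np.diff(dend.heights) >= -1e-10)

    def test_single_point_is_error(self):
        with pytest.raises(DataError):
            ward_linkage(euclidean_distance_matrix(np.array([[0.0]]), ["a"]))


class TestCutTree:
    @pytest.fixture
    def dend(self):
        pts = np.array([[0.0], [1.0], [4.0], [5.0]])
        return ward_linkage(euclidean_distance_matrix(pts, list("abcd")))

    def test_k1_single_cluster(self, dend):
        assert cut_tree(dend, 1).k == 1

    def test_kn_singletons(self, dend):
        part = cut_tree(dend, 4)
        assert part.k == 4

    def test_k2_recovers_pairs(self, dend):
        part = cut_tree(dend, 2)
        assert part.labels.tolist() == [1, 1, 2, 2]

    def test_out_of_range(self, dend):
        with pytest.raises(DataError):
            cut_tree(dend, 0)
        with pytest.raises(DataError):
            cut_tree(dend, 5)


class TestAdjustedRandIndex:
    ids = list("abcd")

    def test_worked_examples(self):
        p = Partition(self.ids, [1, 1, 2, 2])
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)
        assert adjusted_rand_index(
            p, Partition(self.ids, [1, 1, 1, 2])
        ) == pytest.approx(0.0)
        assert adjusted_rand_index(
            p, Partition(self.ids, [1, 2, 1, 2])
        ) == pytest.approx(-0.5)

    def test_relabeling_invariance_and_sklearn_agreement(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(30)]
        for _ in range(20):
            a = rng.integers(1, 5, size=30)
            b = rng.integers(1, 4, size=30)
            ari = adjusted_rand_index(Partition(ids, a), Partition(ids, b))
            assert ari == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)
            relabeled = np.array([5 - x for x in a])  # bijective relabel
            assert ari == pytest.approx(
                adjusted_rand_index(Partition(ids, relabeled), Partition(ids, b))
            )

    def test_mean_over_random_shuffles_near_zero(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(40)]
        a = Partition(ids, rng.integers(1, 5, size=40))
        b = rng.integers(1, 5, size=40)
        vals = [
            adjusted_rand_index(a, Partition(ids, rng.permutation(b)))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_id_mismatch_is_error(self):
        with pytest.raises(DataError):
            adjusted_rand_index(
                Partition(["a", "b"], [1, 2]), Partition(["a", "c"], [1, 2])
            )


class TestScreenParameters:
    # six subjects per BMI group so the rank test has room to reject
    BMIS = [g + 0.5 * k for g in (19.0, 25.5, 30.5, 35.5, 40.5) for k in range(6)]

    @classmethod
    def _cohort(cls, param_values, bmis=None):
        bmis = bmis if bmis is not None else cls.BMIS
        return CohortTable(
            [
                make_sample(f"s{i}", float(b), param=float(v))
                for i, (b, v) in enumerate(zip(bmis, param_values))
            ]
        )

    def test_identical_parameter_not_selected(self):
        cohort = self._cohort([5.0] * 30)
        res = screen_parameters(cohort)
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(1.0)
        assert not res[0].selected

    def test_bmi_linked_parameter_strongly_selected(self):
        cohort = self._cohort(self.BMIS)  # param == BMI itself
        res = screen_parameters(cohort)
        assert res[0].selected and res[0].p_value < 1e-3

    def test_null_parameter_type_i_error_controlled(self):
        """A parameter independent of group should be selected about 5% of
        the time at alpha = 0.05."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            cohort = self._cohort(rng.normal(size=30))
            hits += screen_parameters(cohort)[0].selected
        assert 1 <= hits <= 25  # binomial(200, .05): ~3 SE envelope

    def test_mostly_missing_parameter_excluded(self):
        samples = [make_sample(f"s{i}", 20.0 + i, param=float("nan")) for i in range(8)]
        samples[0].clinical["param"] = 1.0
        cohort = CohortTable(samples)
        with pytest.warns(UserWarning, match="excluded"):
            assert screen_parameters(cohort) == []


class TestCompareClusterBmi:
    @staticmethod
    def _cohort(bmis):
        return CohortTable([make_sample(f"s{i}", float(b)) for i, b in enumerate(bmis)])

    def test_exact_small_sample_p_value(self):
        cohort = self._cohort([40, 42, 20, 22])
        part = Partition(cohort.sample_ids, [1, 1, 2, 2])
        mean_in, mean_out, p = compare_cluster_bmi(part, cohort, 1)
        assert (mean_in, mean_out) == (41.0, 21.0)
        # complete separation at n=(2,2): the smallest attainable two-sided p
        expected = mannwhitneyu([40, 42], [20, 22], alternative="two-sided",
                                method="exact")[1]
        assert p == pytest.approx(expected) == pytest.approx(1 / 3)

    def test_swapping_cluster_and_complement(self):
        cohort = self._cohort([40, 42, 20, 22])
        part = Partition(cohort.sample_ids, [1, 1, 2, 2])
        in1, out1, p1 = compare_cluster_bmi(part, cohort, 1)
        in2, out2, p2 = compare_cluster_bmi(part, cohort, 2)
        assert (in1, out1) == (out2, in2)
        assert p1 == pytest.approx(p2)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(7)
        bmis = np.linspace(19, 50, 40)
        rejections = 0
        for _ in range(200):
            labels = rng.permutation([1] * 20 + [2] * 20)
            cohort = self._cohort(bmis)
            part = Partition(cohort.sample_ids, labels)
            _, _, p = compare_cluster_bmi(part, cohort, 1)
            rejections += p < 0.05
        assert rejections <= 20  # ~10 expected at the 5% level

    def test_degenerate_cluster_is_error(self):
        cohort = self._cohort([20, 30])
        part = Partition(cohort.sample_ids, [1, 1])
        with pytest.raises(DataError):
            compare_cluster_bmi(part, cohort, 1)


class TestPatternExtraction:
    @staticmethod
    def _matrix(values, ids=None):
        values = np.asarray(values, dtype=np.int8)
        return PresenceMatrix(
            [f"s{i}" for i in range(values.shape[0])],
            ids or [f"P{j:05d}" for j in range(values.shape[1])],
            values,
        )

    def test_perfect_separator_ranks_first(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 2, size=(20, 6))
        vals[:, 0] = [1] * 10 + [0] * 10  # perfect marker of cluster 1
        m = self._matrix(vals)
        part = Partition(m.sample_ids, [1] * 10 + [2] * 10)
        res = extract_discriminative_pattern(m, part, 1, alpha=0.05)
        assert res.pattern and res.pattern[0] == "P00000"

    def test_equal_prevalence_excluded(self):
        col = [1, 1, 0, 0, 0, 1, 1, 0, 0, 0]  # 40% inside and outside
        m = self._matrix(np.array(col).reshape(-1, 1))
        part = Partition(m.sample_ids, [1] * 5 + [2] * 5)
        res = extract_discriminative_pattern(m, part, 1, alpha=0.05)
        assert res.pattern == []

    def test_alpha_zero_empty_and_monotone_nested(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 2, size=(30, 12))
        vals[:15, :3] = 1
        vals[15:, :3] = 0
        m = self._matrix(vals)
        part = Partition(m.sample_ids, [1] * 15 + [2] * 15)
        assert extract_discriminative_pattern(m, part, 1, alpha=0.0).pattern == []
        prev: set[str] = set()
        for alpha in (0.001, 0.01, 0.05, 0.2, 1.0):
            cur = set(extract_discriminative_pattern(m, part, 1, alpha=alpha).pattern)
            assert prev <= cur
            prev = cur

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(10)
        m = self._matrix(rng.integers(0, 2, size=(16, 8)))
        part = Partition(m.sample_ids, [1] * 8 + [2] * 8)
        t = extract_discriminative_pattern(m, part, 1, alpha=0.05).table
        assert (t["p_adjusted"] >= t["p_value"] - 1e-12).all()

    def test_planted_pattern_recovery(self):
        """Ward/Jaccard clustering at k=2 followed by Fisher/BH extraction
        should recover most of a strongly planted 15-protein panel."""
        effects = [EffectSpec(f"P{k + 1:05d}", 0.0, 3.0) for k in range(15)]
        cfg = SimConfig(groups=default_group_specs(), effects=effects,
                        n_noise_proteins=85, n_ubiquitous=0, n_singletonish=0)
        hits = 0
        for s in range(100):
            cohort = simulate_cohort(cfg, seed=3000 + s)
            m, truth = simulate_proteome(cohort, cfg, seed=3000 + s)
            from plasmapattern import filter_proteins

            f = filter_proteins(m)
            dend = ward_linkage(jaccard_distance_matrix(f))
            part = cut_tree(dend, 2)
            target = high_bmi_cluster(part, cohort)
            res = extract_discriminative_pattern(f, part, target, alpha=0.05)
            if len(set(res.pattern) & truth) >= 10:
                hits += 1
        assert hits >= 80


class TestPca:
    def test_collinear_data_single_component(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        with pytest.warns(UserWarning, match="rank"):
            _, frac = pca_scores(x, n_components=2)
        assert frac[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(10_000, 2))
        _, frac = pca_scores(x, n_components=2)
        assert frac == pytest.approx([0.5, 0.5], abs=0.03)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(50, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        _, f1 = pca_scores(x, 4)
        _, f2 = pca_scores(x @ q, 4)
        assert f1 == pytest.approx(f2, abs=1e-9)
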