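import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chemprofile import (
    DistanceMatrix,
    balanced_exclusion,
    gower_center,
    iterated_permanova,
    permanova_sequential,
    pool_permutation_pvalues,
)

# ---------------------------------------------------------------------------
# brute-force oracle: single-factor PERMANOVA from within/between distance sums
# ---------------------------------------------------------------------------

def oracle_single_factor(d: np.ndarray, labels: np.ndarray):
    """F and exhaustive-permutation P from group-wise distance sums alone."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = (d[iu] ** 2).sum() / n

    def stats(lab):
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.where(lab == g)[0]
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), k=1)] ** 2).sum() / len(idx)
        a = len(np.unique(lab))
        ss_between = ss_total - ss_within
        return ss_between, (ss_between / (a - 1)) / (ss_within / (n - a))

    ss_obs, f_obs = stats(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        _, f = stats(labels[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return ss_obs, f_obs, count / total


def _meta_from_labels(labels):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(labels))],
            "sex": ["female" if l == 0 else "male" for l in labels],
            "pair_id": [None] * len(labels),
            "days_after_laying": np.arange(len(labels), dtype=float),
            "is_blank": [False] * len(labels),
        }
    )


def _random_distance(rng, n):
    X = rng.gamma(1.0, 1.0, size=(n, 4))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X, metric="braycurtis"))


class TestGowerCenter:
    def test_zero_distances_give_zero(self):
        np.testing.assert_allclose(gower_center(np.zeros((4, 4))), 0.0)

    def test_one_dimensional_points(self):
        d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        G = gower_center(d)
        vals = np.sort(np.linalg.eigvalsh(G))[::-1]
        np.testing.assert_allclose(vals, [2.0, 0.0, 0.0], atol=1e-12)

    def test_trace_identity_and_centering(self):
        rng = np.random.default_rng(5)
        d = _random_distance(rng, 8)
        G = gower_center(d)
        iu = np.triu_indices(8, k=1)
        assert np.trace(G) == pytest.approx((d[iu] ** 2).sum() / 8, abs=1e-10)
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(G, G.T)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            gower_center(np.array([[0, 1.0], [2.0, 0]]))


class TestPermanovaSequential:
    def test_two_plus_two_worked_example(self):
        d = np.array([[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0.0]])
        meta = _meta_from_labels([0, 0, 1, 1])
        res = permanova_sequential(d, meta, terms=("sex",), n_perm=9999, seed=0)
        assert res.ss_total == pytest.approx(4.5, abs=1e-12)
        assert res.ss[0] == pytest.approx(3.5, abs=1e-12)
        assert res.f[0] == pytest.approx(7.0, abs=1e-12)
        assert res.exhaustive  # 4! = 24 <= 9999
        assert res.p[0] == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (7, 3)])
    def test_matches_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        d = _random_distance(rng, n)
        labels = rng.integers(0, 2, size=n)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=n)
        ss_o, f_o, p_o = oracle_single_factor(d, labels)
        res = permanova_sequential(d, _meta_from_labels(labels), ("sex",), math.factorial(n), 0)
        assert res.ss[0] == pytest.approx(ss_o, abs=1e-9)
        assert res.f[0] == pytest.approx(f_o, abs=1e-9)
        assert res.exhaustive
        assert res.p[0] == pytest.approx(p_o, abs=1e-12)

    def test_decomposition_exact_for_every_permutation(self):
        rng = np.random.default_rng(11)
        d = _random_distance(rng, 9)
        meta = _meta_from_labels(rng.integers(0, 2, size=9))
        for _ in range(20):
            perm = rng.permutation(9)
            res = permanova_sequential(d[np.ix_(perm, perm)], meta, n_perm=9, seed=1)
            assert res.ss.sum() + res.ss_residual == pytest.approx(res.ss_total, abs=1e-9)
            assert res.r2.sum() + res.ss_residual / res.ss_total == pytest.approx(1.0, abs=1e-9)

    def test_three_term_sequential_r2_sums_to_one(self, default_dataset):
        from chemprofile import align_peaks, bray_curtis, filter_substances, log_transform, normalize_relative

        ds = default_dataset
        mat = log_transform(
            normalize_relative(filter_substances(align_peaks(ds.peak_lists), ds.metadata))
        )
        D = bray_curtis(mat)
        biol = ds.metadata[~ds.metadata["is_blank"]]
        res = permanova_sequential(D, biol, n_perm=99, seed=1)
        assert res.terms == ["sex", "days_after_laying", "sex:days_after_laying"]
        assert res.df.tolist() == [1, 1, 1]
        assert res.ss.sum() + res.ss_residual == pytest.approx(res.ss_total, abs=1e-9)
        assert all(1 / 100 <= p <= 1 for p in res.p)

    def test_constant_factor_errors(self):
        d = _random_distance(np.random.default_rng(0), 6)
        meta = _meta_from_labels([1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="aliased"):
            permanova_sequential(d, meta, terms=("sex",), n_perm=9, seed=0)

    def test_reproducible_from_seed(self):
        d = _random_distance(np.random.default_rng(3), 10)
        meta = _meta_from_labels(np.random.default_rng(4).integers(0, 2, size=10))
        r1 = permanova_sequential(d, meta, ("sex",), n_perm=199, seed=42)
        r2 = permanova_sequential(d, meta, ("sex",), n_perm=199, seed=42)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_agrees_with_skbio_single_factor(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        d = _random_distance(rng, 12)
        labels = rng.integers(0, 2, size=12)
        ids = [f"s{i}" for i in range(12)]
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d, ids),
            grouping=[str(l) for l in labels],
            permutations=0,
        )
        res = permanova_sequential(d, _meta_from_labels(labels), ("sex",), n_perm=9, seed=0)
        assert res.f[0] == pytest.approx(ref["test statistic"], abs=1e-9)


class TestBalancedExclusion:
    def test_study_composition_retains_seven_females_nine_males(self, paired_metadata):
        retained = balanced_exclusion(paired_metadata, seed=0)
        meta = paired_metadata.set_index("sample_id").loc[retained]
        assert len(retained) == 16
        assert (meta["sex"] == "female").sum() == 7
        assert (meta["sex"] == "male").sum() == 9
        # exactly one member retained per complete pair
        assert meta["pair_id"].dropna().is_unique

    def test_all_six_admissible_patterns_reachable(self, paired_metadata):
        # C(4,2) = 6 ways of choosing which two pairs drop the female
        seen = set()
        for seed in range(200):
            retained = balanced_exclusion(paired_metadata, seed=seed)
            dropped = tuple(sorted(set(paired_metadata["sample_id"]) - set(retained)))
            seen.add(dropped)
        assert len(seen) == 6
        for dropped in seen:
            sexes = paired_metadata.set_index("sample_id").loc[list(dropped), "sex"]
            assert (sexes == "female").sum() == 2 and (sexes == "male").sum() == 2

    def test_no_pairs_is_identity(self, paired_metadata):
        meta = paired_metadata.assign(pair_id=None)
        assert balanced_exclusion(meta, seed=3) == list(meta["sample_id"])

    def test_same_sex_pairs_infeasible(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e", "f"],
                "sex": ["female"] * 4 + ["male"] * 2,
                "pair_id": ["P1", "P1", "P2", "P2", None, None],
                "days_after_laying": [1, 2, 3, 4, 5, 6],
                "is_blank": [False] * 6,
            }
        )
        with pytest.raises(ValueError, match="infeasible"):
            balanced_exclusion(meta, seed=0)


class TestPooledPvalue:
    def test_boundary_identities(self):
        # no permuted F ever reaches observed -> P = 1/(1+N_perm)
        counts = np.zeros((1000, 3), dtype=int)
        np.testing.assert_allclose(pool_permutation_pvalues(counts, 9999), 1e-4)
        # every permuted F >= observed -> P = 1
        np.testing.assert_allclose(pool_permutation_pvalues(counts + 9999, 9999), 1.0)

    def test_single_iteration_reduction(self):
        assert pool_permutation_pvalues([[41]], 199)[0] == pytest.approx(42 / 200)


@pytest.fixture(scope="module")
def logged_matrix(default_dataset):
    from chemprofile import align_peaks, filter_substances, log_transform, normalize_relative

    ds = default_dataset
    return log_transform(
        normalize_relative(filter_substances(align_peaks(ds.peak_lists), ds.metadata))
    )


class TestIteratedPermanova:
    def test_summary_shape_and_bounds(self, logged_matrix, default_dataset):
        res = iterated_permanova(
            logged_matrix, default_dataset.metadata, n_iterations=30, n_perm=99, seed=5
        )
        assert res.summary.shape[0] == 3
        for t in range(3):
            lo = 1 / (1 + res.n_perm)
            assert lo <= res.pooled_p[t] <= 1.0
            assert res.summary["F_q1"][t] <= res.summary["F_median"][t] <= res.summary["F_q3"][t]
            assert res.iteration_f[:, t].min() <= res.summary["F_median"][t] <= res.iteration_f[:, t].max()

    def test_bit_reproducible_from_seed(self, logged_matrix, default_dataset):
        a = iterated_permanova(logged_matrix, default_dataset.metadata, n_iterations=10, n_perm=49, seed=9)
        b = iterated_permanova(logged_matrix, default_dataset.metadata, n_iterations=10, n_perm=49, seed=9)
        np.testing.assert_array_equal(a.pooled_p, b.pooled_p)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_no_pairs_makes_iterations_identical_subsets(self, logged_matrix, default_dataset):
        meta = default_dataset.metadata.copy()
        meta["pair_id"] = None
        res = iterated_permanova(logged_matrix, meta, n_iterations=4, n_perm=49, seed=2)
        # observed statistics cannot vary when every iteration keeps all samples
        assert np.ptp(res.iteration_f, axis=0).max() == 0.0

    def test_pooled_matches_formula_from_counts(self, logged_matrix, default_dataset):
        res = iterated_permanova(
            logged_matrix, default_dataset.metadata, n_iterations=5, n_perm=99, seed=31
        )
        # recompute each iteration independently from its spawned stream
        streams = np.random.SeedSequence(31).spawn(5)
        biol = default_dataset.metadata[~default_dataset.metadata["is_blank"]]
        from chemprofile import bray_curtis

        D = bray_curtis(logged_matrix)
        counts = []
        for stream in streams:
            rng = np.random.default_rng(stream)
            retained = balanced_exclusion(biol, rng)
            sub = biol.set_index("sample_id").loc[retained].reset_index()
            r = permanova_sequential(D.subset(retained), sub, n_perm=99, seed=rng)
            counts.append(r.exceed_counts)
        np.testing.assert_allclose(
            res.pooled_p, pool_permutation_pvalues(np.array(counts), 99)
        )
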