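import itertools

import numpy as np
import pytest

from gaitclust.clustering import ClusterEnsemble, KMeansResult, SilhouetteResult
from gaitclust.selection import (
    AlignedEnsemble,
    align_labels,
    boundary_analysis,
    median_allocation,
    repeatability,
    select_k,
)


def make_ensemble(labels_by_k, s_by_k=None):
    """Build a ClusterEnsemble from prescribed R x n label matrices."""
    k_range = tuple(sorted(labels_by_k))
    R = next(iter(labels_by_k.values())).shape[0]
    ens = ClusterEnsemble(k_range=k_range, n_repetitions=R,
                          rng_seeds=list(range(R)))
    for k, labmat in labels_by_k.items():
        labmat = np.asarray(labmat)
        n = labmat.shape[1]
        smat = (np.asarray(s_by_k[k]) if s_by_k and k in s_by_k
                else np.full((R, n), 0.5))
        for r in range(R):
            ens.results[(r, k)] = KMeansResult(
                k=k, labels=labmat[r], centroids=np.zeros((k, 2)),
                sse=1.0, n_iter=1)
            ens.silhouettes[(r, k)] = SilhouetteResult(
                smat[r], np.zeros(n), np.zeros(n))
    return ens


def paper_style_k4(n=37, R=10):
    """Truth labels (5,12,12,8) with exactly 12 switched records:
    two participants switch once, three twice, one four times."""
    base = np.array([1] * 5 + [2] * 12 + [3] * 12 + [4] * 8)
    labels = np.tile(base, (R, 1))
    switch_plan = {0: 4, 5: 2, 6: 2, 17: 2, 29: 1, 30: 1}
    rep = 0
    for participant, count in switch_plan.items():
        for _ in range(count):
            labels[rep % R, participant] = base[participant] % 4 + 1
            rep += 1
    return labels


class TestAlignment:
    def test_permuted_identical_partitions_align(self):
        base = np.array([1, 1, 2, 2, 3, 3])
        permuted = np.array([2, 2, 3, 3, 1, 1])
        ens = make_ensemble({3: np.vstack([base, permuted])})
        aligned = align_labels(ens, 3)
        np.testing.assert_array_equal(aligned.labels[1], base)

    def test_single_mismatch_survives_alignment(self):
        base = np.array([1, 1, 1, 2, 2, 2])
        other = np.array([2, 2, 2, 1, 1, 2])  # permuted names + 1 disagreement
        ens = make_ensemble({2: np.vstack([base, other])})
        aligned = align_labels(ens, 2)
        assert int((aligned.labels[1] != base).sum()) == 1

    def test_matches_exhaustive_permutation_search(self, rng):
        """Optimal-assignment alignment equals brute force over all k!
        relabellings on random partitions."""
        k, n = 4, 37
        for _ in range(10):
            ref = rng.integers(1, k + 1, size=n)
            other = rng.integers(1, k + 1, size=n)
            ens = make_ensemble({k: np.vstack([ref, other])})
            aligned = align_labels(ens, k)
            best = max(
                (sum((np.array([perm[l - 1] for l in other]) == ref))
                 for perm in itertools.permutations(range(1, k + 1))),
            )
            assert int((aligned.labels[1] == ref).sum()) == best

    def test_alignment_preserves_partition(self, rng):
        k, n = 3, 20
        ref = rng.integers(1, k + 1, size=n)
        other = rng.integers(1, k + 1, size=n)
        ens = make_ensemble({k: np.vstack([ref, other])})
        aligned = align_labels(ens, k)
        # same partition: co-membership matrices identical
        before = other[:, None] == other[None, :]
        after = aligned.labels[1][:, None] == aligned.labels[1][None, :]
        np.testing.assert_array_equal(before, after)


class TestRepeatability:
    def test_identical_repetitions_are_fully_repeatable(self):
        labels = np.tile(np.array([1, 1, 2, 2, 3, 3]), (10, 1))
        ens = make_ensemble({3: labels})
        pct, events, switching = repeatability(align_labels(ens, 3))
        assert pct == 100.0
        assert events == 0
        assert switching == 0

    def test_twelve_of_370_gives_96_8(self):
        ens = make_ensemble({4: paper_style_k4()})
        pct, events, switching = repeatability(align_labels(ens, 4))
        assert events == 12
        assert round(pct, 1) == 96.8
        assert round(100 - pct, 1) == 3.2
        assert switching == 6

    def test_participant_switching_four_times(self):
        labels = paper_style_k4()
        ens = make_ensemble({4: labels})
        aligned = align_labels(ens, 4)
        table = boundary_analysis(aligned)
        assert int(table.loc[0, "n_switches"]) == 4


class TestMedianAllocation:
    def test_unanimous(self):
        aligned = AlignedEnsemble(2, np.tile([1, 2], (10, 1)),
                                  np.full((10, 2), 0.5), [])
        np.testing.assert_array_equal(median_allocation(aligned), [1, 2])

    def test_majority(self):
        col = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2, 2])
        aligned = AlignedEnsemble(2, col[:, None], np.full((10, 1), 0.5), [])
        assert median_allocation(aligned)[0] == 1

    def test_tie_broken_by_highest_silhouette(self):
        col = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        s = np.full((10, 1), 0.1)
        s[7, 0] = 0.9  # best silhouette occurs in a repetition voting 2
        aligned = AlignedEnsemble(2, col[:, None], s, [])
        assert median_allocation(aligned)[0] == 2


class TestSelectK:
    @pytest.fixture()
    def paper_like_ensemble(self, rng):
        n, R = 37, 10
        stable2 = np.tile(rng.integers(1, 3, size=n), (R, 1))
        stable3 = np.tile(rng.integers(1, 4, size=n), (R, 1))
        unstable5 = rng.integers(1, 6, size=(R, n))
        return make_ensemble({2: stable2, 3: stable3,
                              4: paper_style_k4(), 5: unstable5})

    def test_largest_repeatable_k_chosen(self, paper_like_ensemble):
        report = select_k(paper_like_ensemble, threshold=95.0)
        assert report.chosen_k == 4
        assert not report.fallback

    def test_raising_threshold_never_increases_k(self, paper_like_ensemble):
        previous = 5
        for threshold in (90.0, 95.0, 99.0, 100.0):
            chosen = select_k(paper_like_ensemble, threshold=threshold).chosen_k
            assert chosen <= previous
            previous = chosen

    def test_stricter_threshold_drops_to_3(self, paper_like_ensemble):
        assert select_k(paper_like_ensemble, threshold=99.0).chosen_k == 3

    def test_all_stable_chooses_max_k(self, rng):
        labels_by_k = {k: np.tile(np.arange(20) % k + 1, (5, 1))
                       for k in (2, 3, 4)}
        assert select_k(make_ensemble(labels_by_k)).chosen_k == 4

    def test_fallback_when_nothing_repeatable(self, rng):
        labels_by_k = {k: rng.integers(1, k + 1, size=(10, 30))
                       for k in (4, 5)}
        report = select_k(make_ensemble(labels_by_k), threshold=99.9)
        assert report.fallback
        assert report.chosen_k == 4

    def test_report_serializes(self, paper_like_ensemble, tmp_path):
        report = select_k(paper_like_ensemble)
        report.to_json(tmp_path / "sel.json")
        md = report.to_markdown()
        assert "Chosen k" in md and "| 4 |" in md


class TestBoundaryAnalysis:
    def test_no_switches_when_stable(self):
        labels = np.tile(np.array([1, 2, 1, 2]), (10, 1))
        aligned = AlignedEnsemble(2, labels, np.full((10, 4), 1.0), [])
        table = boundary_analysis(aligned)
        assert (table["n_switches"] == 0).all()

    def test_low_silhouette_participant_carries_switches(self):
        labels = np.tile(np.array([1, 2]), (10, 1))
        labels[3, 0] = 2
        labels[7, 0] = 2
        s = np.full((10, 2), 0.8)
        s[:, 0] = 0.02
        aligned = AlignedEnsemble(2, labels, s, [])
        table = boundary_analysis(aligned)
        assert int(table.loc[0, "n_switches"]) == 2
        assert int(table.loc[1, "n_switches"]) == 0

    def test_switch_count_anticorrelates_with_silhouette(self, default_cohort):
        """On a generated cohort ensemble, participants with lower mean
        silhouette switch at least as often (Spearman rho <= 0)."""
        from scipy.stats import spearmanr

        from gaitclust.clustering import run_ensemble
        from gaitclust.preprocessing import participants_to_matrix

        M = participants_to_matrix(default_cohort.participants).values
        ens = run_ensemble(M, k_range=(4,), n_restarts=10, n_repetitions=10,
                           master_seed=2)
        table = boundary_analysis(align_labels(ens, 4))
        if table["n_switches"].sum() == 0:
            pytest.skip("no allocation switches in this ensemble")
        rho = spearmanr(table["mean_s"], table["n_switches"]).statistic
        assert rho <= 0
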