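"""Summit co-occupancy, binned signal quantification and the NN-chain
clustering equivalence with naive agglomerative clustering."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from stat5targets.cooccupancy import (
    REDUCIBLE_LINKAGES,
    heatmap_order,
    leaf_order,
    match_summits,
    nn_chain_cluster,
    quantify_signal_matrix,
    venn_counts,
)
from stat5targets.genomics_io import SignalTrack

from conftest import make_peak


# ---------------------------------------------------------------------------
# naive O(n^3) agglomerative oracle (independent of the implementation)
# ---------------------------------------------------------------------------


def naive_agglomerative(X, linkage):
    X = np.asarray(X, float)
    n = X.shape[0]
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    size = {i: 1 for i in range(n)}
    cluster_id = {i: i for i in range(n)}
    active = list(range(n))
    Z = []
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or D[i, j] < best[0]:
                    best = (D[i, j], i, j)
        d, i, j = best
        Z.append(
            (min(cluster_id[i], cluster_id[j]), max(cluster_id[i], cluster_id[j]),
             d, size[i] + size[j])
        )
        for k in active:
            if k in (i, j):
                continue
            if linkage == "single":
                new = min(D[i, k], D[j, k])
            elif linkage == "complete":
                new = max(D[i, k], D[j, k])
            elif linkage == "average":
                new = (size[i] * D[i, k] + size[j] * D[j, k]) / (size[i] + size[j])
            elif linkage == "ward":
                tot = size[i] + size[j] + size[k]
                new = np.sqrt(
                    ((size[i] + size[k]) * D[i, k] ** 2
                     + (size[j] + size[k]) * D[j, k] ** 2
                     - size[k] * D[i, j] ** 2) / tot
                )
            D[i, k] = D[k, i] = new
        size[i] += size[j]
        cluster_id[i] = next_id
        next_id += 1
        active.remove(j)
        D[j, :] = np.inf
        D[:, j] = np.inf
    return np.array(Z)


def canonical(Z):
    """Order-insensitive form: per merge, the sorted leaf sets + height."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    rows = []
    for t in range(n - 1):
        m = members[int(Z[t, 0])] | members[int(Z[t, 1])]
        members[n + t] = m
        rows.append((round(float(Z[t, 2]), 9), tuple(sorted(m))))
    return sorted(rows)


class TestMatchSummits:
    def test_boundary_distances(self):
        a = [make_peak("chr1", 10_000)]
        for d, expect_pair in [(0, True), (500, True), (501, False)]:
            b = [make_peak("chr1", 10_000 + d, "b")]
            pairs = match_summits(a, b, max_dist=500)
            assert bool(pairs) is expect_pair
            if pairs:
                assert pairs[0].summit_distance == d

    def test_pairs_with_nearest_qualifying_summit(self):
        a = [make_peak("chr1", 10_000)]
        b = [make_peak("chr1", 10_400, "far"), make_peak("chr1", 9_900, "near")]
        (pair,) = match_summits(a, b)
        assert pair.peak_b.name == "near"

    def test_chromosomes_never_mix(self):
        a = [make_peak("chr1", 100)]
        b = [make_peak("chr2", 100)]
        assert match_summits(a, b) == []

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            match_summits([make_peak("chr1", 1)], [make_peak("chr1", 2)], -1)

    def test_count_symmetric_for_unique_pairings(self, rng):
        summits_a = np.cumsum(rng.integers(4000, 8000, size=40))
        offsets = rng.integers(-500, 501, size=40)
        mask = rng.random(40) < 0.5
        a = [make_peak("chr1", int(s), f"a{i}") for i, s in enumerate(summits_a)]
        b = [
            make_peak("chr1", int(s + (o if m else 2000 + abs(o))), f"b{i}")
            for i, (s, o, m) in enumerate(zip(summits_a, offsets, mask))
        ]
        assert len(match_summits(a, b)) == len(match_summits(b, a)) == int(mask.sum())

    def test_monotone_in_max_dist(self, rng):
        a = [make_peak("chr1", int(s)) for s in np.cumsum(rng.integers(1000, 5000, 30))]
        b = [make_peak("chr1", int(s)) for s in np.cumsum(rng.integers(1000, 5000, 30))]
        counts = [len(match_summits(a, b, d)) for d in (0, 100, 500, 2000, 10_000)]
        assert counts == sorted(counts)


class TestVennCounts:
    def test_self_cooccupancy_is_total(self):
        ref = [make_peak("chr1", s, f"p{s}") for s in (1000, 9000, 30_000)]
        counts = venn_counts(ref, {"self": ref})
        assert counts["self_total"] == 3 and counts["none"] == 0

    def test_disjoint_chromosomes_have_zero_overlap(self):
        ref = [make_peak("chr1", 1000)]
        counts = venn_counts(ref, {"other": [make_peak("chr2", 1000)]})
        assert counts["other_total"] == 0 and counts["none"] == 1

    def test_empty_reference_rejected(self):
        ref = [make_peak("chr1", 1000)]
        with pytest.raises(ValueError):
            venn_counts([], {"a": ref})

    def test_regions_partition_reference(self, default_dataset):
        ds = default_dataset
        counts = venn_counts(
            ds.peak_sets["pSTAT5"],
            {"KLF1": ds.peak_sets["KLF1"], "GATA1": ds.peak_sets["GATA1"]},
        )
        regions = ["none", "GATA1", "KLF1", "GATA1+KLF1"]
        assert sum(counts[r] for r in regions) == len(ds.peak_sets["pSTAT5"])

    def test_planted_cooccupancy_counts_recovered_exactly(self, default_dataset):
        """Planted fractions 67/302 and 147/302 are recovered as exact
        totals; the generator's geometry admits no accidental pairs."""
        ds = default_dataset
        counts = venn_counts(
            ds.peak_sets["pSTAT5"],
            {"KLF1": ds.peak_sets["KLF1"], "GATA1": ds.peak_sets["GATA1"]},
        )
        assert counts["KLF1_total"] == 67
        assert counts["GATA1_total"] == 147
        planted_both = sum(
            {"KLF1", "GATA1"} <= set(p)
            for p in ds.truth.peak_partners.values()
        )
        assert counts["GATA1+KLF1"] == planted_both


class TestQuantifySignalMatrix:
    def test_constant_track_and_max_normalisation(self):
        track = SignalTrack(
            {"chr1": (np.array([0]), np.array([100_000]), np.array([3.0]))},
            total_reads=1e6,
        )
        peaks = [make_peak("chr1", 50_000)]
        raw, trunc = quantify_signal_matrix(
            track, peaks, 500, 50, log_transform=False, max_normalize=False
        )
        assert np.allclose(raw, 3.0)
        normed, _ = quantify_signal_matrix(
            track, peaks, 500, 50, log_transform=False, max_normalize=True
        )
        assert np.allclose(normed, 1.0)
        assert not trunc.any()

    def test_zero_track_stays_zero_after_log(self):
        track = SignalTrack(
            {"chr1": (np.array([0]), np.array([1000]), np.array([0.0]))},
            total_reads=1e6,
        )
        m, _ = quantify_signal_matrix(track, [make_peak("chr1", 500)], 100, 10)
        assert np.all(m == 0.0)

    def test_triangle_bin_means_match_per_base_oracle(self):
        summit, half, height = 5000, 300, 12.0
        pos = np.arange(summit - half, summit + half + 1)
        vals = height * (1 - np.abs(pos - summit) / half)
        track = SignalTrack(
            {"chr1": (pos, pos + 1, vals)}, total_reads=1e6
        )
        m, _ = quantify_signal_matrix(
            track, [make_peak("chr1", summit)], 500, 50,
            log_transform=False, max_normalize=False,
        )
        base = np.zeros(12_000)
        base[pos] = vals
        expected = base[summit - 500 : summit + 500].reshape(50, 20).mean(axis=1)
        assert np.allclose(m[0], expected)

    def test_rpm_invariant_under_joint_scaling(self):
        steps = (np.array([0]), np.array([1000]), np.array([5.0]))
        t1 = SignalTrack({"chr1": steps}, total_reads=2e6)
        t2 = SignalTrack(
            {"chr1": (steps[0], steps[1], steps[2] * 7)}, total_reads=2e6 * 7
        )
        peaks = [make_peak("chr1", 500)]
        m1, _ = quantify_signal_matrix(t1, peaks, 100, 10, log_transform=False)
        m2, _ = quantify_signal_matrix(t2, peaks, 100, 10, log_transform=False)
        assert np.allclose(m1, m2)

    def test_window_off_chromosome_start_is_truncated_and_flagged(self):
        track = SignalTrack(
            {"chr1": (np.array([0]), np.array([1000]), np.array([1.0]))},
            total_reads=1e6,
        )
        m, trunc = quantify_signal_matrix(
            track, [make_peak("chr1", 100)], 500, 50,
            log_transform=False, max_normalize=False,
        )
        assert trunc[0]
        assert m[0, 0] == 0.0  # bins before the chromosome start are empty

    def test_bins_must_divide_window(self):
        track = SignalTrack(
            {"chr1": (np.array([0]), np.array([100]), np.array([1.0]))},
            total_reads=1e6,
        )
        with pytest.raises(ValueError):
            quantify_signal_matrix(track, [make_peak("chr1", 50)], 30, 7)


class TestNnChainClustering:
    def test_single_row_has_no_merges(self):
        Z, order = nn_chain_cluster(np.array([[1.0, 2.0]]))
        assert Z.shape == (0, 4) and order == [0]

    def test_identical_rows_merge_first_at_height_zero(self, rng):
        X = rng.normal(size=(5, 8))
        X[3] = X[1]
        Z, _ = nn_chain_cluster(X, "average")
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {1, 3}

    @pytest.mark.parametrize("linkage", REDUCIBLE_LINKAGES)
    def test_tree_equals_naive_oracle_on_random_matrices(self, linkage):
        """Merge tree (same merges, same heights) equals naive O(n^3)
        agglomerative clustering for 50 random 20x50 matrices."""
        rng = np.random.default_rng(hash(linkage) % 2**31)
        for _ in range(50):
            X = rng.normal(size=(20, 50))
            Z, _ = nn_chain_cluster(X, linkage)
            Z_naive = naive_agglomerative(X, linkage)
            assert canonical(Z) == canonical(Z_naive)

    @pytest.mark.parametrize("linkage", REDUCIBLE_LINKAGES)
    def test_tree_matches_scipy_linkage(self, linkage, rng):
        """Independent library cross-check on the same data."""
        for _ in range(5):
            X = rng.normal(size=(15, 10))
            Z, _ = nn_chain_cluster(X, linkage)
            Z_ref = hierarchy.linkage(X, method=linkage)
            assert canonical(Z) == canonical(Z_ref)
            assert np.allclose(np.sort(Z[:, 2]), np.sort(Z_ref[:, 2]))

    def test_non_reducible_linkage_refused_with_explanation(self):
        with pytest.raises(ValueError, match="reducible"):
            nn_chain_cluster(np.zeros((3, 2)), "centroid")

    def test_leaf_order_visits_tighter_cluster_first(self):
        X = np.array([[0.0], [0.1], [10.0], [30.0]])
        Z, order = nn_chain_cluster(X, "average")
        # at every node the lower-height child leads: the singleton row 3
        # (height 0) precedes the looser super-cluster, and inside it row 2
        # precedes the {0, 1} pair merged at height 0.1
        assert order == [3, 2, 0, 1]
        assert leaf_order(Z) == order


class TestHeatmapOrder:
    def _two_block_setup(self, rng, n=30):
        summits = np.cumsum(rng.integers(4000, 8000, size=n)) + 2000
        tall = rng.permutation(n) < n // 2
        pos_all, val_all = [], []
        for s, is_tall in zip(summits, tall):
            pos = np.arange(s - 300, s + 301)
            h = 40.0 if is_tall else 5.0
            val_all.append(h * (1 - np.abs(pos - s) / 300))
            pos_all.append(pos)
        track = SignalTrack(
            {"chr1": (np.concatenate(pos_all), np.concatenate(pos_all) + 1,
                      np.concatenate(val_all))}
        )
        peaks = [make_peak("chr1", int(s), f"p{i}") for i, s in enumerate(summits)]
        return peaks, track, tall

    def test_planted_blocks_become_contiguous(self, rng):
        peaks, track, tall = self._two_block_setup(rng)
        result = heatmap_order(peaks, {"ref": track})
        labels = [tall[i] for i in result.row_order]
        switches = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert switches == 1  # exactly one boundary between the blocks

    def test_display_equals_cluster_matrix_at_equal_widths(self, rng):
        peaks, track, _ = self._two_block_setup(rng, n=10)
        res = heatmap_order(
            peaks, {"ref": track}, cluster_half_width=250, display_half_width=250
        )
        from stat5targets.cooccupancy import quantify_signal_matrix as q

        raw, _ = q(track, peaks, 250, 50, log_transform=True, max_normalize=True)
        assert np.allclose(res.display["ref"], raw[res.row_order])

    def test_empty_track_dict_is_an_error(self):
        with pytest.raises(ValueError):
            heatmap_order([make_peak("chr1", 100)], {})
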