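"""Summit-distance co-occupancy, binding/Venn counts, binned signal
matrices and nearest-neighbour-chain hierarchical clustering.

Two factors co-occupy a site when their ChIP summits lie within a fixed
distance (default 500 bp, inclusive) on the same chromosome.  Signal
heatmaps are quantified as per-bin, reads-per-million-normalised means
around the reference summits, log-transformed and normalised to each
track's maximum over the clustered area, then row-clustered with the
NN-chain algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genomics_io import Peak, SignalTrack

DEFAULT_MAX_DIST = 500

REDUCIBLE_LINKAGES = ("average", "complete", "single", "ward")


@dataclass(frozen=True)
class CooccupancyPair:
    peak_a: Peak
    peak_b: Peak
    summit_distance: int

    def __post_init__(self) -> None:
        if self.summit_distance < 0:
            raise ValueError("summit_distance must be >= 0")


def match_summits(
    set_a: list[Peak], set_b: list[Peak], max_dist: int = DEFAULT_MAX_DIST
) -> list[CooccupancyPair]:
    """Pair each A-peak with its nearest B-summit within ``max_dist`` (inclusive)."""
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    if not set_a or not set_b:
        raise ValueError("both peak sets must be non-empty")
    by_chrom: dict[str, list[Peak]] = {}
    for b in set_b:
        by_chrom.setdefault(b.chrom, []).append(b)
    sorted_summits = {
        chrom: (
            np.array([p.summit for p in sorted(peaks, key=lambda p: p.summit)]),
            sorted(peaks, key=lambda p: p.summit),
        )
        for chrom, peaks in by_chrom.items()
    }
    pairs: list[CooccupancyPair] = []
    for a in set_a:
        if a.chrom not in sorted_summits:
            continue
        summits, peaks = sorted_summits[a.chrom]
        i = int(np.searchsorted(summits, a.summit))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(peaks):
                d = abs(int(summits[j]) - a.summit)
                if best is None or d < best[0]:
                    best = (d, peaks[j])
        if best is not None and best[0] <= max_dist:
            pairs.append(CooccupancyPair(a, best[1], best[0]))
    return pairs


def binding_matrix(
    reference: list[Peak],
    others: dict[str, list[Peak]],
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Boolean reference-peak x factor matrix of co-occupancy."""
    if len(set(others)) != len(others):
        raise ValueError("duplicate factor names")
    names = [p.name for p in reference]
    if len(set(names)) != len(names):
        names = [f"{p.name}#{i}" for i, p in enumerate(reference)]
    matrix = pd.DataFrame(False, index=names, columns=list(others))
    index_of = {id(p): name for p, name in zip(reference, names)}
    for factor, peaks in others.items():
        for pair in match_summits(reference, peaks, max_dist):
            matrix.loc[index_of[id(pair.peak_a)], factor] = True
    return matrix


def venn_counts(
    reference: list[Peak],
    others: dict[str, list[Peak]],
    max_dist: int = DEFAULT_MAX_DIST,
) -> dict[str, int]:
    """Counts per Venn region over the reference set.

    Keys are '+'-joined sorted factor-name combinations plus "none";
    additionally "<factor>_total" gives per-factor totals.  Regions
    partition the reference set.
    """
    if not reference:
        raise ValueError("reference peak set must be non-empty")
    if len(others) != len(set(others)):
        raise ValueError("duplicate factor names")
    matrix = binding_matrix(reference, others, max_dist)
    counts: dict[str, int] = {}
    factors = list(others)
    for r in range(len(factors) + 1):
        for combo in combinations(factors, r):
            mask = np.ones(len(matrix), dtype=bool)
            for f in factors:
                col = matrix[f].to_numpy()
                mask &= col if f in combo else ~col
            key = "+".join(sorted(combo)) if combo else "none"
            counts[key] = int(mask.sum())
    for f in factors:
        counts[f"{f}_total"] = int(matrix[f].sum())
    return counts


# ---------------------------------------------------------------------------
# Binned signal matrices
# ---------------------------------------------------------------------------


def quantify_signal_matrix(
    track: SignalTrack,
    peaks: list[Peak],
    half_width: int,
    n_bins: int = 50,
    log_transform: bool = True,
    max_normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak binned signal around summits, reads-per-million normalised.

    Returns (matrix of shape (n_peaks, n_bins), truncated-row flags).
    Windows reaching below position 0 are truncated (missing bases count
    as zero signal) and flagged.  With ``log_transform`` values map to
    log2(v + 1); with ``max_normalize`` the whole matrix is divided by
    its maximum (when positive).
    """
    if (2 * half_width) % n_bins != 0:
        raise ValueError("2*half_width must be divisible by n_bins")
    if track.total_reads <= 0:
        raise ValueError("track.total_reads must be positive")
    matrix = np.zeros((len(peaks), n_bins), dtype=float)
    truncated = np.zeros(len(peaks), dtype=bool)
    scale = 1e6 / track.total_reads
    width = (2 * half_width) // n_bins
    for i, peak in enumerate(peaks):
        start = peak.summit - half_width
        end = peak.summit + half_width
        if start < 0:
            truncated[i] = True
            # clip to the chromosome start; missing bases contribute 0
            edges = np.clip(
                start + np.arange(n_bins + 1, dtype=np.int64) * width, 0, None
            )
            f = track._integral_to(peak.chrom, edges)
            matrix[i] = np.diff(f) / width
        else:
            matrix[i] = track.bin_means(peak.chrom, start, end, n_bins)
    matrix *= scale
    if log_transform:
        matrix = np.log2(matrix + 1.0)
    if max_normalize:
        peak_max = matrix.max()
        if peak_max > 0:
            matrix = matrix / peak_max
    return matrix, truncated


# ---------------------------------------------------------------------------
# Nearest-neighbour-chain agglomerative clustering
# ---------------------------------------------------------------------------


def _lance_williams(linkage: str):
    if linkage == "single":
        return lambda d_ik, d_jk, d_ij, n_i, n_j, n_k: np.minimum(d_ik, d_jk)
    if linkage == "complete":
        return lambda d_ik, d_jk, d_ij, n_i, n_j, n_k: np.maximum(d_ik, d_jk)
    if linkage == "average":
        return lambda d_ik, d_jk, d_ij, n_i, n_j, n_k: (
            (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
        )
    if linkage == "ward":
        def ward(d_ik, d_jk, d_ij, n_i, n_j, n_k):
            tot = n_i + n_j + n_k
            return np.sqrt(
                ((n_i + n_k) * d_ik**2 + (n_j + n_k) * d_jk**2 - n_k * d_ij**2) / tot
            )
        return ward
    raise ValueError(
        f"linkage {linkage!r} is not usable with the nearest-neighbour chain "
        f"algorithm (it requires a reducible linkage: {REDUCIBLE_LINKAGES}); "
        "centroid/median can invert merges under the chain and are refused"
    )


def nn_chain_cluster(
    matrix: np.ndarray, linkage: str = "average"
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering of rows via the nearest-neighbour chain.

    Distances are Euclidean on row vectors.  Returns a scipy-style merge
    matrix Z of shape (n-1, 4) — children ids, merge height, cluster size,
    sorted by height — and the display leaf order (recursive traversal,
    tighter child first).  The merge tree equals naive O(n^3)
    agglomerative clustering for every reducible linkage.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one row")
    update = _lance_williams(linkage)
    if n == 1:
        return np.zeros((0, 4)), [0]
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    size = np.ones(n)
    active = np.ones(n, dtype=bool)
    rep_leaf = np.arange(n)  # a representative original row per live cluster slot
    merges: list[tuple[int, int, float, int]] = []
    chain: list[int] = []
    remaining = n
    while remaining > 1:
        if not chain:
            chain.append(int(np.nonzero(active)[0][0]))
        while True:
            x = chain[-1]
            row = np.where(active, D[x], np.inf)
            row[x] = np.inf
            dmin = row.min()
            prev = chain[-2] if len(chain) > 1 else -1
            # prefer the chain predecessor on ties so reciprocity is detected
            y = prev if prev >= 0 and row[prev] == dmin else int(np.argmin(row))
            if y == prev:
                break
            chain.append(y)
        x = chain.pop()
        y = chain.pop()
        lo, hi = (x, y) if x < y else (y, x)
        merges.append((int(rep_leaf[lo]), int(rep_leaf[hi]), float(D[lo, hi]), int(size[lo] + size[hi])))
        # merge hi into lo
        others = active.copy()
        others[[lo, hi]] = False
        idx = np.nonzero(others)[0]
        D[lo, idx] = update(D[lo, idx], D[hi, idx], D[lo, hi], size[lo], size[hi], size[idx])
        D[idx, lo] = D[lo, idx]
        active[hi] = False
        D[hi, :] = np.inf
        D[:, hi] = np.inf
        size[lo] += size[hi]
        remaining -= 1
    Z = _label(merges, n)
    return Z, leaf_order(Z)


def _label(merges: list[tuple[int, int, float, int]], n: int) -> np.ndarray:
    """Sort chain merges by height and assign scipy-style cluster ids."""
    order = sorted(range(len(merges)), key=lambda i: (merges[i][2], i))
    parent = np.arange(n)
    cluster_id = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    Z = np.zeros((n - 1, 4))
    for t, mi in enumerate(order):
        a, b, height, sz = merges[mi]
        ra, rb = find(a), find(b)
        ca, cb = cluster_id[ra], cluster_id[rb]
        lo, hi = (ca, cb) if ca < cb else (cb, ca)
        Z[t] = (lo, hi, height, sz)
        parent[rb] = ra
        cluster_id[ra] = n + t
    return Z


def leaf_order(Z: np.ndarray) -> list[int]:
    """Display order of leaves: recursive traversal, tighter cluster first.

    At each internal node the child with the smaller merge height (leaves
    count as height 0) is visited first; ties go to the smaller id.
    """
    n = Z.shape[0] + 1
    if n == 1:
        return [0]
    height = {i: 0.0 for i in range(n)}
    children = {}
    for t in range(Z.shape[0]):
        node = n + t
        height[node] = float(Z[t, 2])
        children[node] = (int(Z[t, 0]), int(Z[t, 1]))
    out: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            out.append(node)
            continue
        a, b = children[node]
        first, second = sorted((a, b), key=lambda c: (height[c], c))
        stack.append(second)
        stack.append(first)
    return out


# ---------------------------------------------------------------------------
# Heatmap assembly
# ---------------------------------------------------------------------------


@dataclass
class HeatmapResult:
    row_order: list[int]  # indices into the reference peak list
    row_names: list[str]  # peak names in display order
    display: dict[str, np.ndarray]  # per-track matrices, rows in display order
    merge_tree: np.ndarray  # scipy-style Z from the clustering window


def heatmap_order(
    peaks: list[Peak],
    tracks: dict[str, SignalTrack],
    cluster_half_width: int = 250,
    display_half_width: int = 5000,
    n_bins: int = 50,
    linkage: str = "average",
    log_transform: bool = True,
) -> HeatmapResult:
    """Cluster peaks on signal within the clustering window; return display
    matrices at the (wider) display window in the clustered row order.

    Every track is reads-per-million normalised, log-transformed, and
    divided by its own maximum over the *clustered* area; the display
    matrices reuse the same per-track maxima so the two windows share a
    scale.
    """
    if not tracks:
        raise ValueError("at least one signal track is required")
    if not peaks:
        raise ValueError("at least one reference peak is required")
    cluster_parts: list[np.ndarray] = []
    display_mats: dict[str, np.ndarray] = {}
    for name, track in tracks.items():
        cmat, _ = quantify_signal_matrix(
            track, peaks, cluster_half_width, n_bins,
            log_transform=log_transform, max_normalize=False,
        )
        dmat, _ = quantify_signal_matrix(
            track, peaks, display_half_width, n_bins,
            log_transform=log_transform, max_normalize=False,
        )
        peak_val = cmat.max()
        if peak_val > 0:
            cmat = cmat / peak_val
            dmat = dmat / peak_val
        cluster_parts.append(cmat)
        display_mats[name] = dmat
    stacked = np.hstack(cluster_parts)
    Z, order = nn_chain_cluster(stacked, linkage=linkage)
    display = {name: mat[order] for name, mat in display_mats.items()}
    names = [peaks[i].name for i in order]
    return HeatmapResult(order, names, display, Z)
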