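"""Degenerate-consensus and PWM motif detection plus central enrichment.

The central-enrichment statistic asks whether the best motif site per
summit-centred sequence concentrates near the sequence centre — evidence
that the ChIP signal derives from direct, sequence-specific binding.  For
each odd window width W the count of best-site centres within W/2 of the
sequence centre is compared with a binomial null in which best sites fall
uniformly over the possible offsets; the best window's tail probability is
Bonferroni-adjusted for the number of windows tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

# Shipping consensus presets.  The GAS element is printed with a Y/M core
# in the motif-discovery figure; note it is *not* exactly self-reverse-
# complementary (revcomp(TTCYMRGAA) = TTCYKRGAA), which is_palindromic
# reports honestly.  Two GATA variants circulate (WGATAA, WGATAR); both
# are provided.
GAS_CONSENSUS = "TTCYMRGAA"
GATA_CONSENSUS = "WGATAR"
GATA_CONSENSUS_ALT = "WGATAA"
KLF_CONSENSUS = "CCMCRCCCN"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "M": "K", "K": "M", "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
# Base bit encoding: N in a *sequence* carries its own bit so that only a
# pattern N (whose expansion includes N) can match it.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC degenerate consensus pattern."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifError("empty consensus pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise MotifError(f"invalid IUPAC symbols: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def width(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int
    strand: str
    score: float  # log-odds bits for PWM hits; 1.0 for consensus matches


@dataclass(frozen=True)
class CentralEnrichmentResult:
    best_window_width: int
    central_count: int
    total_count: int
    p_value: float
    adjusted_p: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.central_count > self.total_count:
            raise ValueError("central_count cannot exceed total_count")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise MotifError(f"invalid IUPAC symbol {exc}") from exc


def is_palindromic(motif: ConsensusMotif | str) -> bool:
    """True iff the degenerate pattern equals its own reverse complement."""
    pattern = motif.pattern if isinstance(motif, ConsensusMotif) else ConsensusMotif(motif).pattern
    return reverse_complement(pattern) == pattern


def _encode_bits(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise MotifError(f"sequence contains invalid bases: {sorted(bad)}")
    return np.array([_BASE_BIT[b] for b in seq], dtype=np.uint8)


def _pattern_masks(pattern: str) -> np.ndarray:
    masks = []
    for sym in pattern:
        mask = 0
        for base in IUPAC[sym]:
            mask |= _BASE_BIT[base]
        masks.append(mask)
    return np.array(masks, dtype=np.uint8)


def _match_offsets(pattern: str, seq_bits: np.ndarray) -> np.ndarray:
    w = len(pattern)
    if len(seq_bits) < w:
        return np.zeros(0, dtype=bool)
    windows = sliding_window_view(seq_bits, w)
    return ((windows & _pattern_masks(pattern)) != 0).all(axis=1)


def iupac_match(
    motif: ConsensusMotif | str, seq: str, sequence_id: str = "seq"
) -> list[MotifHit]:
    """All exact degenerate matches on both strands.

    The reverse strand is scanned by matching the reverse complement of
    the pattern on the forward sequence; hit coordinates are forward-
    strand starts in both cases.
    """
    motif = motif if isinstance(motif, ConsensusMotif) else ConsensusMotif(motif)
    bits = _encode_bits(seq)
    hits = [
        MotifHit(sequence_id, int(i), "+", 1.0)
        for i in np.nonzero(_match_offsets(motif.pattern, bits))[0]
    ]
    rc = reverse_complement(motif.pattern)
    for i in np.nonzero(_match_offsets(rc, bits))[0]:
        hits.append(MotifHit(sequence_id, int(i), "-", 1.0))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Column-stochastic base probabilities with a background model.

    Scores are log2(prob/background) bits; sequence N scores -inf.
    """

    probs: np.ndarray  # (width, 4) columns A, C, G, T
    background: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise MotifError("probs must be (width, 4)")
        if probs.shape[0] < 1:
            raise MotifError("PWM needs at least one position")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise MotifError("each PWM column must sum to 1")
        if np.any(np.abs(background.sum() - 1.0) > 1e-9) or np.any(background <= 0):
            raise MotifError("background must be positive and sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", background)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score_matrix(self) -> np.ndarray:
        """(width, 5) log2-odds matrix; column 5 (N) is -inf."""
        with np.errstate(divide="ignore"):
            s = np.log2(self.probs / self.background)
        return np.hstack([s, np.full((self.width, 1), -np.inf)])

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


UNIFORM_BACKGROUND = np.full(4, 0.25)


def build_pwm(
    sites: list[str],
    pseudocount: float = 0.0,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> PWM:
    """Estimate a PWM from aligned equal-length sites.

    probs = (count + pseudocount) / (n + 4 * pseudocount) per column.
    """
    if len(sites) < 2:
        raise MotifError("need at least two aligned sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise MotifError("sites must have equal length")
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        for j, base in enumerate(site.upper()):
            if base not in "ACGT":
                raise MotifError(f"site base {base!r} is not A/C/G/T")
            counts[j, _BASE_INDEX[base]] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(probs, np.asarray(background, dtype=float))


def _pwm_scores_both_strands(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset log-odds scores on forward and reverse strands."""
    idx = np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    if len(idx) < pwm.width:
        raise MotifError("sequence shorter than PWM width")
    windows = sliding_window_view(idx, pwm.width)  # (n_offsets, w)
    fwd = pwm.score_matrix()[np.arange(pwm.width), windows].sum(axis=1)
    rev = pwm.reverse_complement().score_matrix()[np.arange(pwm.width), windows].sum(axis=1)
    return fwd, rev


def scan_pwm(
    pwm: PWM, seq: str, threshold: float, sequence_id: str = "seq"
) -> list[MotifHit]:
    """Both-strand log-odds scan; hits where score >= threshold (bits)."""
    fwd, rev = _pwm_scores_both_strands(pwm, seq)
    hits = [
        MotifHit(sequence_id, int(i), "+", float(fwd[i]))
        for i in np.nonzero(fwd >= threshold)[0]
    ]
    hits += [
        MotifHit(sequence_id, int(i), "-", float(rev[i]))
        for i in np.nonzero(rev >= threshold)[0]
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Central enrichment
# ---------------------------------------------------------------------------


def _best_offset(scores_by_strand: tuple[np.ndarray, np.ndarray], centre: float) -> int | None:
    """Best-scoring offset; ties -> closest to centre, then lowest offset,
    then forward strand.  None when every score is -inf."""
    fwd, rev = scores_by_strand
    best = np.maximum(fwd, rev)
    if np.all(np.isinf(best) & (best < 0)):
        return None
    top = best.max()
    cand = np.nonzero(best == top)[0]
    dist = np.abs(cand - centre)
    order = np.lexsort((cand, dist))
    return int(cand[order[0]])


def best_site_positions(
    motif: "PWM | ConsensusMotif | str", sequences: list[str]
) -> tuple[np.ndarray, int, int]:
    """Best-site centre positions (one per sequence with a site).

    Returns (centre positions, L, w).  For a consensus motif only exact
    matches count as sites; sequences without a match are dropped.  For a
    PWM every finite-scoring offset is a candidate.
    """
    if not sequences:
        raise MotifError("no sequences supplied")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise MotifError("sequences must have equal length")
    if isinstance(motif, str):
        motif = ConsensusMotif(motif)
    w = motif.width
    if w > L:
        raise MotifError("motif wider than the sequences")
    centre_offset = (L - w) / 2.0
    half_w = (w - 1) / 2.0
    positions: list[float] = []
    if isinstance(motif, PWM):
        for seq in sequences:
            off = _best_offset(_pwm_scores_both_strands(motif, seq), centre_offset)
            if off is not None:
                positions.append(off + half_w)
    else:
        rc = reverse_complement(motif.pattern)
        for seq in sequences:
            bits = _encode_bits(seq)
            match = _match_offsets(motif.pattern, bits) | _match_offsets(rc, bits)
            offs = np.nonzero(match)[0]
            if len(offs) == 0:
                continue
            order = np.lexsort((offs, np.abs(offs - centre_offset)))
            positions.append(float(offs[order[0]]) + half_w)
    return np.asarray(positions, dtype=float), L, w


def enrichment_from_positions(
    positions: np.ndarray,
    L: int,
    w: int,
    max_window: int | None = None,
    n_total: int | None = None,
) -> CentralEnrichmentResult:
    """Binomial central-enrichment test on best-site centre positions.

    ``positions`` are site centres (offset + (w-1)/2).  For each odd
    window width W the null probability is the fraction of candidate
    site-centre positions within W/2 of the sequence centre; the reported
    window minimises the binomial tail p, Bonferroni-adjusted by the
    number of windows tested.
    """
    positions = np.asarray(positions, dtype=float)
    n = int(len(positions)) if n_total is None else int(n_total)
    if n == 0:
        raise MotifError("central enrichment needs at least one best site")
    if max_window is None:
        max_window = L // 2
    widths = np.arange(1, max_window + 1, 2, dtype=int)
    if len(widths) == 0:
        raise MotifError("max_window too small: no odd window widths to test")
    centre = (L - 1) / 2.0
    offsets = np.arange(L - w + 1, dtype=float) + (w - 1) / 2.0  # candidate centres
    dist = np.abs(positions - centre)
    cand_dist = np.abs(offsets - centre)
    best: tuple[float, int, int] | None = None  # (p, W, k)
    for W in widths:
        half = (W - 1) / 2.0
        n_inside = int(np.sum(cand_dist <= half))
        if n_inside == 0:
            continue
        p0 = n_inside / len(offsets)
        k = int(np.sum(dist <= half))
        p = float(stats.binom.sf(k - 1, n, p0))
        if best is None or p < best[0]:
            best = (p, int(W), k)
    assert best is not None
    p, W, k = best
    return CentralEnrichmentResult(
        best_window_width=W,
        central_count=k,
        total_count=n,
        p_value=min(1.0, p),
        adjusted_p=p * len(widths),
        n_windows=len(widths),
    )


def central_enrichment_test(
    motif: "PWM | ConsensusMotif | str",
    sequences: list[str],
    max_window: int | None = None,
) -> CentralEnrichmentResult:
    """Central-enrichment test on equal-length summit-centred sequences."""
    positions, L, w = best_site_positions(motif, sequences)
    if len(positions) == 0:
        raise MotifError("no sequence contains a motif site")
    return enrichment_from_positions(positions, L, w, max_window=max_window)
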