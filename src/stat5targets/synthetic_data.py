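"""Deterministic, seeded generator of synthetic study inputs with planted truth.

The generator emulates the data structure of an EPO-stimulation study in
an erythroid cell line: a few hundred ChIP peaks with summits, fold
enrichments and centrally planted GAS 9-mers; partially co-occupied
GATA1/KLF1 summit sets; peak-shaped signal tracks; replicated nascent-RNA
count tables with planted induced/repressed genes; and CAGE tag time
courses with immediate, delayed and unresponsive dynamics.

The genome is laid out in role zones so every planted label is exact by
construction:

* *mixed* chromosomes carry the host genes of all gene-attached peak
  classes (promoter/UTR/CDS/intron/distal), including the planted direct
  target genes;
* a *quiet* chromosome carries the planted factor-independent DEGs and
  filler genes — it contains no reference peak at all, so no peak can
  fall within the linkage window of these genes;
* the last chromosome carries only unresponsive host genes plus a >50 kb
  gene desert for intergenic peaks, so every peak there is
  bound-unresponsive by construction.

Reference summits are spaced >= ~2 kb apart, co-occupancy partners sit
within +/-500 bp of their reference summit and decoy factor peaks >= 2 kb
away, which makes the planted co-occupancy counts exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_response import CageExperiment
from .genomics_io import (
    CountTable,
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    write_counts,
    write_fasta,
    write_gene_models,
    write_peaks,
    write_signal,
)
from .motif_analysis import GAS_CONSENSUS, IUPAC

REFERENCE_FACTOR = "pSTAT5"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study's scale."""

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    n_genes: int = 330
    # peaks
    n_peaks: int = 302
    feature_class_counts: dict = field(
        default_factory=lambda: {
            "promoter": 70, "UTR": 12, "CDS": 10,
            "intron": 90, "distal": 75, "intergenic": 45,
        }
    )
    n_unresponsive_hosts: int = 25
    cooccupancy_fractions: dict = field(
        default_factory=lambda: {"KLF1": 67 / 302, "GATA1": 147 / 302}
    )
    n_decoys_per_factor: int = 60
    cooccupancy_max_offset: int = 500
    decoy_min_distance: int = 2000
    central_motif_rate: float = 0.8
    peak_half_width: int = 200
    flank: int = 500
    fold_enrichment_range: tuple = (5.0, 40.0)
    # expression
    n_induced: int = 63
    n_repressed: int = 24
    n_direct_induced: int = 40
    n_direct_repressed: int = 15
    fold_range: tuple = (1.5, 8.4)
    dispersion: float = 0.01
    count_mean_range: tuple = (500.0, 5000.0)
    n_replicates: int = 2
    library_size_factors: tuple = (1.0, 1.08, 0.94, 1.02)
    # signal tracks
    triangle_half_width: int = 300
    tall_height: float = 30.0
    short_height: float = 8.0
    tall_fraction: float = 0.5
    noise_floor: float = 0.2
    partner_height: float = 15.0
    # CAGE
    cage_region_counts: dict = field(
        default_factory=lambda: {"immediate": 10, "delayed": 10, "unresponsive": 10}
    )
    # stable background promoters; median-of-ratios normalisation assumes
    # most regions are unchanged, as in a genome-wide CAGE library
    cage_background_regions: int = 170
    cage_times: tuple = (0, 30, 60, 120, 240, 480, 1440)
    cage_replicates: int = 2
    cage_base_count: float = 200.0
    cage_amplitude_range: tuple = (3.0, 8.0)
    cage_noise_sd: float = 0.15
    cage_profile_width: float = 0.55  # log-time bump width

    def __post_init__(self) -> None:
        if self.n_chroms < 3 and self.n_peaks > 0:
            raise ValueError("need at least 3 chromosomes (mixed/quiet/desert roles)")
        if sum(self.feature_class_counts.values()) != self.n_peaks:
            raise ValueError("feature class counts must sum to n_peaks")
        for factor, frac in self.cooccupancy_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"co-occupancy fraction for {factor} outside [0,1]")
        if not 0.0 <= self.central_motif_rate <= 1.0:
            raise ValueError("central_motif_rate outside [0,1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.fold_range) <= 0:
            raise ValueError("fold changes must be > 0")
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.n_direct_induced > self.n_induced or self.n_direct_repressed > self.n_repressed:
            raise ValueError("direct DEG counts exceed DEG counts")
        if len(self.library_size_factors) != 2 * self.n_replicates:
            raise ValueError("need one library size factor per sample")
        if tuple(sorted(self.cage_times)) != tuple(self.cage_times) or (
            self.cage_times and self.cage_times[0] != 0
        ):
            raise ValueError("cage_times must be increasing and start at 0")

    @property
    def n_hosts(self) -> int:
        return sum(
            c for cls, c in self.feature_class_counts.items() if cls != "intergenic"
        )

    @property
    def n_independent(self) -> int:
        return (self.n_induced - self.n_direct_induced) + (
            self.n_repressed - self.n_direct_repressed
        )

    @classmethod
    def small(cls, seed: int = 0) -> "SimulationConfig":
        """A reduced preset for fast file-level and oracle tests."""
        return cls(
            seed=seed,
            chrom_length=800_000,
            n_genes=50,
            n_peaks=40,
            feature_class_counts={
                "promoter": 10, "UTR": 4, "CDS": 4,
                "intron": 10, "distal": 8, "intergenic": 4,
            },
            n_unresponsive_hosts=6,
            n_decoys_per_factor=10,
            n_induced=10,
            n_repressed=4,
            n_direct_induced=6,
            n_direct_repressed=2,
            cage_region_counts={"immediate": 4, "delayed": 4, "unresponsive": 4},
        )


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """What the generator planted, for recovery tests."""

    peak_class: dict = field(default_factory=dict)
    peak_partners: dict = field(default_factory=dict)  # peak -> list of factors
    peak_motif_centre: dict = field(default_factory=dict)  # peak -> pos or None
    peak_bound_unresponsive: dict = field(default_factory=dict)
    peak_signal_cluster: dict = field(default_factory=dict)  # peak -> tall/short
    gene_scenario: dict = field(default_factory=dict)
    gene_binding_mode: dict = field(default_factory=dict)
    gene_fold: dict = field(default_factory=dict)  # true EPO+/EPO- ratio
    gene_direction: dict = field(default_factory=dict)
    region_dynamics: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass
class HostPlan:
    gene_id: str
    peak_class: str  # the feature class planted at this gene's peak
    summit: int
    scenario: str  # direct / background (independent genes host no peak)


@dataclass
class Genome:
    config: SimulationConfig
    sequences: dict  # chrom -> bytearray of ACGT
    genes: list
    hosts: list  # HostPlan per gene-attached peak
    intergenic_summits: list  # (chrom, summit)
    chrom_names: list

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].decode()


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(bases[rng.integers(0, 4, size=length)].tobytes())


def _build_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, strand: str
) -> GeneModel:
    """A gene with a >=600 nt first/last exon, CDS inset 400/300 nt from the
    oriented ends, and introns >= 700 nt — guaranteeing plantable UTR, CDS
    and intron positions."""
    n_mid = int(rng.integers(0, 4))
    first = int(rng.integers(600, 901))
    last = int(rng.integers(600, 901))
    mids = [int(rng.integers(250, 401)) for _ in range(n_mid)]
    introns = [int(rng.integers(700, 1501)) for _ in range(n_mid + 1)]
    segments: list[tuple[str, int]] = [("exon", first)]
    for i, m in enumerate(mids):
        segments.append(("intron", introns[i]))
        segments.append(("exon", m))
    segments.append(("intron", introns[-1]))
    segments.append(("exon", last))
    body_len = sum(length for _, length in segments)
    # oriented exon offsets
    oriented_exons = []
    pos = 0
    for kind, length in segments:
        if kind == "exon":
            oriented_exons.append((pos, pos + length))
        pos += length
    cds_oriented = (400, body_len - 300)

    def to_abs(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return start + a, start + b
        return start + body_len - b, start + body_len - a

    body = GenomicInterval(chrom, start, start + body_len, strand)
    exons = tuple(
        GenomicInterval(chrom, *to_abs(a, b), strand)
        for a, b in sorted(oriented_exons, key=lambda e: to_abs(*e))
    )
    cds = GenomicInterval(chrom, *to_abs(*cds_oriented), strand)
    return GeneModel(gene_id, strand, body, exons, cds)


def _oriented_to_abs(gene: GeneModel, offset: int) -> int:
    """Absolute position of an oriented offset from the TSS (0 = TSS)."""
    if gene.strand == "+":
        return gene.body.start + offset
    return gene.body.end - 1 - offset


def _plant_summit(rng: np.random.Generator, gene: GeneModel, peak_class: str) -> int:
    """A summit position realising ``peak_class`` at this host gene."""
    body_len = len(gene.body)
    first_exon_len = None
    # oriented first-exon length (the exon containing the TSS)
    for exon in gene.exons:
        if exon.contains(gene.tss):
            first_exon_len = len(exon)
            break
    assert first_exon_len is not None and first_exon_len >= 600
    if peak_class == "promoter":
        d = int(rng.integers(-1000, 101))  # inclusive window boundaries
        return _oriented_to_abs(gene, d)
    if peak_class == "UTR":
        # exonic (first exon), upstream of the CDS inset at +400,
        # beyond the +100 promoter edge
        return _oriented_to_abs(gene, int(rng.integers(150, 351)))
    if peak_class == "CDS":
        hi = min(first_exon_len - 20, 560)
        return _oriented_to_abs(gene, int(rng.integers(430, hi + 1)))
    if peak_class == "intron":
        # the first oriented intron starts right after the first exon and
        # is >= 700 nt by construction
        intron_start = first_exon_len
        return _oriented_to_abs(gene, int(rng.integers(intron_start + 200, intron_start + 500)))
    if peak_class == "distal":
        # downstream (absolute right) of the body; reserve handled by layout
        return gene.body.end + int(rng.integers(1100, 12001))
    raise ValueError(f"cannot plant class {peak_class!r} at a gene")


def generate_genome(config: SimulationConfig) -> Genome:
    """Lay out chromosomes, genes and planted summit positions.

    Gene bodies are pairwise disjoint; packing that exceeds a chromosome
    raises.  Returns sequences (i.i.d. uniform ACGT), gene models and the
    placement plan consumed by :func:`generate_peak_sets`.
    """
    rng = np.random.default_rng([1, config.seed])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {
        chrom: _random_sequence(rng, config.chrom_length) for chrom in chrom_names
    }
    if config.n_genes == 0:
        if config.n_peaks:
            raise ValueError("peaks without genes are not supported")
        return Genome(config, sequences, [], [], [], chrom_names)

    classes: list[str] = []
    for cls, count in config.feature_class_counts.items():
        if cls != "intergenic":
            classes.extend([cls] * count)
    rng.shuffle(classes)
    n_hosts = len(classes)
    if config.n_unresponsive_hosts > n_hosts:
        raise ValueError("more unresponsive hosts than gene-attached peaks")
    n_filler = config.n_genes - n_hosts - config.n_independent
    if n_filler < 0:
        raise ValueError(
            f"n_genes={config.n_genes} too small for "
            f"{n_hosts} hosts + {config.n_independent} independent genes"
        )

    mixed_chroms = chrom_names[:-2]
    quiet_chrom = chrom_names[-2]
    desert_chrom = chrom_names[-1]

    n_mixed_hosts = n_hosts - config.n_unresponsive_hosts
    direct_idx = set(
        rng.choice(n_mixed_hosts, size=config.n_direct_induced + config.n_direct_repressed, replace=False).tolist()
    ) if n_mixed_hosts else set()

    genes: list[GeneModel] = []
    hosts: list[HostPlan] = []
    gene_counter = 0

    def next_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"gene{gene_counter:04d}"

    # ---- mixed chromosomes: hosts with planted peaks -------------------
    per_chrom = -(-n_mixed_hosts // max(1, len(mixed_chroms)))  # ceil split
    host_i = 0
    for chrom in mixed_chroms:
        cursor = 2000
        for _ in range(min(per_chrom, n_mixed_hosts - host_i)):
            cls = classes[host_i]
            cursor += int(rng.integers(4000, 6001))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _build_gene(rng, next_gene_id(), chrom, cursor, strand)
            cursor = gene.body.end
            summit = _plant_summit(rng, gene, cls)
            if cls == "distal":
                cursor = summit + 1500
            if cursor > config.chrom_length - 3000:
                raise ValueError(
                    f"infeasible packing: {chrom} exceeded at gene {gene.gene_id}"
                )
            scenario = "direct" if host_i in direct_idx else "background"
            genes.append(gene)
            hosts.append(HostPlan(gene.gene_id, cls, summit, scenario))
            host_i += 1

    # ---- quiet chromosome: independent DEGs + filler, no peaks ---------
    cursor = 2000
    for k in range(config.n_independent + n_filler):
        cursor += int(rng.integers(4000, 6001))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene(rng, next_gene_id(), quiet_chrom, cursor, strand)
        cursor = gene.body.end
        if cursor > config.chrom_length - 3000:
            raise ValueError(f"infeasible packing: {quiet_chrom} exceeded")
        genes.append(gene)
        if k < config.n_independent:
            hosts.append(HostPlan(gene.gene_id, "none", -1, "independent"))

    # ---- desert chromosome: unresponsive hosts + intergenic desert -----
    cursor = 2000
    for j in range(config.n_unresponsive_hosts):
        cls = classes[n_mixed_hosts + j]
        cursor += int(rng.integers(4000, 6001))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene(rng, next_gene_id(), desert_chrom, cursor, strand)
        cursor = gene.body.end
        summit = _plant_summit(rng, gene, cls)
        if cls == "distal":
            cursor = summit + 1500
        genes.append(gene)
        hosts.append(HostPlan(gene.gene_id, cls, summit, "background"))
    desert_start = cursor + 51_000
    intergenic_summits = []
    pos = desert_start
    for _ in range(config.feature_class_counts.get("intergenic", 0)):
        intergenic_summits.append((desert_chrom, pos))
        pos += 3000
    if pos > config.chrom_length - 2000:
        raise ValueError("infeasible packing: desert exceeds chromosome")

    return Genome(config, sequences, genes, hosts, intergenic_summits, chrom_names)


# ---------------------------------------------------------------------------
# Peaks, motifs and flanks
# ---------------------------------------------------------------------------


def _realise_consensus(rng: np.random.Generator, pattern: str) -> str:
    """A concrete ACGT word drawn uniformly from a degenerate pattern."""
    out = []
    for sym in pattern:
        choices = [b for b in IUPAC[sym] if b != "N"] or list("ACGT")
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def generate_peak_sets(
    config: SimulationConfig, genome: Genome
) -> tuple[dict, dict, PlantedTruth]:
    """Reference peaks plus partially co-occupied factor sets and flanks.

    Returns (peak sets by factor, summit-centred flank sequences by peak
    name, planted truth).  GAS 9-mers are written into the genome at the
    summit for ``central_motif_rate`` of the reference peaks.
    """
    rng = np.random.default_rng([2, config.seed])
    truth = PlantedTruth()
    gene_by_id = {g.gene_id: g for g in genome.genes}

    ref_specs: list[tuple[str, int, str, str | None]] = []  # chrom, summit, class, host gene
    for host in genome.hosts:
        if host.peak_class == "none":
            continue
        chrom = gene_by_id[host.gene_id].chrom
        ref_specs.append((chrom, host.summit, host.peak_class, host.gene_id))
    for chrom, summit in genome.intergenic_summits:
        ref_specs.append((chrom, summit, "intergenic", None))
    assert len(ref_specs) == config.n_peaks

    half = config.peak_half_width
    lo_f, hi_f = config.fold_enrichment_range
    reference: list[Peak] = []
    for i, (chrom, summit, cls, _) in enumerate(ref_specs):
        name = f"{REFERENCE_FACTOR}_{i + 1:04d}"
        fold = float(np.exp(rng.uniform(np.log(lo_f), np.log(hi_f))))
        qvalue = float(10.0 ** -rng.uniform(2.0, 10.0))
        interval = GenomicInterval(chrom, summit - half, summit + half + 1, ".")
        reference.append(Peak(interval, summit, round(fold, 2), qvalue, name))
        truth.peak_class[name] = cls
        truth.peak_partners[name] = []

    # plant central GAS elements
    n_motif = int(round(config.central_motif_rate * len(reference)))
    motif_idx = set(
        rng.choice(len(reference), size=n_motif, replace=False).tolist()
    ) if n_motif else set()
    for i, peak in enumerate(reference):
        if i in motif_idx:
            site = _realise_consensus(rng, GAS_CONSENSUS)
            seq = genome.sequences[peak.chrom]
            start = peak.summit - (len(site) - 1) // 2
            seq[start : start + len(site)] = site.encode()
            truth.peak_motif_centre[peak.name] = peak.summit
        else:
            truth.peak_motif_centre[peak.name] = None

    # co-occupied partners and decoys per factor
    peak_sets: dict[str, list[Peak]] = {REFERENCE_FACTOR: reference}
    ref_summits = {(p.chrom, p.summit) for p in reference}
    desert_chrom = genome.chrom_names[-1]
    decoy_base = (
        max(
            [s for c, s in genome.intergenic_summits if c == desert_chrom],
            default=config.chrom_length // 2,
        )
        + 8000
    )
    for f_i, (factor, fraction) in enumerate(sorted(config.cooccupancy_fractions.items())):
        n_partner = int(round(fraction * len(reference)))
        partner_idx = rng.choice(len(reference), size=n_partner, replace=False)
        peaks: list[Peak] = []
        for k, idx in enumerate(sorted(partner_idx.tolist())):
            ref = reference[idx]
            offset = int(rng.integers(-config.cooccupancy_max_offset,
                                      config.cooccupancy_max_offset + 1))
            summit = ref.summit + offset
            interval = GenomicInterval(ref.chrom, summit - half, summit + half + 1, ".")
            peaks.append(
                Peak(interval, summit, round(float(rng.uniform(5, 25)), 2), 1e-4,
                     f"{factor}_{k + 1:04d}")
            )
            truth.peak_partners[ref.name].append(factor)
        # decoys: far (>= decoy_min_distance) from every reference summit
        pos = decoy_base + f_i * 1500
        for k in range(config.n_decoys_per_factor):
            pos += 3000
            if pos > config.chrom_length - 2000:
                raise ValueError("infeasible packing: decoy region exceeds chromosome")
            assert all(
                c != desert_chrom or abs(s - pos) >= config.decoy_min_distance
                for c, s in ref_summits
            )
            interval = GenomicInterval(desert_chrom, pos - half, pos + half + 1, ".")
            peaks.append(
                Peak(interval, pos, round(float(rng.uniform(5, 25)), 2), 1e-3,
                     f"{factor}_decoy_{k + 1:04d}")
            )
        peak_sets[factor] = peaks

    flanks = {
        p.name: genome.sequences[p.chrom][
            p.summit - config.flank : p.summit + config.flank + 1
        ].decode()
        for p in reference
    }
    return peak_sets, flanks, truth


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


def _track_from_triangles(
    chrom_length: int,
    chrom_names: list,
    triangles: dict,  # chrom -> list of (summit, height)
    half_width: int,
    floor: float,
) -> SignalTrack:
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chrom_names:
        tri = sorted(triangles.get(chrom, []))
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        values: list[np.ndarray] = []
        cursor = 0
        for summit, height in tri:
            a = max(0, summit - half_width)
            b = min(chrom_length, summit + half_width + 1)
            if floor > 0 and a > cursor:
                starts.append(np.array([cursor]))
                ends.append(np.array([a]))
                values.append(np.array([floor]))
            pos = np.arange(a, b)
            starts.append(pos)
            ends.append(pos + 1)
            values.append(floor + height * (1.0 - np.abs(pos - summit) / half_width))
            cursor = b
        if floor > 0 and cursor < chrom_length:
            starts.append(np.array([cursor]))
            ends.append(np.array([chrom_length]))
            values.append(np.array([floor]))
        if starts:
            steps[chrom] = (
                np.concatenate(starts),
                np.concatenate(ends),
                np.concatenate(values),
            )
    return SignalTrack(steps)


def generate_signal_tracks(
    config: SimulationConfig, genome: Genome, peak_sets: dict, truth: PlantedTruth
) -> dict:
    """Triangular-peak bedGraph-style tracks over a flat noise floor.

    The reference track carries two planted row clusters (tall and short
    triangles, recorded in the truth) so heatmap clustering has known
    structure to recover.
    """
    rng = np.random.default_rng([3, config.seed])
    tracks: dict[str, SignalTrack] = {}
    reference = peak_sets[REFERENCE_FACTOR]
    n_tall = int(round(config.tall_fraction * len(reference)))
    tall_idx = set(rng.choice(len(reference), size=n_tall, replace=False).tolist())
    triangles: dict[str, list] = {}
    for i, peak in enumerate(reference):
        tall = i in tall_idx
        truth.peak_signal_cluster[peak.name] = "tall" if tall else "short"
        height = config.tall_height if tall else config.short_height
        triangles.setdefault(peak.chrom, []).append((peak.summit, height))
    tracks[REFERENCE_FACTOR] = _track_from_triangles(
        config.chrom_length, genome.chrom_names, triangles,
        config.triangle_half_width, config.noise_floor,
    )
    for factor, peaks in peak_sets.items():
        if factor == REFERENCE_FACTOR:
            continue
        triangles = {}
        for peak in peaks:
            triangles.setdefault(peak.chrom, []).append(
                (peak.summit, config.partner_height)
            )
        tracks[factor] = _track_from_triangles(
            config.chrom_length, genome.chrom_names, triangles,
            config.triangle_half_width, config.noise_floor,
        )
    return tracks


# ---------------------------------------------------------------------------
# Counts and CAGE
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_count_table(
    config: SimulationConfig,
    genome: Genome,
    truth: PlantedTruth,
) -> CountTable:
    """Replicated EPO+/EPO- counts with planted fold changes.

    Baseline means are log-uniform over ``count_mean_range``; planted
    DEGs get their condition mean multiplied (induced) or divided
    (repressed) by a fold drawn log-uniform over ``fold_range``; counts
    follow a negative-binomial noise model with the configured
    dispersion, scaled by per-library size factors.
    """
    rng = np.random.default_rng([4, config.seed])
    genes = genome.genes
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series(
        {g.gene_id: sum(len(e) for e in g.exons) for g in genes}
    )

    # planted DEG assignment: direct genes from the layout, independent
    # genes from the quiet chromosome, split induced/repressed
    direct = [h.gene_id for h in genome.hosts if h.scenario == "direct"]
    independent = [h.gene_id for h in genome.hosts if h.scenario == "independent"]
    rng.shuffle(direct)
    rng.shuffle(independent)
    induced = direct[: config.n_direct_induced] + independent[
        : config.n_induced - config.n_direct_induced
    ]
    repressed = (
        direct[config.n_direct_induced :]
        + independent[config.n_induced - config.n_direct_induced :]
    )
    host_by_gene = {h.gene_id: h for h in genome.hosts}
    for g in gene_ids:
        plan = host_by_gene.get(g)
        scenario = plan.scenario if plan else "background"
        truth.gene_scenario[g] = scenario
        truth.gene_direction[g] = "unchanged"
        truth.gene_fold[g] = 1.0
        if scenario == "direct":
            truth.gene_binding_mode[g] = (
                "promoter_bound" if plan.peak_class == "promoter" else "enhancer_bound"
            )
        else:
            truth.gene_binding_mode[g] = "none"
    lo, hi = config.fold_range
    for g in induced:
        truth.gene_direction[g] = "induced"
        truth.gene_fold[g] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    for g in repressed:
        truth.gene_direction[g] = "repressed"
        truth.gene_fold[g] = float(1.0 / np.exp(rng.uniform(np.log(lo), np.log(hi))))

    m_lo, m_hi = config.count_mean_range
    base = np.exp(rng.uniform(np.log(m_lo), np.log(m_hi), size=len(gene_ids)))
    fold = np.array([truth.gene_fold[g] for g in gene_ids])
    mean_minus = base
    mean_plus = base * fold

    samples = [f"EPO+_rep{i + 1}" for i in range(config.n_replicates)] + [
        f"EPO-_rep{i + 1}" for i in range(config.n_replicates)
    ]
    lib = np.asarray(config.library_size_factors, dtype=float)
    data = {}
    for j, sample in enumerate(samples):
        mean = (mean_plus if sample.startswith("EPO+") else mean_minus) * lib[j]
        data[sample] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), dtype=np.int64)
    conditions = pd.Series(
        {s: ("EPO+" if s.startswith("EPO+") else "EPO-") for s in samples}
    )
    replicates = pd.Series({s: int(s.rsplit("rep", 1)[1]) for s in samples})
    return CountTable(counts, conditions, lengths, replicates)


def generate_cage_series(
    config: SimulationConfig, truth: PlantedTruth
) -> CageExperiment:
    """CAGE tag-count time courses with planted dynamics classes.

    Responsive regions follow a log-time bump peaking at 30-60 min
    (immediate) or 120-240 min (delayed) with amplitude drawn from
    ``cage_amplitude_range``; unresponsive regions are flat.  Counts are
    Poisson draws around the profile with multiplicative (log-normal)
    noise and per-library depth factors that RLE normalisation removes.
    """
    rng = np.random.default_rng([5, config.seed])
    times = np.asarray(config.cage_times, dtype=float)
    libraries = [
        f"t{int(t)}_rep{r + 1}"
        for t in times
        for r in range(config.cage_replicates)
    ]
    lib_times = pd.Series(
        {lib: float(lib.split("_")[0][1:]) for lib in libraries}
    )
    lib_reps = pd.Series({lib: int(lib.rsplit("rep", 1)[1]) for lib in libraries})
    depth = np.exp(rng.normal(0.0, 0.2, size=len(libraries)))

    peak_times = {"immediate": (30.0, 60.0), "delayed": (120.0, 240.0)}
    rows = []
    region_ids = []
    counter = 0
    a_lo, a_hi = config.cage_amplitude_range
    region_spec = dict(config.cage_region_counts)
    region_spec["unresponsive"] = (
        region_spec.get("unresponsive", 0) + config.cage_background_regions
    )
    for dyn_class, count in region_spec.items():
        for _ in range(count):
            counter += 1
            region = f"region{counter:03d}"
            region_ids.append(region)
            truth.region_dynamics[region] = dyn_class
            base = config.cage_base_count * float(np.exp(rng.uniform(-0.5, 0.5)))
            if dyn_class == "unresponsive":
                profile = np.full(len(times), base)
            else:
                pt = float(rng.choice(peak_times[dyn_class]))
                amp = float(rng.uniform(a_lo, a_hi))
                g = np.zeros(len(times))
                nonzero = times > 0
                g[nonzero] = np.exp(
                    -(np.log(times[nonzero] / pt) ** 2)
                    / (2 * config.cage_profile_width**2)
                )
                profile = base * (1.0 + (amp - 1.0) * g)
            means = np.repeat(profile, config.cage_replicates) * depth
            noise = np.exp(rng.normal(0.0, config.cage_noise_sd, size=len(means)))
            rows.append(rng.poisson(means * noise))
    counts = pd.DataFrame(rows, index=pd.Index(region_ids, name="region_id"), columns=libraries)
    return CageExperiment(counts, lib_times, lib_reps)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome
    peak_sets: dict
    flanks: dict
    tracks: dict
    counts: CountTable
    cage: CageExperiment
    truth: PlantedTruth

    def write(self, outdir: str | Path) -> dict:
        """Emit all artifacts as plain-text files; returns {label: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fasta = {c: self.genome.sequence_str(c) for c in self.genome.chrom_names}
        write_fasta(fasta, outdir / "genome.fa")
        paths["genome"] = outdir / "genome.fa"
        write_gene_models(self.genome.genes, outdir / "genes.gtf")
        paths["gtf"] = outdir / "genes.gtf"
        for factor, peaks in self.peak_sets.items():
            p = outdir / f"{factor}.narrowPeak"
            write_peaks(peaks, p)
            paths[f"peaks_{factor}"] = p
        write_fasta(self.flanks, outdir / "peaks_flank.fa")
        paths["flanks"] = outdir / "peaks_flank.fa"
        for factor, track in self.tracks.items():
            p = outdir / f"{factor}.bedGraph"
            write_signal(track, p)
            paths[f"track_{factor}"] = p
        write_counts(self.counts, outdir / "counts.tsv", outdir / "design.tsv")
        paths["counts"] = outdir / "counts.tsv"
        paths["design"] = outdir / "design.tsv"
        cage = self.cage.counts.copy()
        cage.to_csv(outdir / "cage.tsv", sep="\t")
        meta = pd.DataFrame(
            {"time_min": self.cage.times, "replicate": self.cage.replicates}
        )
        meta.index.name = "library"
        meta.to_csv(outdir / "cage_design.tsv", sep="\t")
        paths["cage"] = outdir / "cage.tsv"
        self.truth.to_json(outdir / "truth.json")
        paths["truth"] = outdir / "truth.json"
        return paths


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage; a pure function of the config (incl. seed)."""
    genome = generate_genome(config)
    peak_sets, flanks, truth = generate_peak_sets(config, genome)
    tracks = generate_signal_tracks(config, genome, peak_sets, truth)
    counts = generate_count_table(config, genome, truth)
    cage = generate_cage_series(config, truth)
    # planted bound-unresponsive flags: no planted-DEG TSS within the
    # default linkage window of the summit (plain loop, kept independent
    # of the classification module's implementation)
    deg_tss = [
        (g.chrom, g.tss)
        for g in genome.genes
        if truth.gene_direction[g.gene_id] != "unchanged"
    ]
    for peak in peak_sets[REFERENCE_FACTOR]:
        near_deg = any(
            chrom == peak.chrom and abs(tss - peak.summit) <= 100_000
            for chrom, tss in deg_tss
        )
        truth.peak_bound_unresponsive[peak.name] = not near_deg
    return SyntheticDataset(config, genome, peak_sets, flanks, tracks, counts, cage, truth)
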