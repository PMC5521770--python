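"""Readers, writers and core genomic types shared by every pipeline stage.

All coordinates are 0-based half-open internally.  GTF (1-based inclusive)
is converted at the reader boundary; BED-family formats (narrowPeak,
bedGraph, BED6+summit) are taken as-is.  Chromosome names are matched by
exact string comparison — no "chr" aliasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class ValidationError(ValueError):
    """An input violated a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP peak with its summit (the best single-base binding estimate)."""

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    qvalue: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for peak {self.name}"
            )
        if self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be >= 0")
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValidationError("qvalue must lie in [0, 1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A gene body with TSS, exon structure and optional CDS span.

    The TSS equals ``body.start`` on the + strand and ``body.end - 1`` on
    the - strand; exons are sorted, non-overlapping and contained in the
    body.
    """

    gene_id: str
    strand: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = -1
        for exon in self.exons:
            if exon.start < self.body.start or exon.end > self.body.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{exon.start}, {exon.end}) "
                    f"outside body [{self.body.start}, {self.body.end})"
                )
            if exon.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end
        if self.cds is not None and (
            self.cds.start < self.body.start or self.cds.end > self.body.end
        ):
            raise ValidationError(f"gene {self.gene_id}: CDS outside body")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom


class SignalTrack:
    """A per-base step function (bedGraph semantics) per chromosome.

    ``total_reads`` is the library size used for per-million normalisation;
    by default it is the coverage sum (value x span) over all steps.
    """

    def __init__(
        self,
        steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: float | None = None,
    ) -> None:
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        coverage = 0.0
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged step arrays")
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: zero/negative-length step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping or unsorted steps")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValidationError(f"{chrom}: step values must be finite and >= 0")
            self.steps[chrom] = (starts, ends, values)
            areas = values * (ends - starts)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(areas)])
            coverage += float(areas.sum())
        self.total_reads = float(coverage if total_reads is None else total_reads)

    def _integral_to(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the step function over (-inf, pos)."""
        if chrom not in self.steps:
            return np.zeros_like(pos, dtype=float)
        starts, ends, values = self.steps[chrom]
        cum = self._cum[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        out = np.zeros(len(pos), dtype=float)
        has = idx >= 0
        i = idx[has]
        inside = pos[has] < ends[i]
        partial = np.where(
            inside,
            values[i] * (pos[has] - starts[i]),
            values[i] * (ends[i] - starts[i]),
        )
        out[has] = cum[i] + partial
        return out

    def mean_per_base(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over [start, end); positions without a step count 0."""
        if end <= start:
            raise ValidationError("end must exceed start")
        pts = np.array([start, end], dtype=np.int64)
        f = self._integral_to(chrom, pts)
        return float((f[1] - f[0]) / (end - start))

    def bin_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean per-base value in ``n_bins`` equal bins across [start, end)."""
        if (end - start) % n_bins != 0:
            raise ValidationError("window length must be divisible by n_bins")
        width = (end - start) // n_bins
        edges = start + np.arange(n_bins + 1, dtype=np.int64) * width
        f = self._integral_to(chrom, edges)
        return np.diff(f) / width


@dataclass
class CountTable:
    """Gene x sample integer counts with condition labels and gene lengths."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    conditions: pd.Series  # sample -> condition label (e.g. EPO+/EPO-)
    gene_lengths: pd.Series  # gene -> length in nt
    replicates: pd.Series = field(default=None)  # sample -> replicate index

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts contain negative entries")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValidationError(f"samples without condition label: {sorted(missing)}")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValidationError("every gene needs a positive length")
        self.gene_lengths = lengths
        if self.replicates is None:
            reps = {}
            for cond in self.conditions.unique():
                for i, s in enumerate(
                    self.conditions.index[self.conditions == cond], start=1
                ):
                    reps[s] = i
            self.replicates = pd.Series(reps)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# Peak files
# ---------------------------------------------------------------------------

PEAK_FORMATS = ("narrowPeak", "bed6summit")


def _summit_from_offset(start: int, end: int, offset: int) -> int:
    # ENCODE convention: offset -1 means "no summit estimate".
    if offset == -1:
        return (start + end) // 2
    if offset < -1:
        raise ValidationError(f"invalid summit offset {offset}")
    return start + offset


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a narrowPeak (10 columns) or BED6+summit (7 columns) file.

    Column 10 (narrowPeak) / column 7 (bed6summit) is the summit offset from
    ``start``; -1 maps to the interval midpoint.  narrowPeak column 7 is the
    fold enrichment over input and column 9 a -log10 q-value, converted to a
    plain q-value.
    """
    if format not in PEAK_FORMATS:
        raise ValueError(f"format must be one of {PEAK_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_cols = 10 if format == "narrowPeak" else 7
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in STRANDS else "."
                if format == "narrowPeak":
                    fold = float(fields[6])
                    neglog_q = float(fields[8])
                    qvalue = 1.0 if neglog_q < 0 else min(1.0, 10.0 ** (-neglog_q))
                    offset = int(fields[9])
                else:
                    fold = float(fields[4])
                    qvalue = 1.0
                    offset = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            summit = _summit_from_offset(start, end, offset)
            interval = GenomicInterval(chrom, start, end, strand)
            if not interval.contains(summit):
                raise ValidationError(
                    f"{path}:{lineno}: summit {summit} outside [{start}, {end})"
                )
            peaks.append(Peak(interval, summit, fold, qvalue, name))
    if not peaks:
        logger.warning("no peaks read from %s", path)
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks; inverse of :func:`read_peaks` for coordinates and summits."""
    if format not in PEAK_FORMATS:
        raise ValueError(f"format must be one of {PEAK_FORMATS}")
    path = Path(path)
    with open(path, "w") as handle:
        for peak in peaks:
            iv = peak.interval
            offset = peak.summit - iv.start
            if format == "narrowPeak":
                neglog_q = (
                    -1.0
                    if peak.qvalue >= 1.0
                    else (999.0 if peak.qvalue <= 0 else -math.log10(peak.qvalue))
                )
                fields = [
                    iv.chrom, iv.start, iv.end, peak.name, 0, iv.strand,
                    f"{peak.fold_enrichment:g}", -1, f"{neglog_q:g}", offset,
                ]
            else:
                fields = [
                    iv.chrom, iv.start, iv.end, peak.name,
                    f"{peak.fold_enrichment:g}", iv.strand, offset,
                ]
            handle.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon/CDS features, 1-based inclusive).

    Coordinates are converted to 0-based half-open.  Exons are merged per
    gene; a gene without exon records falls back to its body as a single
    exon (with a warning).  Records with unknown strand are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_text = fields
            if feature not in ("gene", "exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: skipping %s record with strand %r", path, lineno, feature, strand
                )
                continue
            try:
                start = int(start1) - 1  # GTF 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attrs = _parse_gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            rec = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "body": None, "exons": [], "cds": []},
            )
            if gene_id not in order:
                order.append(gene_id)
            if feature == "gene":
                rec["body"] = (start, end)
            elif feature == "exon":
                rec["exons"].append((start, end))
            else:
                rec["cds"].append((start, end))
    models: list[GeneModel] = []
    for gene_id in order:
        rec = genes[gene_id]
        chrom, strand = rec["chrom"], rec["strand"]
        if rec["body"] is None:
            if not rec["exons"]:
                logger.warning("gene %s has no gene or exon records; skipped", gene_id)
                continue
            lo = min(s for s, _ in rec["exons"])
            hi = max(e for _, e in rec["exons"])
            rec["body"] = (lo, hi)
        body = GenomicInterval(chrom, *rec["body"], strand)
        exon_pairs = sorted(rec["exons"])
        if not exon_pairs:
            logger.warning("gene %s has no exons; using body as a single exon", gene_id)
            exon_pairs = [(body.start, body.end)]
        merged: list[tuple[int, int]] = []
        for s, e in exon_pairs:
            if s < body.start or e > body.end:
                raise ValidationError(
                    f"gene {gene_id}: exon [{s}, {e}) outside declared span "
                    f"[{body.start}, {body.end})"
                )
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)
        cds = None
        if rec["cds"]:
            cds = GenomicInterval(
                chrom,
                min(s for s, _ in rec["cds"]),
                max(e for _, e in rec["cds"]),
                strand,
            )
        models.append(GeneModel(gene_id, strand, body, exons, cds))
    return models


def write_gene_models(genes: list[GeneModel], path: str | Path, source: str = "stat5targets") -> None:
    """Write gene models as GTF (1-based inclusive on output)."""
    with open(path, "w") as handle:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}";'
            rows = [("gene", gene.body)]
            rows += [("exon", exon) for exon in gene.exons]
            if gene.cds is not None:
                rows.append(("CDS", gene.cds))
            for feature, iv in rows:
                handle.write(
                    "\t".join(
                        [
                            gene.chrom, source, feature,
                            str(iv.start + 1), str(iv.end), ".", gene.strand, ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Signal, sequence and count tables
# ---------------------------------------------------------------------------


def read_signal(path: str | Path, total_reads: float | None = None) -> SignalTrack:
    """Read a bedGraph file (0-based half-open) into a :class:`SignalTrack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        steps[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(float),
        )
    return SignalTrack(steps, total_reads=total_reads)


def write_signal(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(track.steps):
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                handle.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercased sequence}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountTable:
    """Read a counts TSV (gene_id, length, one column per sample) plus a
    design TSV (sample, condition[, replicate])."""
    counts_path, design_path = Path(counts_path), Path(design_path)
    for p in (counts_path, design_path):
        if not p.exists():
            raise FileNotFoundError(p)
    df = pd.read_csv(counts_path, sep="\t")
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ParseError(f"{counts_path}: needs a header with gene_id and length columns")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"duplicate gene ids in {counts_path}: {list(dups)[:5]}")
    df = df.set_index("gene_id")
    lengths = df.pop("length")
    if (df.values < 0).any():
        raise ValidationError(f"{counts_path}: negative count entries")
    design = pd.read_csv(design_path, sep="\t")
    if "sample" not in design.columns or "condition" not in design.columns:
        raise ParseError(f"{design_path}: needs sample and condition columns")
    design = design.set_index("sample")
    reps = design["replicate"] if "replicate" in design.columns else None
    return CountTable(
        counts=df.astype(np.int64),
        conditions=design["condition"],
        gene_lengths=lengths,
        replicates=reps,
    )


def write_counts(table: CountTable, counts_path: str | Path, design_path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    design = pd.DataFrame(
        {"condition": table.conditions, "replicate": table.replicates}
    )
    design.index.name = "sample"
    design.to_csv(design_path, sep="\t")
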