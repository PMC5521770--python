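"""Nearest-TSS annotation and genomic feature classification of ChIP peaks.

Classification is by summit position.  A summit is a *promoter* hit if its
gene-oriented distance to **any** TSS falls in the promoter window
(default 1 kb upstream to 100 nt downstream, boundaries inclusive);
otherwise a summit inside a gene body is UTR / CDS / intron depending on
exon and CDS-span membership; otherwise it is *distal* when within the
distal limit (default 50 kb) of any gene-body edge, else *intergenic*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genomics_io import GeneModel, Peak

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("promoter", "UTR", "CDS", "intron", "distal", "intergenic")

DEFAULT_PROMOTER_WINDOW = (-1000, 100)
DEFAULT_DISTAL_LIMIT = 50_000


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    nearest_gene: str | None
    distance_to_tss: int | None  # signed, gene-oriented; negative = upstream
    feature: str
    hosting_gene: str | None = None  # gene whose body contains the summit

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature!r}")


def tss_distance(summit: int, gene: GeneModel) -> int:
    """Signed gene-oriented distance from TSS to summit.

    Positive values are downstream of the TSS in the direction of
    transcription, negative values upstream.
    """
    if gene.strand == "+":
        return summit - gene.tss
    return gene.tss - summit


def nearest_tss(
    chrom: str, summit: int, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Return (gene_id, signed distance) of the nearest TSS on ``chrom``.

    Ties on |distance| go to the lexicographically smallest gene_id (and
    are logged).  With no gene on the chromosome returns (None, None).
    """
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, d)
    tied = False
    for gene in genes:
        if gene.chrom != chrom:
            continue
        d = tss_distance(summit, gene)
        key = (abs(d), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            tied = best is not None and abs(d) == best[0]
            best = (abs(d), gene.gene_id, d)
        elif abs(d) == best[0]:
            tied = True
    if best is None:
        logger.warning("no gene on chromosome %s for summit %d", chrom, summit)
        return None, None
    if tied:
        logger.info(
            "nearest-TSS tie at %s:%d resolved to %s", chrom, summit, best[1]
        )
    return best[1], best[2]


def classify_feature(
    chrom: str,
    summit: int,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    distal_limit: int = DEFAULT_DISTAL_LIMIT,
) -> tuple[str, str | None]:
    """Classify a summit; returns (feature_class, hosting_gene_id).

    Precedence: promoter (window around any TSS) > gene-body membership
    (UTR/CDS/intron) > distal (within ``distal_limit`` of any body edge)
    > intergenic.
    """
    lo, hi = promoter_window
    chrom_genes = [g for g in genes if g.chrom == chrom]
    for gene in chrom_genes:
        if lo <= tss_distance(summit, gene) <= hi:
            return "promoter", _host(summit, chrom_genes)
    host = _host(summit, chrom_genes)
    if host is not None:
        gene = next(g for g in chrom_genes if g.gene_id == host)
        in_exon = any(e.contains(summit) for e in gene.exons)
        if in_exon:
            if gene.cds is not None and gene.cds.contains(summit):
                return "CDS", host
            return "UTR", host
        return "intron", host
    near = any(
        _gap_to_body(summit, g) <= distal_limit for g in chrom_genes
    )
    return ("distal" if near else "intergenic"), None


def _host(summit: int, chrom_genes: list[GeneModel]) -> str | None:
    """Gene whose body contains the summit; nearest TSS wins ties."""
    hosts = [g for g in chrom_genes if g.body.contains(summit)]
    if not hosts:
        return None
    hosts.sort(key=lambda g: (abs(tss_distance(summit, g)), g.gene_id))
    return hosts[0].gene_id


def _gap_to_body(summit: int, gene: GeneModel) -> int:
    if gene.body.contains(summit):
        return 0
    if summit < gene.body.start:
        return gene.body.start - summit
    return summit - gene.body.end + 1


def annotate_peaks(
    peaks: list[Peak],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    distal_limit: int = DEFAULT_DISTAL_LIMIT,
) -> tuple[list[AnnotatedPeak], dict[str, float]]:
    """Annotate every peak and summarise class fractions.

    Returns (annotated peaks, {feature class: fraction}); fractions over
    the six classes sum to 1.
    """
    if not peaks:
        raise ValueError("annotate_peaks requires a non-empty peak list")
    annotated: list[AnnotatedPeak] = []
    counts = dict.fromkeys(FEATURE_CLASSES, 0)
    for peak in peaks:
        gene_id, dist = nearest_tss(peak.chrom, peak.summit, genes)
        feature, host = classify_feature(
            peak.chrom, peak.summit, genes, promoter_window, distal_limit
        )
        if gene_id is None:
            feature, host = "intergenic", None
        annotated.append(AnnotatedPeak(peak, gene_id, dist, feature, host))
        counts[feature] += 1
    fractions = {cls: counts[cls] / len(peaks) for cls in FEATURE_CLASSES}
    return annotated, fractions


def annotation_table(annotated: list[AnnotatedPeak]) -> pd.DataFrame:
    """Tabular form: peak_name, chrom, summit, nearest_gene, distance, feature."""
    return pd.DataFrame(
        {
            "peak_name": [a.peak.name for a in annotated],
            "chrom": [a.peak.chrom for a in annotated],
            "summit": [a.peak.summit for a in annotated],
            "nearest_gene": [a.nearest_gene for a in annotated],
            "distance_to_tss": [a.distance_to_tss for a in annotated],
            "feature": [a.feature for a in annotated],
            "hosting_gene": [a.hosting_gene for a in annotated],
        }
    )
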