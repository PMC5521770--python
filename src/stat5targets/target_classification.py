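"""Integration of DEG calls with annotated peaks into target scenarios.

Three scenarios for the stimulated transcriptome: a differentially
expressed gene with a peak within the linkage window of its TSS is a
likely *direct* target (promoter-bound when a linked peak sits in that
gene's promoter window, enhancer-bound otherwise); a DEG with no linked
peak is likely *independent* of the ChIPped factor; and every peak whose
linked genes are all unresponsive is reported *bound-unresponsive*.
Non-DEG genes form the *background*.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomics_io import GeneModel
from .peak_annotation import (
    DEFAULT_PROMOTER_WINDOW,
    AnnotatedPeak,
    tss_distance,
)

DEFAULT_LINK_WINDOW = 100_000

SCENARIOS = ("direct", "independent", "bound_unresponsive", "background")
BINDING_MODES = ("promoter_bound", "enhancer_bound", "none")


@dataclass(frozen=True)
class PeakGeneLink:
    peak_name: str
    gene_id: str
    distance: int  # signed, gene-oriented TSS -> summit distance
    is_promoter_of_gene: bool


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    scenario: str
    binding_mode: str
    closest_peak: str | None = None
    peak_distance: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.binding_mode not in BINDING_MODES:
            raise ValueError(f"unknown binding mode {self.binding_mode!r}")
        if self.scenario == "direct" and self.binding_mode == "none":
            raise ValueError("a direct target must have a binding mode")
        if self.scenario == "independent" and self.binding_mode != "none":
            raise ValueError("an independent DEG cannot carry a binding mode")


def link_peaks_to_tss(
    peaks: list[AnnotatedPeak],
    genes: list[GeneModel],
    window: int = DEFAULT_LINK_WINDOW,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> list[PeakGeneLink]:
    """Link every peak to every gene whose TSS lies within ``window`` nt
    of the summit (inclusive).  Links are not exclusive: one peak may
    link to several genes and one gene may collect several peaks.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = promoter_window
    links: list[PeakGeneLink] = []
    for ap in peaks:
        for gene in genes:
            if gene.chrom != ap.peak.chrom:
                continue
            d = tss_distance(ap.peak.summit, gene)
            if abs(d) <= window:
                links.append(
                    PeakGeneLink(
                        peak_name=ap.peak.name,
                        gene_id=gene.gene_id,
                        distance=d,
                        is_promoter_of_gene=lo <= d <= hi,
                    )
                )
    return links


def classify_target_genes(
    degs: pd.DataFrame,
    links: list[PeakGeneLink],
    genes: list[GeneModel],
    all_peak_names: list[str] | None = None,
) -> tuple[list[TargetCall], pd.DataFrame]:
    """Combine DEG calls and peak-gene links into scenario calls.

    ``degs`` is the table from :func:`~stat5targets.expression_response.call_degs`
    (indexed by gene, with a ``call`` column).  Returns (per-gene target
    calls, per-peak table with a bound_unresponsive flag).  Raises when
    the DEG table names genes absent from the gene models.
    """
    known = {g.gene_id for g in genes}
    offenders = sorted(set(degs.index) - known)
    if offenders:
        raise ValueError(
            f"DEG table contains {len(offenders)} gene ids absent from the gene "
            f"models, e.g. {offenders[:5]}"
        )
    by_gene: dict[str, list[PeakGeneLink]] = {}
    by_peak: dict[str, list[PeakGeneLink]] = {}
    for link in links:
        by_gene.setdefault(link.gene_id, []).append(link)
        by_peak.setdefault(link.peak_name, []).append(link)

    is_deg = degs["call"] != "unchanged"
    calls: list[TargetCall] = []
    for gene_id in degs.index:
        gene_links = by_gene.get(gene_id, [])
        closest = min(gene_links, key=lambda l: abs(l.distance), default=None)
        if gene_links:
            mode = (
                "promoter_bound"
                if any(l.is_promoter_of_gene for l in gene_links)
                else "enhancer_bound"
            )
        else:
            mode = "none"
        if is_deg[gene_id]:
            scenario = "direct" if gene_links else "independent"
        else:
            scenario = "background"
        calls.append(
            TargetCall(
                gene_id=gene_id,
                scenario=scenario,
                binding_mode=mode,
                closest_peak=closest.peak_name if closest else None,
                peak_distance=closest.distance if closest else None,
            )
        )

    deg_genes = set(degs.index[is_deg])
    peak_rows = []
    # a peak with no linked gene at all is trivially bound-unresponsive
    peak_names = (
        list(all_peak_names) if all_peak_names is not None else list(by_peak)
    )
    for peak_name in peak_names:
        linked = [l.gene_id for l in by_peak.get(peak_name, [])]
        unresponsive = all(g not in deg_genes for g in linked)
        peak_rows.append((peak_name, len(linked), unresponsive))
    peak_flags = pd.DataFrame(
        peak_rows, columns=["peak_name", "n_linked_genes", "bound_unresponsive"]
    ).set_index("peak_name")
    return calls, peak_flags


def summary_report(
    calls: list[TargetCall], peak_flags: pd.DataFrame | None = None
) -> dict[str, int]:
    """Scenario and binding-mode counts; scenario counts partition the genes."""
    out: dict[str, int] = {s: 0 for s in SCENARIOS if s != "bound_unresponsive"}
    modes = {m: 0 for m in BINDING_MODES}
    for call in calls:
        out[call.scenario] = out.get(call.scenario, 0) + 1
        if call.scenario == "direct":
            modes[call.binding_mode] += 1
    out["direct_promoter_bound"] = modes["promoter_bound"]
    out["direct_enhancer_bound"] = modes["enhancer_bound"]
    out["n_deg"] = out.get("direct", 0) + out.get("independent", 0)
    if peak_flags is not None:
        out["bound_unresponsive_peaks"] = int(peak_flags["bound_unresponsive"].sum())
    return out
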