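"""Peak-gene linkage windows and the three-scenario target classification."""

import numpy as np
import pandas as pd
import pytest

from stat5targets.peak_annotation import AnnotatedPeak, annotate_peaks
from stat5targets.target_classification import (
    TargetCall,
    classify_target_genes,
    link_peaks_to_tss,
    summary_report,
)

from conftest import make_gene, make_peak


def annotate(peaks, genes):
    return annotate_peaks(peaks, genes)[0]


def deg_frame(calls: dict) -> pd.DataFrame:
    df = pd.DataFrame(
        {"fold_change": 2.0, "mean_fpkm": 10.0, "p_value": 0.001, "fdr": 0.01,
         "call": pd.Series(calls)}
    )
    df.index.name = "gene_id"
    return df


class TestLinkPeaksToTss:
    def test_window_boundary_is_inclusive(self):
        genes = [make_gene("g", "chr1", 200_000, 210_000, "+")]
        for offset, linked in [(99_999, True), (100_000, True), (100_001, False)]:
            peaks = annotate([make_peak("chr1", 200_000 - offset)], genes)
            links = link_peaks_to_tss(peaks, genes, window=100_000)
            assert bool(links) is linked

    def test_one_peak_can_link_two_genes(self):
        genes = [
            make_gene("left", "chr1", 10_000, 20_000, "+"),
            make_gene("right", "chr1", 60_000, 70_000, "+"),
        ]
        peaks = annotate([make_peak("chr1", 40_000)], genes)
        links = link_peaks_to_tss(peaks, genes, window=100_000)
        assert sorted(l.gene_id for l in links) == ["left", "right"]

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            link_peaks_to_tss([], [], window=0)

    def test_signed_distance_carried_on_links(self):
        genes = [make_gene("g", "chr1", 10_000, 20_000, "-")]
        peaks = annotate([make_peak("chr1", 25_000)], genes)
        (link,) = link_peaks_to_tss(peaks, genes)
        assert link.distance == (20_000 - 1) - 25_000  # upstream of - strand TSS


class TestClassifyTargetGenes:
    GENES = [
        make_gene("cish_like", "chr1", 100_000, 110_000, "+"),
        make_gene("thbs1_like", "chr2", 500_000, 510_000, "+"),
        make_gene("cdk5_like", "chr1", 400_000, 410_000, "+"),
    ]

    def _links(self, peaks):
        annotated = annotate(peaks, self.GENES)
        return link_peaks_to_tss(annotated, self.GENES), annotated

    def test_promoter_bound_direct_target(self):
        # an induced gene with a peak just downstream of its own TSS
        links, ann = self._links([make_peak("chr1", 100_031, "peak1")])
        degs = deg_frame({"cish_like": "induced", "thbs1_like": "unchanged",
                          "cdk5_like": "unchanged"})
        calls, flags = classify_target_genes(degs, links, self.GENES,
                                             all_peak_names=["peak1"])
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["cish_like"].scenario == "direct"
        assert by_gene["cish_like"].binding_mode == "promoter_bound"
        assert by_gene["cish_like"].closest_peak == "peak1"
        assert not flags.loc["peak1", "bound_unresponsive"]

    def test_induced_gene_without_nearby_peak_is_independent(self):
        links, _ = self._links([make_peak("chr1", 100_031, "peak1")])
        degs = deg_frame({"cish_like": "unchanged", "thbs1_like": "induced",
                          "cdk5_like": "unchanged"})
        calls, _ = classify_target_genes(degs, links, self.GENES)
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["thbs1_like"].scenario == "independent"
        assert by_gene["thbs1_like"].binding_mode == "none"

    def test_peak_at_unresponsive_gene_reported_bound_unresponsive(self):
        links, _ = self._links([make_peak("chr1", 399_989, "peak1")])
        degs = deg_frame({"cish_like": "induced", "thbs1_like": "unchanged",
                          "cdk5_like": "unchanged"})
        calls, flags = classify_target_genes(degs, links, self.GENES,
                                             all_peak_names=["peak1"])
        assert flags.loc["peak1", "bound_unresponsive"]
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["cdk5_like"].scenario == "background"
        # the induced gene far away is independent, not rescued by this peak
        assert by_gene["cish_like"].scenario == "independent"

    def test_enhancer_bound_when_no_promoter_link(self):
        links, _ = self._links([make_peak("chr1", 140_000, "peak1")])
        degs = deg_frame({"cish_like": "induced", "thbs1_like": "unchanged",
                          "cdk5_like": "unchanged"})
        calls, _ = classify_target_genes(degs, links, self.GENES)
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["cish_like"].binding_mode == "enhancer_bound"

    def test_unknown_gene_ids_rejected_with_offenders(self):
        degs = deg_frame({"mystery": "induced"})
        with pytest.raises(ValueError, match="mystery"):
            classify_target_genes(degs, [], self.GENES)

    def test_unlinked_peak_is_trivially_bound_unresponsive(self):
        degs = deg_frame({"cish_like": "induced", "thbs1_like": "unchanged",
                          "cdk5_like": "unchanged"})
        _, flags = classify_target_genes(degs, [], self.GENES,
                                         all_peak_names=["orphan"])
        assert flags.loc["orphan", "bound_unresponsive"]

    def test_scenarios_partition_degs(self, default_dataset, default_result):
        summary = default_result.summary
        n_deg = int((default_result.degs["call"] != "unchanged").sum())
        assert summary["direct"] + summary["independent"] == n_deg
        assert summary["n_deg"] == n_deg

    def test_invariants_of_targetcall(self):
        with pytest.raises(ValueError):
            TargetCall("g", "direct", "none")
        with pytest.raises(ValueError):
            TargetCall("g", "independent", "promoter_bound")


class TestWindowMonotonicity:
    def test_enlarging_window_never_moves_direct_to_independent(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 8000, "+")
            for i, s in enumerate(np.cumsum(rng.integers(30_000, 120_000, size=12)))
        ]
        peaks = annotate(
            [make_peak("chr1", int(p), f"p{j}")
             for j, p in enumerate(rng.integers(0, 1_500_000, size=25))],
            genes,
        )
        degs = deg_frame({g.gene_id: "induced" for g in genes})
        prev_direct: set = set()
        for window in (5_000, 20_000, 50_000, 100_000, 400_000):
            links = link_peaks_to_tss(peaks, genes, window)
            calls, _ = classify_target_genes(degs, links, genes)
            direct = {c.gene_id for c in calls if c.scenario == "direct"}
            assert prev_direct <= direct
            prev_direct = direct


class TestBruteForceEquivalence:
    def test_classification_equals_all_pairs_distance_check(self, small_dataset):
        """On synthetic data the scenario labels equal a brute-force
        all-pairs summit-TSS distance check using the planted DEG truth."""
        ds = small_dataset
        genes = ds.genome.genes
        peaks = annotate(ds.peak_sets["pSTAT5"], genes)
        window = 100_000
        # oracle: direct iff any peak summit within the window of the TSS
        deg_truth = {
            g: d for g, d in ds.truth.gene_direction.items() if d != "unchanged"
        }
        degs = deg_frame(
            {g.gene_id: deg_truth.get(g.gene_id, "unchanged") for g in genes}
        )
        links = link_peaks_to_tss(peaks, genes, window)
        calls, flags = classify_target_genes(
            degs, links, genes, all_peak_names=[p.name for p in ds.peak_sets["pSTAT5"]]
        )
        by_gene = {c.gene_id: c for c in calls}
        for gene in genes:
            near = any(
                p.chrom == gene.chrom and abs(p.summit - gene.tss) <= window
                for p in ds.peak_sets["pSTAT5"]
            )
            expected = (
                ("direct" if near else "independent")
                if gene.gene_id in deg_truth
                else "background"
            )
            assert by_gene[gene.gene_id].scenario == expected
        for p in ds.peak_sets["pSTAT5"]:
            near_deg = any(
                g.chrom == p.chrom and abs(p.summit - g.tss) <= window
                for g in genes if g.gene_id in deg_truth
            )
            assert bool(flags.loc[p.name, "bound_unresponsive"]) == (not near_deg)

    def test_planted_scenarios_recovered_exactly_with_true_deg_labels(
        self, small_dataset
    ):
        """With the DEG truth substituted for noisy calls, the planted
        direct/independent/bound-unresponsive geometry is recovered
        exactly (placement is deterministic given the seed)."""
        ds = small_dataset
        genes = ds.genome.genes
        peaks = annotate(ds.peak_sets["pSTAT5"], genes)
        degs = deg_frame(
            {g.gene_id: ds.truth.gene_direction[g.gene_id] for g in genes}
        )
        links = link_peaks_to_tss(peaks, genes)
        calls, flags = classify_target_genes(
            degs, links, genes, all_peak_names=[p.name for p in ds.peak_sets["pSTAT5"]]
        )
        by_gene = {c.gene_id: c for c in calls}
        for g, scenario in ds.truth.gene_scenario.items():
            if scenario in ("direct", "independent"):
                assert by_gene[g].scenario == scenario
                if scenario == "direct":
                    assert by_gene[g].binding_mode == ds.truth.gene_binding_mode[g]
        for p, planted in ds.truth.peak_bound_unresponsive.items():
            assert bool(flags.loc[p, "bound_unresponsive"]) == planted


class TestSummaryReport:
    def test_all_degs_linked_means_no_independent(self):
        calls = [TargetCall("a", "direct", "promoter_bound", "p1", 10),
                 TargetCall("b", "direct", "enhancer_bound", "p2", 500)]
        summary = summary_report(calls)
        assert summary["independent"] == 0 and summary["direct"] == 2
        assert summary["direct_promoter_bound"] == 1

    def test_no_peaks_means_all_degs_independent(self):
        calls = [TargetCall("a", "independent", "none"),
                 TargetCall("b", "independent", "none"),
                 TargetCall("c", "background", "none")]
        summary = summary_report(calls)
        assert summary["direct"] == 0 and summary["independent"] == 2
        assert summary["n_deg"] == 2
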