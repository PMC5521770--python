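import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stat5targets import pipeline as pl
from stat5targets import synthetic_data as sd
from stat5targets.genomics_io import GeneModel, GenomicInterval, Peak


@pytest.fixture(scope="session")
def default_dataset() -> sd.SyntheticDataset:
    """The full study-scale synthetic dataset (302 peaks, 330 genes)."""
    return sd.simulate(sd.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return pl.run_on_synthetic(default_dataset)


@pytest.fixture(scope="session")
def default_score(default_dataset, default_result):
    return pl.score_against_truth(default_result, default_dataset.truth)


@pytest.fixture(scope="session")
def small_dataset() -> sd.SyntheticDataset:
    return sd.simulate(sd.SimulationConfig.small(seed=3))


def make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    exons=None,
    cds=None,
) -> GeneModel:
    body = GenomicInterval(chrom, start, end, strand)
    exon_ivs = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in (exons or [(start, end)])
    )
    cds_iv = GenomicInterval(chrom, *cds, strand) if cds else None
    return GeneModel(gene_id, strand, body, exon_ivs, cds_iv)


def make_peak(chrom: str, summit: int, name: str = "p", half: int = 50) -> Peak:
    iv = GenomicInterval(chrom, max(0, summit - half), summit + half + 1)
    return Peak(iv, summit, 10.0, 0.01, name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def null_deg_false_call_rate() -> float:
    """Fraction of genes called differential when nothing is planted:
    200 simulated studies of 2000 genes, 2+2 replicates at default
    depth/dispersion, FDR threshold 0.05.  Computed once per session."""
    import pandas as pd

    from stat5targets.expression_response import call_degs
    from stat5targets.genomics_io import CountTable

    gen = np.random.default_rng(42)
    n_genes, n_reps = 2000, 200
    called = 0
    conditions = pd.Series(
        {"p1": "EPO+", "p2": "EPO+", "m1": "EPO-", "m2": "EPO-"}
    )
    lengths = pd.Series(1000, index=pd.RangeIndex(n_genes))
    for _ in range(n_reps):
        base = np.exp(gen.uniform(np.log(500), np.log(5000), size=n_genes))
        r = 1 / 0.01
        counts = pd.DataFrame(
            {s: gen.negative_binomial(r, r / (r + base)) for s in conditions.index}
        )
        table = CountTable(counts, conditions, lengths)
        result = call_degs(table)
        called += int((result["call"] != "unchanged").sum())
    return called / (n_genes * n_reps)
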