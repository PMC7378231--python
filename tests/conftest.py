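"""Shared fixtures: session-scoped synthetic study and small hand models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crpclnc.core import ExpressionMatrix, GeneModel, GenomicInterval, SampleSheet
from crpclnc.pipeline import PipelineConfig, run_discover
from crpclnc.simulate import SimulationConfig, load_ground_truth, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_gene(
    gene_id: str,
    chrom: str = "chr1",
    start: int = 1000,
    end: int = 3000,
    strand: str = "+",
    exons: list[tuple[int, int]] | None = None,
    biotype: str = "coding",
    database: str = "RefSeq",
) -> GeneModel:
    if exons is None:
        exons = [(start, end)]
    return GeneModel(
        gene_id=gene_id,
        name=gene_id.upper(),
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
        database=database,
    )


def cohort_sheet(n_benign: int = 6, n_pca: int = 8, n_crpc: int = 6) -> SampleSheet:
    entries = {}
    for grp, n in (("benign", n_benign), ("pca", n_pca), ("crpc", n_crpc)):
        for i in range(n):
            entries[f"{grp}_{i + 1}"] = (grp, 20_000_000)
    return SampleSheet(entries=entries, declared_groups=("benign", "pca", "crpc"))


def matrix_from_rows(
    rows: dict[str, list[float]], samples: list[str], unit: str = "rpkm"
) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index", columns=samples),
        unit=unit,
    )


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One complete-separation synthetic study shared across tests."""
    outdir = tmp_path_factory.mktemp("sim_default")
    return simulate(SimulationConfig(seed=20), outdir)


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return load_ground_truth(default_sim.paths["ground_truth"], default_sim.genes)


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """A full discovery run on the default synthetic study."""
    outdir = tmp_path_factory.mktemp("run_default")
    config = PipelineConfig.from_simulation_dir(default_sim.outdir, outdir)
    return run_discover(config)
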