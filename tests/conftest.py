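"""Shared fixtures: hand-built transcripts and simulated cohorts."""
from __future__ import annotations

import warnings
from dataclasses import dataclass


import pandas as pd
import pytest

from genebuild import GeneCase, build_gene  # noqa: F401  (re-exported for tests)
from lofkit.pipeline import run_constraint, run_constraint_files
from lofkit.simulate import (
    SimulationConfig,
    default_rate_table,
    generate_reference_and_transcripts,
    simulate_cohort_vcf,
    simulate_to_dir,
)

#: frozen seed of every simulated-cohort fixture in this suite
SUITE_SEED = 1234


def mirror_pos(case_plus: GeneCase, pos0: int) -> int:
    """Genomic position of the mirrored site in the minus-strand construction."""
    return len(case_plus.contig_seq) - 1 - pos0


@dataclass
class Cohort:
    config: SimulationConfig
    bundle: object
    cohort: object
    result: object
    truth: pd.DataFrame

    @property
    def observed(self) -> pd.DataFrame:
        return self.result.observed

    @property
    def table_with_truth(self) -> pd.DataFrame:
        return self.result.table.merge(
            self.truth[["gene_id", "group", "depletion"]], on="gene_id"
        )


def _run_cohort(config: SimulationConfig) -> Cohort:
    bundle = generate_reference_and_transcripts(config)
    rates = default_rate_table(config)
    cohort = simulate_cohort_vcf(config, bundle, rates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_constraint(
            bundle.reference,
            bundle.transcripts,
            cohort.variants,
            cohort.coverage,
            rates,
            methylation=bundle.methylation,
            max_af=1.0,
        )
    return Cohort(
        config=config,
        bundle=bundle,
        cohort=cohort,
        result=result,
        truth=bundle.truth_genes,
    )


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The reference simulation: 300 genes, AN = 20,000 (takes ~1 min)."""
    return _run_cohort(SimulationConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A fast 40-gene cohort for tests that only need structure, not power."""
    return _run_cohort(
        SimulationConfig(
            seed=SUITE_SEED,
            n_genes=40,
            cds_length=(300, 1500),
            n_haplotypes=4000,
        )
    )


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    """The small cohort written to disk through every format writer."""
    outdir = tmp_path_factory.mktemp("study")
    config = SimulationConfig(
        seed=SUITE_SEED, n_genes=40, cds_length=(300, 1500), n_haplotypes=4000
    )
    paths = simulate_to_dir(config, outdir)
    return config, paths
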