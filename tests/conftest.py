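"""Shared fixtures: the default synthetic atlas is generated once per session.

The heavy recovery tests (consensus clustering, ISA, signature calling,
concordance) all operate on the same default-world realization, so the
generator and the merge/normalize steps run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cortexatlas as ca

ATLAS_SEED = 1  # atlas realization used by all recovery tests
ALGO_SEED = 2  # base seed for the stochastic algorithms


@pytest.fixture(scope="session")
def default_atlas():
    cfg = ca.AtlasConfig(seed=ATLAS_SEED)
    tables, truth = ca.generate_proteome(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def batch_tables(default_atlas):
    _, tables, _ = default_atlas
    return [
        ca.compute_reference_ratios(
            t.intensities, t.channel_design, t.reference_region, t.batch_id, t.replicate_id
        )
        for t in tables
    ]


@pytest.fixture(scope="session")
def merged(batch_tables):
    return ca.merge_batches(batch_tables)


@pytest.fixture(scope="session")
def normalized(merged):
    return ca.median_normalize(merged)


@pytest.fixture(scope="session")
def variable(normalized):
    return ca.variability_filter(normalized)


@pytest.fixture(scope="session")
def consensus_result(variable):
    # 200 resamples instead of the 1000 default: identical consensus
    # estimates at test-budget runtime (see docs/methods.md)
    return ca.consensus_cluster(
        variable.retained, range(2, 11), n_resamples=200, seed=ALGO_SEED
    )


@pytest.fixture(scope="session")
def isa_modules(variable):
    return ca.isa_run(variable.retained, n_seeds=200, seed=ALGO_SEED + 1)


@pytest.fixture(scope="session")
def transcriptome_bundle(default_atlas):
    _, _, truth = default_atlas
    counts, meta, lengths = ca.generate_transcriptome(truth, seed=ALGO_SEED + 2)
    return counts, meta, lengths


@pytest.fixture(scope="session")
def rna_region_log2(transcriptome_bundle):
    counts, meta, _ = transcriptome_bundle
    qc = ca.qc_filter(meta)
    detected = ca.detection_filter(counts[list(qc.passing["sample_id"])])
    _, norm = ca.median_of_ratios(detected)
    return ca.region_profile(ca.log2_counts(norm), qc.passing)


@pytest.fixture(scope="session")
def tiny_atlas():
    """Small world for fast structural tests (13 regions, 4 clusters)."""
    cfg = ca.AtlasConfig(
        n_regions=13,
        n_clusters=4,
        n_proteins=300,
        n_batches=4,
        seed=11,
    )
    tables, truth = ca.generate_proteome(cfg)
    return cfg, tables, truth


def ratio_matrix(df: pd.DataFrame, normalized: bool = True) -> ca.RatioMatrix:
    return ca.RatioMatrix(df, normalized=normalized)
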