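"""RNA-seq count processing: QC, median-of-ratios normalization, RPKM, gene signatures.

Sample QC applies inclusive thresholds on RNA integrity (RIN), the 28S/18S
rRNA ratio, and the genome mapping rate.  Counts are depth-normalized with
per-sample size factors (median ratio of counts to per-gene geometric
means), log2(x+1)-transformed, and region-specific signature genes are
called with the same excess-over-median rule used for proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isa import SignatureSet
from .signatures import call_ba_signatures


@dataclass
class QcResult:
    passing: pd.DataFrame
    failing: pd.DataFrame  # with a 'qc_fail_reason' column


_QC_METRICS = ("rin", "rrna_ratio", "mapping_rate")


def qc_filter(
    samples: pd.DataFrame,
    rin_min: float = 6.0,
    rrna_min: float = 0.7,
    map_min: float = 0.4,
) -> QcResult:
    """Inclusive-threshold sample QC; failures carry the failed criterion."""
    missing_cols = [c for c in _QC_METRICS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns {missing_cols}")
    reasons = []
    for _, row in samples.iterrows():
        fails = []
        for metric, cut in (("rin", rin_min), ("rrna_ratio", rrna_min), ("mapping_rate", map_min)):
            v = row[metric]
            if pd.isna(v):
                fails.append(f"{metric}: missing")
            elif v < cut:
                fails.append(f"{metric} {v} < {cut}")
        reasons.append("; ".join(fails))
    reasons = pd.Series(reasons, index=samples.index)
    ok = reasons == ""
    failing = samples.loc[~ok].copy()
    failing["qc_fail_reason"] = reasons[~ok]
    return QcResult(passing=samples.loc[ok].copy(), failing=failing)


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the depth-normalized matrix.

    Reference genes are those with nonzero counts in every sample; each
    sample's size factor is the median over reference genes of
    count / per-gene geometric mean, and normalized counts are
    count / size factor.
    """
    vals = counts.to_numpy(dtype=float)
    nonzero = (vals > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    ref = vals[nonzero]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return sf, normalized


def log2_counts(normalized: pd.DataFrame) -> pd.DataFrame:
    return np.log2(normalized + 1.0)


def detection_filter(
    counts: pd.DataFrame, min_count: float = 1, min_frac: float = 0.5
) -> pd.DataFrame:
    """Keep genes with count > ``min_count`` in >= ceil(min_frac * n) samples."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    need = math.ceil(min_frac * counts.shape[1])
    keep = (counts > min_count).sum(axis=1) >= need
    return counts.loc[keep]


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = count * 1e9 / (gene length in bp * mapped library size)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(library_sizes, axis=1)


def rpkm_threshold_summary(
    rpkm_values: pd.Series, subset: set[str], thresholds: tuple[float, ...] = (1.0, 10.0)
) -> dict[float, float]:
    """Fraction of genes above each RPKM threshold that belong to ``subset``.

    Mirrors coverage statements like "the detected proteins cover X% of
    genes expressed with RPKM > 1".
    """
    out = {}
    for t in thresholds:
        expressed = set(rpkm_values.index[rpkm_values > t])
        out[t] = len(expressed & subset) / len(expressed) if expressed else float("nan")
    return out


def region_profile(log2_matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse samples to genes x regions (mean of log2 values per region)."""
    sample_region = meta.set_index("sample_id")["region"]
    cols = {}
    for region, group in sample_region.groupby(sample_region):
        ids = [s for s in group.index if s in log2_matrix.columns]
        if ids:
            cols[region] = log2_matrix[ids].mean(axis=1)
    return pd.DataFrame(cols)


def call_gene_signatures(
    log2_matrix: pd.DataFrame, cutoff: float = 1.0, max_regions: int = 2
) -> SignatureSet:
    """Region-specific signature genes; same rule as the protein caller."""
    return call_ba_signatures(log2_matrix, cutoff=cutoff, max_regions=max_regions)
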