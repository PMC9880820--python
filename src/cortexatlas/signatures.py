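"""Region-specific signature calling and gene-set over-representation.

A region (BA-level) signature protein is one whose abundance in at most
two regions exceeds its across-region median by a fold-change cutoff.  The
cutoff itself is derived from the data: within-protein pairwise log2
differences across region pairs are approximately normal, and the cutoff
is mean + 3*SD rounded to the nearest half log2 unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._frames import as_frame
from .isa import SignatureSet


@dataclass
class CutoffSpec:
    pairwise_diff_mean: float
    pairwise_diff_sd: float
    mean_plus_3sd: float
    derived_cutoff: float
    rule: str = "mean + 3*SD, rounded to nearest 0.5"

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "CutoffSpec":
        if sd <= 0:
            raise ValueError("pairwise-difference SD must be positive")
        m3 = mean + 3.0 * sd
        rounded = float(np.round(m3 * 2.0) / 2.0)
        if rounded <= 0:
            raise ValueError(f"derived cutoff {rounded} is not positive")
        return cls(float(mean), float(sd), float(m3), rounded)


def derive_cutoff(matrix) -> CutoffSpec:
    """Fit the pairwise log2-difference distribution and derive the cutoff.

    All within-protein differences between unordered region pairs enter;
    the spread of that distribution sets what counts as a real elevation.
    """
    values = as_frame(matrix)
    vals = values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need at least two regions")
    iu, ju = np.triu_indices(vals.shape[1], k=1)
    diffs = (vals[:, iu] - vals[:, ju]).ravel()
    return CutoffSpec.from_moments(diffs.mean(), diffs.std())


def call_ba_signatures(
    matrix, cutoff: float = 1.0, max_regions: int = 2
) -> SignatureSet:
    """Call region-specific signature proteins by excess over the row median.

    A protein qualifies in a region when its log2 value exceeds its own
    median across all regions by at least ``cutoff``; it is a signature of
    its qualifying regions iff it qualifies in 1..``max_regions`` regions.
    Proteins elevated in more regions are not region-specific and are
    excluded entirely.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    values = as_frame(matrix)
    vals = values.to_numpy(dtype=float)
    excess = vals - np.median(vals, axis=1, keepdims=True)
    qual = excess >= cutoff
    n_qual = qual.sum(axis=1)
    assignments: dict = {}
    ok = (n_qual >= 1) & (n_qual <= max_regions)
    for i in np.nonzero(ok)[0]:
        pid = values.index[i]
        for j in np.nonzero(qual[i])[0]:
            assignments.setdefault(values.columns[j], set()).add(pid)
    return SignatureSet(
        level="region",
        assignments=assignments,
        provenance={"cutoff": cutoff, "max_regions": max_regions},
    )


@dataclass
class EnrichmentResult:
    overlap: int
    expected: float
    p_value: float
    neg_log10_p: float
    fold_enrichment: float


def hypergeometric_enrichment(
    signature: set[str],
    gene_set: set[str],
    background: set[str],
    two_sided: bool = False,
) -> EnrichmentResult:
    """Over-representation of ``gene_set`` members within ``signature``.

    One-sided tail P(X >= overlap) under hypergeometric(|background|,
    |gene_set & background|, |signature|); the two-sided option doubles the
    smaller tail, capped at 1.
    """
    if not background:
        raise ValueError("empty background")
    signature = set(signature)
    if not signature <= set(background):
        raise ValueError("signature must be a subset of the background")
    K = len(set(gene_set) & set(background))
    if K == 0:
        raise ValueError("gene set does not intersect the background")
    N = len(set(background))
    n = len(signature)
    k = len(signature & set(gene_set))
    upper = float(hypergeom.sf(k - 1, N, K, n))
    if two_sided:
        lower = float(hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    expected = n * K / N
    fold = (k / n) / (K / N) if n else float("nan")
    return EnrichmentResult(
        overlap=k,
        expected=expected,
        p_value=p,
        neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
        fold_enrichment=fold,
    )
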