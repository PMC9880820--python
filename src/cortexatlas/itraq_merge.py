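"""Assembly of per-batch isobaric reporter ratios into one normalized log2 matrix.

An internal-reference design labels one common region (e.g., BA46) in every
multiplexed batch, so each batch yields protein abundance ratios against the
same reference and batches become comparable.  This module turns raw
channel intensities into reference ratios, merges replicated batches into a
single complete protein x region matrix, median-polishes it on the log2
scale, and applies the inter-region variability filter used upstream of
clustering and signature calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class BatchTable:
    """Per-batch, per-replicate protein x region relative abundances.

    ``values`` holds ratios to the batch's reference region (dimensionless,
    > 0 where present; NaN marks a protein not quantified in this run).  The
    reference-region column, if present, is identically 1.
    """

    batch_id: str
    replicate_id: str
    values: pd.DataFrame
    reference_region: str


@dataclass
class RatioMatrix:
    """Protein x region log2 relative-abundance matrix.

    After :func:`median_normalize`, every row and column median is zero
    within 1e-9.  ``provenance`` records how the matrix was assembled.
    """

    values: pd.DataFrame
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_order(self) -> list[str]:
        return list(self.values.columns)


def compute_reference_ratios(
    intensities: pd.DataFrame,
    design: Mapping[str, str],
    reference_region: str,
    batch_id: str = "batch",
    replicate_id: str = "rep",
) -> BatchTable:
    """Divide each channel by the reference channel, per protein.

    Parameters
    ----------
    intensities
        Protein x channel reporter intensities (>= 0; NaN = not observed).
    design
        Mapping channel -> region; exactly one channel must map to
        ``reference_region``.

    A protein whose reference intensity is zero or missing has no usable
    ratio in this run and its whole row is marked missing.
    """
    ref_channels = [ch for ch, reg in design.items() if reg == reference_region]
    if len(ref_channels) != 1:
        raise ValueError(
            f"design must map exactly one channel to reference region "
            f"{reference_region!r}; found {len(ref_channels)}"
        )
    missing_ch = [ch for ch in design if ch not in intensities.columns]
    if missing_ch:
        raise ValueError(f"channels {missing_ch} not present in intensity table")
    vals = intensities[list(design)].astype(float)
    if (vals < 0).any().any():
        raise ValueError("intensities must be non-negative")
    ref = vals[ref_channels[0]]
    bad_ref = ref.isna() | (ref == 0)
    ratios = vals.div(ref, axis=0)
    ratios.loc[bad_ref, :] = np.nan
    ratios = ratios.rename(columns=dict(design))
    ratios.loc[~bad_ref, reference_region] = 1.0
    return BatchTable(batch_id, replicate_id, ratios, reference_region)


def merge_batches(
    tables: Sequence[BatchTable], avg_scale: str = "linear"
) -> RatioMatrix:
    """Merge replicated batch tables into one complete log2 matrix.

    A protein is retained only if quantified in both (all) technical
    replicates of every batch — a strict complete-case rule on the merged
    matrix.  Replicate ratios are averaged on the linear ratio scale
    (``avg_scale="log"`` averages log2 ratios instead), then
    log2-transformed; the shared reference-region column is filled with
    log2(1) = 0.
    """
    if avg_scale not in ("linear", "log"):
        raise ValueError("avg_scale must be 'linear' or 'log'")
    if not tables:
        raise ValueError("no batch tables supplied")
    reference = tables[0].reference_region
    by_batch: dict[str, list[BatchTable]] = {}
    for t in tables:
        if t.reference_region != reference:
            raise ValueError("all batches must share one reference region")
        by_batch.setdefault(t.batch_id, []).append(t)

    seen: dict[str, str] = {}
    for bid, reps in by_batch.items():
        for reg in reps[0].values.columns:
            if reg == reference:
                continue
            if reg in seen and seen[reg] != bid:
                raise ValueError(f"region {reg!r} appears in batches {seen[reg]!r} and {bid!r}")
            seen[reg] = bid

    # complete-case: no missing value in any replicate of any batch
    proteins = None
    for t in tables:
        ok = t.values.dropna().index
        proteins = ok if proteins is None else proteins.intersection(ok)
    proteins = proteins.sort_values()
    if len(proteins) == 0:
        raise ValueError("no protein is quantified in every replicate of every batch")

    cols: dict[str, pd.Series] = {}
    for bid, reps in by_batch.items():
        regions = [c for c in reps[0].values.columns if c != reference]
        for reg in regions:
            stack = pd.concat([t.values.loc[proteins, reg] for t in reps], axis=1)
            if avg_scale == "linear":
                merged = np.log2(stack.mean(axis=1))
            else:
                merged = np.log2(stack).mean(axis=1)
            cols[reg] = merged
    region_order = sorted(cols) + [reference]
    out = pd.DataFrame(cols, index=proteins)
    out[reference] = 0.0
    out = out[region_order]
    return RatioMatrix(
        out,
        normalized=False,
        provenance={
            "n_batches": len(by_batch),
            "replicates_per_batch": {b: len(r) for b, r in by_batch.items()},
            "reference_region": reference,
            "avg_scale": avg_scale,
        },
    )


def median_normalize(
    matrix: RatioMatrix, tol: float = 1e-9, max_sweeps: int = 100
) -> RatioMatrix:
    """Median-polish the log2 matrix to zero row and column medians.

    A single column-then-row median subtraction does not guarantee both
    medians end up at zero, so the two steps alternate until the largest
    absolute row/column median is <= ``tol`` (or ``max_sweeps``).
    """
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite values; complete it before normalizing")
    for _ in range(max_sweeps):
        vals -= np.median(vals, axis=0, keepdims=True)
        vals -= np.median(vals, axis=1, keepdims=True)
        worst = max(
            np.abs(np.median(vals, axis=0)).max(),
            np.abs(np.median(vals, axis=1)).max(),
        )
        if worst <= tol:
            break
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return RatioMatrix(out, normalized=True, provenance=dict(matrix.provenance))


@dataclass
class VariabilityResult:
    retained: RatioMatrix
    retained_ids: list[str]
    min_log2_range: float
    whisker_q3_iqr: float  # Q3 + 1.5*IQR of all pairwise log2 differences (diagnostic)


def variability_filter(
    matrix: RatioMatrix, min_log2_range: float = 1.0
) -> VariabilityResult:
    """Keep proteins whose log2 range across regions is >= ``min_log2_range``.

    The default of one log2 unit is the max/min fold change >= 2 rule.  The
    empirical Q3 + 1.5*IQR of all within-protein pairwise log2 differences
    is reported as a diagnostic of the fold-change distribution.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty matrix")
    rng_ = vals.max(axis=1) - vals.min(axis=1)
    keep = rng_ >= min_log2_range
    ids = [p for p, k in zip(matrix.values.index, keep) if k]

    n_regions = vals.shape[1]
    iu, ju = np.triu_indices(n_regions, k=1)
    diffs = (vals[:, iu] - vals[:, ju]).ravel()
    q1, q3 = np.percentile(diffs, [25, 75])
    whisker = q3 + 1.5 * (q3 - q1)

    sub = RatioMatrix(
        matrix.values.loc[ids], normalized=matrix.normalized, provenance=dict(matrix.provenance)
    )
    return VariabilityResult(sub, ids, min_log2_range, float(whisker))


def batch_cv(
    tables: Sequence[BatchTable], shared_proteins: Iterable[str] | None = None
) -> dict[str, float]:
    """Median per-batch coefficient of variation across technical replicates.

    CV = sample sd / mean of the replicate ratios, per protein per
    (non-reference) region; the median over all such values summarizes the
    batch.  Requires >= 2 replicates per batch.
    """
    by_batch: dict[str, list[BatchTable]] = {}
    for t in tables:
        by_batch.setdefault(t.batch_id, []).append(t)
    out: dict[str, float] = {}
    for bid, reps in by_batch.items():
        if len(reps) < 2:
            raise ValueError(f"batch {bid!r} has a single replicate; CV undefined")
        regions = [c for c in reps[0].values.columns if c != reps[0].reference_region]
        if shared_proteins is not None:
            idx = pd.Index(shared_proteins)
        else:
            idx = reps[0].values.index
            for t in reps[1:]:
                idx = idx.intersection(t.values.index)
        stack = np.stack([t.values.loc[idx, regions].to_numpy(dtype=float) for t in reps])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mean
        out[bid] = float(np.nanmedian(cv))
    return out
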