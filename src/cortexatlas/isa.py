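"""Iterative signature algorithm (ISA) biclustering, restricted to up-regulated modules.

ISA alternates between scoring proteins against a region signature and
regions against a protein signature, thresholding each score vector at
mean + t*sd, until a fixed point.  A module is a co-elevated protein/region
subset.  Modules are matched against a region partition to call
cluster-specific signature proteins: a module is accepted for a cluster if
its regions all lie inside the cluster and cover at least 80% of it, and
member proteins with normalized score >= 0.7 are pooled as signatures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._frames import as_frame

logger = logging.getLogger(__name__)


@dataclass
class IsaModule:
    """One bicluster: scores are zero outside the module, in [0, 1] inside."""

    protein_scores: pd.Series
    region_scores: pd.Series
    row_threshold: float
    col_threshold: float
    seed_id: int
    converged: bool = True
    n_seeds: int = 1  # how many seeds converged to this module (robustness)

    @property
    def proteins(self) -> list[str]:
        return list(self.protein_scores.index[self.protein_scores > 0])

    @property
    def regions(self) -> list[str]:
        return list(self.region_scores.index[self.region_scores > 0])


@dataclass
class SignatureSet:
    level: str  # "cluster" or "region"
    assignments: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def all_proteins(self) -> set[str]:
        return set().union(*self.assignments.values()) if self.assignments else set()


def _standardize(vals: np.ndarray, axis: int) -> np.ndarray:
    mean = vals.mean(axis=axis, keepdims=True)
    sd = vals.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (vals - mean) / sd


def _threshold_up(scores: np.ndarray, t: float) -> np.ndarray:
    """Keep scores above mean + t*sd, up-direction only (non-negative)."""
    cut = scores.mean() + t * scores.std()
    kept = np.where((scores > cut) & (scores > 0), scores, 0.0)
    return kept


def isa_run(
    matrix,
    n_seeds: int = 200,
    row_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0),
    col_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0),
    direction: str = "up",
    max_iter: int = 100,
    seed: int = 0,
    seed_regions: int = 2,
    conv_corr: float = 0.99,
    jaccard_merge: float = 0.8,
    score_corr_merge: float = 0.9,
) -> list[IsaModule]:
    """Run ISA from random sparse region seeds over a threshold grid.

    Every seed is iterated at every (row, column) threshold combination.
    Convergence requires the protein-score vector's correlation with the
    previous iteration to reach ``conv_corr`` for two consecutive
    iterations.  Final scores are rescaled to max |score| = 1, and
    near-duplicate modules (region Jaccard >= 0.8 and protein-score
    correlation >= 0.9) are merged, keeping the one reached by most seeds.
    """
    if direction != "up":
        raise ValueError("only up-regulated modules are supported")
    values = as_frame(matrix)
    vals = values.to_numpy(dtype=float)
    if np.allclose(vals.std(), 0):
        raise ValueError("zero-variance matrix")
    proteins = list(values.index)
    regions = list(values.columns)
    n_prot, n_reg = vals.shape
    Ec = _standardize(vals, axis=0)  # column-standardized: protein scores
    Er = _standardize(vals, axis=1)  # row-standardized: region scores
    rng = np.random.default_rng(seed)

    raw_modules: list[IsaModule] = []
    n_dropped = 0
    for sid in range(n_seeds):
        seed_vec = np.zeros(n_reg)
        seed_vec[rng.choice(n_reg, size=min(seed_regions, n_reg), replace=False)] = 1.0
        for tr, tc in itertools.product(row_thresholds, col_thresholds):
            r = seed_vec.copy()
            prev_p = None
            stable = 0
            converged = False
            p = np.zeros(n_prot)
            for _ in range(max_iter):
                p_raw = Ec @ r
                p = _threshold_up(p_raw, tr)
                if not p.any():
                    break
                pn = p / np.linalg.norm(p)
                r_raw = Er.T @ pn
                r = _threshold_up(r_raw, tc)
                if not r.any():
                    break
                r = r / np.linalg.norm(r)
                if prev_p is not None and prev_p.any() and p.any():
                    c = np.corrcoef(prev_p, p)[0, 1]
                    if np.isfinite(c) and c >= conv_corr:
                        stable += 1
                        if stable >= 2:
                            converged = True
                            break
                    else:
                        stable = 0
                prev_p = p
            if not converged or not p.any() or not r.any():
                n_dropped += 1
                continue
            p_scaled = p / np.abs(p).max()
            r_scaled = r / np.abs(r).max()
            raw_modules.append(
                IsaModule(
                    protein_scores=pd.Series(p_scaled, index=proteins),
                    region_scores=pd.Series(r_scaled, index=regions),
                    row_threshold=tr,
                    col_threshold=tc,
                    seed_id=sid,
                )
            )
    if n_dropped:
        logger.info("ISA: dropped %d non-convergent seed runs", n_dropped)
    return _merge_duplicates(raw_modules, jaccard_merge, score_corr_merge)


def _merge_duplicates(
    modules: list[IsaModule], jaccard_min: float, score_corr_min: float
) -> list[IsaModule]:
    kept: list[IsaModule] = []
    for mod in modules:
        mreg = set(mod.regions)
        merged = False
        for other in kept:
            oreg = set(other.regions)
            jac = len(mreg & oreg) / len(mreg | oreg) if (mreg | oreg) else 0.0
            if jac < jaccard_min:
                continue
            c = np.corrcoef(
                mod.protein_scores.to_numpy(), other.protein_scores.to_numpy()
            )[0, 1]
            if np.isfinite(c) and c >= score_corr_min:
                other.n_seeds += 1
                merged = True
                break
        if not merged:
            kept.append(mod)
    kept.sort(key=lambda m: -m.n_seeds)
    return kept


def select_cluster_modules(
    modules: list[IsaModule],
    partition: pd.Series | dict,
    coverage_min: float = 0.8,
    score_min: float = 0.7,
) -> SignatureSet:
    """Call cluster-specific signature proteins from accepted ISA modules.

    A module is accepted for cluster c iff every member region lies in c
    (no regions outside the cluster) and the members cover at least
    ``coverage_min`` of c's regions.  Proteins of accepted modules with
    normalized score >= ``score_min`` are pooled per cluster.
    """
    part = pd.Series(partition)
    clusters: dict = {}
    cluster_regions = {c: set(part.index[part == c]) for c in part.unique()}
    if not modules:
        logger.warning("no ISA modules supplied; empty signature set")
    for mod in modules:
        mreg = set(mod.regions)
        missing = mreg - set(part.index)
        if missing:
            raise ValueError(f"partition does not cover module regions {sorted(missing)}")
        for c, creg in cluster_regions.items():
            if mreg <= creg and len(mreg & creg) >= coverage_min * len(creg):
                sig = set(mod.protein_scores.index[mod.protein_scores >= score_min])
                clusters.setdefault(c, set()).update(sig)
    return SignatureSet(
        level="cluster",
        assignments=clusters,
        provenance={"coverage_min": coverage_min, "score_min": score_min,
                    "n_modules": len(modules)},
    )


def cluster_differential(
    matrix,
    partition: pd.Series | dict,
    cluster_a,
    cluster_b,
    min_fc: float = 1.5,
) -> tuple[list[str], list[str]]:
    """Proteins higher in cluster a vs cluster b at a mean fold-change cutoff.

    Per protein, the difference of mean log2 values between the two
    clusters is compared with log2(min_fc).
    """
    part = pd.Series(partition)
    values = as_frame(matrix)
    for c in (cluster_a, cluster_b):
        if c not in set(part.values):
            raise ValueError(f"unknown cluster label {c!r}")
    reg_a = [r for r in values.columns if part.get(r) == cluster_a]
    reg_b = [r for r in values.columns if part.get(r) == cluster_b]
    diff = values[reg_a].mean(axis=1) - values[reg_b].mean(axis=1)
    cut = np.log2(min_fc)
    higher_a = list(values.index[diff >= cut])
    higher_b = list(values.index[diff <= -cut])
    return higher_a, higher_b
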