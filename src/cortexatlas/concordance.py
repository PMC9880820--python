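"""Six-category mRNA-protein fold-change concordance classification.

For a gene and an (unordered) region pair, compare the protein log2 fold
change P and the mRNA log2 fold change M at a fold-change threshold
(|log2FC| > 1, i.e. FC > 2):

* neither passes            -> "no change"
* only protein passes       -> "protein only"
* only mRNA passes          -> "mRNA only"
* both pass, opposite signs -> "disagree"
* both pass, same sign      -> "agree" when |P - M| <= 1 log2 unit
                               (magnitudes within 2-fold), else
                               "partially agree"

The six labels are mutually exclusive and exhaustive; fold changes exactly
at the threshold fall on the "no change" side (FC <= 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._frames import as_frame

CATEGORIES = (
    "no change",
    "agree",
    "partially agree",
    "protein only",
    "mRNA only",
    "disagree",
)


def classify_gene(
    protein_log2fc: float,
    mrna_log2fc: float,
    fc_threshold: float = 1.0,
    magnitude_tolerance: float = 1.0,
) -> str:
    """Classify a single (protein, mRNA) log2 fold-change pair."""
    if not (np.isfinite(protein_log2fc) and np.isfinite(mrna_log2fc)):
        raise ValueError("fold changes must be finite")
    return _classify(
        np.asarray([protein_log2fc]), np.asarray([mrna_log2fc]), fc_threshold, magnitude_tolerance
    )[0]


def _classify(
    p: np.ndarray, m: np.ndarray, fc_threshold: float, magnitude_tolerance: float
) -> np.ndarray:
    P = np.abs(p) > fc_threshold
    M = np.abs(m) > fc_threshold
    same_sign = np.sign(p) == np.sign(m)
    close = np.abs(p - m) <= magnitude_tolerance
    out = np.where(
        ~P & ~M,
        "no change",
        np.where(
            P & ~M,
            "protein only",
            np.where(
                M & ~P,
                "mRNA only",
                np.where(~same_sign, "disagree", np.where(close, "agree", "partially agree")),
            ),
        ),
    )
    return out


@dataclass
class ConcordanceTable:
    entries: pd.DataFrame  # gene, region_a, region_b, protein_log2fc, mrna_log2fc, category
    pair_proportions: pd.DataFrame  # (region_a, region_b) x category
    mean_proportions: pd.Series  # category -> mean proportion across pairs

    @property
    def n_genes(self) -> int:
        return self.entries["gene"].nunique()


def classify_all(
    protein_matrix,
    mrna_matrix: pd.DataFrame,
    fc_threshold: float = 1.0,
    magnitude_tolerance: float = 1.0,
) -> ConcordanceTable:
    """Classify every shared gene for every unordered shared-region pair.

    Genes are matched by identifier (symbol); both matrices are zero-mean
    normalized per gene across the shared regions before fold changes are
    taken (pair fold changes themselves are shift-invariant).  Proportions
    are reported per pair and averaged across pairs.
    """
    prot = as_frame(protein_matrix)
    genes = prot.index.intersection(mrna_matrix.index)
    regions = [r for r in prot.columns if r in set(mrna_matrix.columns)]
    if len(genes) == 0 or len(regions) < 2:
        raise ValueError(
            f"need shared genes and >= 2 shared regions "
            f"(got {len(genes)} genes, {len(regions)} regions)"
        )
    P = prot.loc[genes, regions].to_numpy(dtype=float)
    M = mrna_matrix.loc[genes, regions].to_numpy(dtype=float)
    P = P - P.mean(axis=1, keepdims=True)
    M = M - M.mean(axis=1, keepdims=True)

    frames = []
    prop_rows = {}
    for i, j in combinations(range(len(regions)), 2):
        pfc = P[:, i] - P[:, j]
        mfc = M[:, i] - M[:, j]
        cats = _classify(pfc, mfc, fc_threshold, magnitude_tolerance)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "region_a": regions[i],
                    "region_b": regions[j],
                    "protein_log2fc": pfc,
                    "mrna_log2fc": mfc,
                    "category": cats,
                }
            )
        )
        counts = pd.Series(cats).value_counts()
        prop_rows[(regions[i], regions[j])] = counts.reindex(CATEGORIES, fill_value=0) / len(genes)
    entries = pd.concat(frames, ignore_index=True)
    pair_proportions = pd.DataFrame(prop_rows).T
    pair_proportions.index.names = ["region_a", "region_b"]
    mean_proportions = pair_proportions.mean(axis=0)
    return ConcordanceTable(entries, pair_proportions, mean_proportions)


def category_for_pair(table: ConcordanceTable, gene: str, pair: tuple[str, str]) -> str:
    """Look up a gene's category for an ordered region pair.

    Entries store unordered pairs in matrix column order; looking up the
    reversed pair is valid because swapping regions negates both fold
    changes and preserves the category.
    """
    a, b = pair
    e = table.entries
    hit = e[(e["gene"] == gene) & (e["region_a"] == a) & (e["region_b"] == b)]
    if hit.empty:
        hit = e[(e["gene"] == gene) & (e["region_a"] == b) & (e["region_b"] == a)]
    if hit.empty:
        raise KeyError(f"no entry for gene {gene!r} and pair {pair}")
    return str(hit["category"].iloc[0])
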