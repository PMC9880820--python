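"""iBAQ absolute quantification and cumulative-mass abundance tiering.

iBAQ divides a protein's summed intensity by its number of theoretically
observable tryptic peptides, proxying molar abundance.  Proteins are then
tiered by cumulative mass share: the most abundant proteins accounting for
75% of total abundance are "high", the next 20% "mid", the bottom 5% "low".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def tryptic_peptides(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico trypsin digest: cleave C-terminal to K/R, not before P."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _CANONICAL
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(sequence)]
    fragments = [sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(fragments) - mc):
            peptides.append("".join(fragments[i : i + mc + 1]))
    return peptides


def count_theoretical_peptides(
    sequence: str,
    length_range: tuple[int, int] = (7, 30),
    missed_cleavages: int = 0,
) -> int:
    """Number of tryptic peptides whose length falls in ``length_range``.

    The default window of 7-30 residues with no missed cleavages is the
    conventional iBAQ setting.
    """
    lo, hi = length_range
    return sum(lo <= len(p) <= hi for p in tryptic_peptides(sequence, missed_cleavages))


def compute_ibaq(abundances: pd.Series, peptide_counts: pd.Series) -> pd.DataFrame:
    """Per-protein iBAQ = abundance / theoretical peptide count.

    Proteins with zero countable peptides are flagged unquantifiable
    (``ibaq`` NaN) and must be excluded from tiering.
    """
    if not abundances.index.sort_values().equals(peptide_counts.index.sort_values()):
        raise ValueError("abundance and peptide-count id sets differ")
    if (abundances < 0).any():
        raise ValueError("abundances must be non-negative")
    counts = peptide_counts.reindex(abundances.index)
    ibaq = abundances / counts.replace(0, np.nan)
    return pd.DataFrame(
        {
            "raw_abundance": abundances,
            "theoretical_peptides": counts,
            "ibaq": ibaq,
            "quantifiable": counts > 0,
        }
    )


def tier_by_cumulative_mass(
    ibaq: pd.Series, breaks: tuple[float, float] = (0.75, 0.95)
) -> pd.Series:
    """Assign high/mid/low abundance tiers by cumulative iBAQ share.

    Sorted descending (ties broken by protein id for determinism), "high"
    is the smallest prefix whose cumulative share reaches ``breaks[0]``,
    "mid" continues until ``breaks[1]``, the remainder is "low".  A protein
    straddling a break belongs to the upper tier.
    """
    vals = ibaq.dropna()
    if (vals < 0).any():
        raise ValueError("iBAQ values must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("all iBAQ values are zero; tiers undefined")
    ordered = (
        vals.rename("ibaq")
        .rename_axis("protein_id")
        .reset_index()
        .sort_values(["ibaq", "protein_id"], ascending=[False, True])
        .set_index("protein_id")
    )
    share = ordered["ibaq"].cumsum() / total
    # a protein is "high" iff the cumulative share *before* it is < breaks[0],
    # i.e. it is part of the smallest prefix reaching the break (boundary
    # proteins go to the upper tier)
    before = share.shift(fill_value=0.0)
    hi, mid = breaks
    tier = np.where(before < hi, "high", np.where(before < mid, "mid", "low"))
    return pd.Series(tier, index=ordered.index, name="tier").reindex(ibaq.index)
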