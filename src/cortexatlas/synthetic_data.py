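"""Synthetic multiregion proteome/transcriptome generator with planted truth.

Emulates the study design the analysis pipeline targets: ~29 cortical
regions split over four 8-plex isobaric batches, each batch carrying the
common reference region, two technical replicates per batch, multiplicative
(lognormal) measurement noise and protein-level dropout per run.  Planted
structure — region clusters with cluster-specific signature proteins,
region-specific (one- or two-region) signature proteins, and a coupled
transcriptome whose genes realize known mRNA-protein concordance
categories — gives every downstream stage a parameter-recovery oracle.

The cluster containing the reference region carries no planted signatures:
ratios of the reference to itself are identically 1, so no elevation is
observable in that column.  This mirrors a "heterogeneous/background"
cluster containing the reference area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONCORDANCE_CATEGORIES = (
    "no change",
    "agree",
    "partially agree",
    "protein only",
    "mRNA only",
    "disagree",
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class AtlasConfig:
    """Stated world for the synthetic atlas.

    Defaults mirror a 29-region / 4-batch / 8-channel design with a shared
    reference region, two technical replicates, a planted log2 effect of
    1.5 for signature proteins and log2 noise of 0.25 per measurement.
    """

    n_regions: int = 29
    n_clusters: int = 6
    cluster_sizes: tuple[int, ...] | None = None
    n_proteins: int = 2000
    frac_cluster_signature: float = 0.10
    frac_ba_signature: float = 0.03
    signature_effect: float = 1.5
    noise_sd: float = 0.25
    n_batches: int = 4
    n_tech_reps: int = 2
    missing_rate: float = 0.05
    batch_log2_offset: float = 0.0
    reference_region: str = "BA46"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            base, extra = divmod(self.n_regions, self.n_clusters)
            self.cluster_sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_clusters)
            )
        self.cluster_sizes = tuple(self.cluster_sizes)
        if sum(self.cluster_sizes) != self.n_regions:
            raise ValueError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_regions={self.n_regions}"
            )
        for name in ("frac_cluster_signature", "frac_ba_signature", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (self.n_regions - 1) % self.n_batches:
            raise ValueError(
                "non-reference regions must divide evenly across batches "
                f"({self.n_regions - 1} regions, {self.n_batches} batches)"
            )

    @property
    def regions(self) -> list[str]:
        others = [f"R{i:02d}" for i in range(1, self.n_regions)]
        return others + [self.reference_region]

    @property
    def batch_design(self) -> dict[str, list[str]]:
        """Batch -> region list; every batch includes the reference region."""
        others = self.regions[:-1]
        per = len(others) // self.n_batches
        design = {}
        for b in range(self.n_batches):
            design[f"B{b + 1}"] = others[b * per : (b + 1) * per] + [self.reference_region]
        return design

    def channel_design(self, batch_id: str) -> dict[str, str]:
        regions = self.batch_design[batch_id]
        return {f"ch{i + 1}": r for i, r in enumerate(regions)}


@dataclass
class AtlasTruth:
    """Planted ground truth for parameter-recovery tests."""

    region_cluster: dict[str, int]
    cluster_signature_proteins: dict[int, set[str]]
    ba_signature_proteins: dict[str, set[str]]
    true_log2_matrix: pd.DataFrame  # proteins x regions, noiseless
    reference_region: str
    background_cluster: int
    concordance_category: dict[tuple[str, tuple[str, str]], str] = field(default_factory=dict)

    @property
    def cluster_regions(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for r, c in self.region_cluster.items():
            out.setdefault(c, []).append(r)
        return out

    @property
    def all_cluster_signatures(self) -> set[str]:
        return set().union(*self.cluster_signature_proteins.values()) if self.cluster_signature_proteins else set()

    @property
    def all_ba_signatures(self) -> set[str]:
        return set().union(*self.ba_signature_proteins.values()) if self.ba_signature_proteins else set()


@dataclass
class BatchIntensities:
    """Raw reporter-channel intensities for one batch run (one replicate)."""

    batch_id: str
    replicate_id: str
    intensities: pd.DataFrame  # proteins x channels; NaN rows = dropout
    channel_design: dict[str, str]
    reference_region: str


def generate_proteome(config: AtlasConfig) -> tuple[list[BatchIntensities], AtlasTruth]:
    """Generate per-batch intensity tables plus the planted truth.

    Noise is multiplicative lognormal (additive Gaussian on the log2 scale,
    sd ``noise_sd``) applied to non-reference channels.  Dropout removes a
    protein's whole row from a run with probability ``missing_rate``
    (isobaric missingness is identification-level: a protein seen in a run
    has values in all channels).
    """
    rng = np.random.default_rng(config.seed)
    regions = config.regions
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]

    # --- region -> cluster; reference goes to the last (background) cluster
    others = list(regions[:-1])
    rng.shuffle(others)
    region_cluster: dict[str, int] = {}
    pos = 0
    for cid, size in enumerate(config.cluster_sizes, start=1):
        take = size - 1 if cid == config.n_clusters else size
        for r in others[pos : pos + take]:
            region_cluster[r] = cid
        pos += take
    region_cluster[config.reference_region] = config.n_clusters
    background = config.n_clusters

    # --- planted signature proteins (disjoint id sets)
    order = rng.permutation(config.n_proteins)
    n_csig = int(round(config.frac_cluster_signature * config.n_proteins))
    n_bsig = int(round(config.frac_ba_signature * config.n_proteins))
    sig_clusters = [c for c in range(1, config.n_clusters + 1) if c != background]
    cluster_sig: dict[int, set[str]] = {c: set() for c in sig_clusters}
    for j, idx in enumerate(order[:n_csig]):
        cluster_sig[sig_clusters[j % len(sig_clusters)]].add(proteins[idx])
    ba_sig: dict[str, set[str]] = {}
    non_ref = regions[:-1]
    ba_sig_targets: dict[str, list[str]] = {}
    for idx in order[n_csig : n_csig + n_bsig]:
        pid = proteins[idx]
        k = 1 + int(rng.random() < 0.5)  # one or two target regions
        targets = list(rng.choice(non_ref, size=k, replace=False))
        ba_sig_targets[pid] = targets
        for r in targets:
            ba_sig.setdefault(r, set()).add(pid)

    # --- noiseless log2 matrix
    true = pd.DataFrame(0.0, index=proteins, columns=regions)
    cluster_regions: dict[int, list[str]] = {}
    for r, c in region_cluster.items():
        cluster_regions.setdefault(c, []).append(r)
    for cid, members in cluster_sig.items():
        cols = [r for r in cluster_regions[cid] if r != config.reference_region]
        true.loc[sorted(members), cols] = config.signature_effect
    for pid, targets in ba_sig_targets.items():
        true.loc[pid, targets] = config.signature_effect

    truth = AtlasTruth(
        region_cluster=region_cluster,
        cluster_signature_proteins=cluster_sig,
        ba_signature_proteins=ba_sig,
        true_log2_matrix=true,
        reference_region=config.reference_region,
        background_cluster=background,
    )

    # --- intensity tables: base abundance spans orders of magnitude
    base = 10.0 ** rng.normal(7.0, 1.0, size=config.n_proteins)
    tables: list[BatchIntensities] = []
    for b, (batch_id, batch_regions) in enumerate(config.batch_design.items()):
        ch_design = config.channel_design(batch_id)
        batch_scale = 2.0 ** (config.batch_log2_offset * b)
        for rep in range(config.n_tech_reps):
            cols = {}
            for ch, reg in ch_design.items():
                if reg == config.reference_region:
                    cols[ch] = base * batch_scale
                else:
                    eps = rng.normal(0.0, config.noise_sd, size=config.n_proteins)
                    cols[ch] = (
                        base
                        * batch_scale
                        * 2.0 ** (true[reg].to_numpy() + eps)
                    )
            tab = pd.DataFrame(cols, index=proteins)
            drop = rng.random(config.n_proteins) < config.missing_rate
            tab.loc[drop, :] = np.nan
            tables.append(
                BatchIntensities(batch_id, f"rep{rep + 1}", tab, ch_design, config.reference_region)
            )
    return tables, truth


def generate_sequences(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 400),
    seed: int = 0,
    protein_ids: list[str] | None = None,
) -> dict[str, str]:
    """Random amino-acid sequences over the 20 canonical residues."""
    lo, hi = length_range
    if lo < 10:
        raise ValueError("minimum sequence length is 10 residues")
    rng = np.random.default_rng(seed)
    if protein_ids is None:
        protein_ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    aas = np.array(list(_AMINO_ACIDS))
    out = {}
    for pid in protein_ids:
        length = int(rng.integers(lo, hi + 1))
        out[pid] = "".join(rng.choice(aas, size=length))
    return out


# (protein log2 FC at designated pair, mRNA log2 FC) per planted category;
# margins sized so recovery survives merge noise (protein pair-FC sd ~0.25
# at the default atlas) and mRNA noise 0.1.
_CATEGORY_MRNA_SCALE = {
    "agree": 1.0,  # mRNA profile = protein profile
    "partially agree": None,  # scaled so pair FC = 3.2 (same sign, magnitude differs > 2x)
    "disagree": -1.0,  # mRNA profile = -protein profile
    "protein only": 0.0,
    "mRNA only": 0.0,  # flat protein; +2.0 planted on the mRNA side only
    "no change": 0.0,
}
_PARTIAL_AGREE_MRNA_FC = 3.2
_MRNA_ONLY_FC = 2.0


def default_category_plan(n_per_category: int = 60) -> dict[str, int]:
    return {c: n_per_category for c in CONCORDANCE_CATEGORIES}


def feasible_category_plan(truth: "AtlasTruth", n_per_category: int = 60) -> dict[str, int]:
    """Cap the per-category count by the planted elevated-protein supply.

    Four of the six categories need a protein-level fold change, so at most
    ~70% of the elevated proteins (some lack a usable QC-passing region
    pair) can be planted across them.
    """
    n_elev = len(truth.all_cluster_signatures | truth.all_ba_signatures)
    per = min(n_per_category, max(1, int(0.7 * n_elev) // 4))
    return default_category_plan(per)


def generate_transcriptome(
    truth: AtlasTruth,
    plan: dict[str, int] | None = None,
    library_factors: dict[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.1,
    dispersion: float = 0.002,
    n_qc_fail: int | None = None,
    base_log2_mean: float = 9.5,
    base_log2_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate a coupled RNA-seq count matrix with planted concordance.

    Returns ``(counts, sample_meta, gene_lengths)`` with one sample per
    region and gene ids equal to protein ids (matching by symbol).  For
    each planted gene a designated QC-passing region pair realizes its
    category; entries are recorded in ``truth.concordance_category``.

    Counts are negative binomial (gamma-Poisson, dispersion ``dispersion``)
    around means modulated by the planted mRNA log2 profile plus lognormal
    noise of sd ``noise_sd`` (log2 units).  ``noise_sd = 0`` together with
    ``dispersion = 0`` yields deterministic rounded means.
    """
    if plan is None:
        plan = default_category_plan()
    unknown = set(plan) - set(CONCORDANCE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown concordance categories in plan: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    true = truth.true_log2_matrix
    genes = list(true.index)
    regions = list(true.columns)
    effect = float(true.to_numpy().max()) or 1.5

    non_ref = [r for r in regions if r != truth.reference_region]
    if n_qc_fail is None:
        # default mirrors 8 of 29 samples failing QC, scaled to the atlas size
        n_qc_fail = int(round(len(regions) * 8 / 29))
    failing = set(rng.choice(non_ref, size=n_qc_fail, replace=False)) if n_qc_fail else set()
    passing = [r for r in regions if r not in failing]

    elevated = sorted(truth.all_cluster_signatures | truth.all_ba_signatures)
    flat = sorted(set(genes) - set(elevated))
    rng.shuffle(elevated)
    rng.shuffle(flat)

    def _usable_pair(gene: str) -> tuple[str, str] | None:
        row = true.loc[gene]
        ups = [r for r in passing if row[r] > 0]
        downs = [r for r in passing if row[r] == 0]
        if not ups or not downs:
            return None
        return str(rng.choice(ups)), str(rng.choice(downs))

    m_profile = pd.DataFrame(0.0, index=genes, columns=regions)
    elev_iter = iter(elevated)
    flat_iter = iter(flat)
    for cat in CONCORDANCE_CATEGORIES:
        want = plan.get(cat, 0)
        got = 0
        source = elev_iter if cat in ("agree", "partially agree", "disagree", "protein only") else flat_iter
        while got < want:
            gene = next(source, None)
            if gene is None:
                raise ValueError(f"not enough eligible genes to plant {want} {cat!r} genes")
            if cat in ("agree", "partially agree", "disagree", "protein only"):
                pair = _usable_pair(gene)
                if pair is None:
                    continue
            else:
                a, b = rng.choice(len(passing), size=2, replace=False)
                pair = (passing[a], passing[b])
            scale = _CATEGORY_MRNA_SCALE[cat]
            if cat == "partially agree":
                m_profile.loc[gene] = true.loc[gene] * (_PARTIAL_AGREE_MRNA_FC / effect)
            elif cat == "mRNA only":
                m_profile.loc[gene, pair[0]] = _MRNA_ONLY_FC
            elif scale:
                m_profile.loc[gene] = true.loc[gene] * scale
            truth.concordance_category[(gene, pair)] = cat
            got += 1

    # --- counts
    n_genes, n_samples = len(genes), len(regions)
    base = 2.0 ** rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    if library_factors is None:
        library_factors = {r: float(rng.uniform(0.7, 1.3)) for r in regions}
    logmu = m_profile.to_numpy(dtype=float)
    if noise_sd > 0:
        logmu = logmu + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    mu = base[:, None] * 2.0 ** logmu
    mu = mu * np.array([library_factors[r] for r in regions])[None, :]
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    elif noise_sd > 0:
        counts = rng.poisson(mu)
    else:
        counts = np.round(mu).astype(np.int64)
    sample_ids = [f"S_{r}" for r in regions]
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    # --- QC metadata: failing samples fail exactly one metric
    rows = []
    for r, sid in zip(regions, sample_ids):
        if r in failing:
            which = rng.integers(3)
            rin = float(rng.uniform(2.0, 5.9)) if which == 0 else float(rng.uniform(6.5, 9.8))
            rrna = float(rng.uniform(0.1, 0.65)) if which == 1 else float(rng.uniform(1.0, 2.2))
            maprate = float(rng.uniform(0.1, 0.35)) if which == 2 else float(rng.uniform(0.55, 0.95))
        else:
            rin = float(rng.uniform(6.5, 9.8))
            rrna = float(rng.uniform(1.0, 2.2))
            maprate = float(rng.uniform(0.55, 0.95))
        rows.append(
            dict(
                sample_id=sid,
                region=r,
                rin=round(rin, 2),
                rrna_ratio=round(rrna, 2),
                mapping_rate=round(maprate, 3),
                library_size=int(counts_df[sid].sum()),
            )
        )
    meta = pd.DataFrame(rows)
    gene_lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes), index=genes, name="length_bp"
    )
    return counts_df, meta, gene_lengths


def write_fixture(bundle: dict, directory: str | Path) -> list[Path]:
    """Write a generated bundle as plain-text fixtures.

    Recognized keys: ``proteome_tables`` (list of :class:`BatchIntensities`),
    ``truth`` (:class:`AtlasTruth`), ``sequences`` (id -> sequence),
    ``counts``, ``sample_meta``, ``gene_lengths``.  Round-trips losslessly
    through :mod:`cortexatlas.io` readers.
    """
    if not bundle:
        raise ValueError("empty bundle: nothing to write")
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for tab in bundle.get("proteome_tables", []):
        p = directory / f"intensities_{tab.batch_id}_{tab.replicate_id}.tsv"
        _io.write_matrix_tsv(tab.intensities, p, index_name="protein_id")
        written.append(p)
        d = directory / f"design_{tab.batch_id}.json"
        d.write_text(
            json.dumps(
                {"batch_id": tab.batch_id, "channels": tab.channel_design,
                 "reference_region": tab.reference_region},
                indent=1,
            )
        )
        if d not in written:
            written.append(d)
    if "truth" in bundle:
        p = directory / "truth.json"
        _io.write_truth_json(bundle["truth"], p)
        written.append(p)
    if "sequences" in bundle:
        p = directory / "sequences.fasta"
        _io.write_fasta(bundle["sequences"], p)
        written.append(p)
    if "counts" in bundle:
        p = directory / "counts.tsv"
        _io.write_matrix_tsv(bundle["counts"], p, index_name="gene_id")
        written.append(p)
    if "sample_meta" in bundle:
        p = directory / "sample_meta.tsv"
        bundle["sample_meta"].to_csv(p, sep="\t", index=False)
        written.append(p)
    if "gene_lengths" in bundle:
        p = directory / "gene_lengths.tsv"
        bundle["gene_lengths"].rename_axis("gene_id").to_frame().to_csv(p, sep="\t")
        written.append(p)
    if not written:
        raise ValueError(f"bundle had no recognized keys: {sorted(bundle)}")
    return written
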