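"""Plain-text readers/writers: TSV matrices, FASTA, GMT gene sets, truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    df.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_truth_json(truth, path: str | Path) -> None:
    from .synthetic_data import AtlasTruth  # noqa: F401  (documented schema owner)

    payload = {
        "reference_region": truth.reference_region,
        "background_cluster": truth.background_cluster,
        "region_cluster": truth.region_cluster,
        "cluster_signature_proteins": {
            str(c): sorted(v) for c, v in truth.cluster_signature_proteins.items()
        },
        "ba_signature_proteins": {r: sorted(v) for r, v in truth.ba_signature_proteins.items()},
        "concordance_category": [
            {"gene": g, "region_a": a, "region_b": b, "category": cat}
            for (g, (a, b)), cat in truth.concordance_category.items()
        ],
        "true_log2_matrix": {
            "index": list(truth.true_log2_matrix.index),
            "columns": list(truth.true_log2_matrix.columns),
            "data": truth.true_log2_matrix.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str | Path):
    from .synthetic_data import AtlasTruth

    payload = json.loads(Path(path).read_text())
    tlm = payload["true_log2_matrix"]
    truth = AtlasTruth(
        region_cluster=payload["region_cluster"],
        cluster_signature_proteins={
            int(c): set(v) for c, v in payload["cluster_signature_proteins"].items()
        },
        ba_signature_proteins={r: set(v) for r, v in payload["ba_signature_proteins"].items()},
        true_log2_matrix=pd.DataFrame(tlm["data"], index=tlm["index"], columns=tlm["columns"]),
        reference_region=payload["reference_region"],
        background_cluster=payload["background_cluster"],
    )
    for e in payload["concordance_category"]:
        truth.concordance_category[(e["gene"], (e["region_a"], e["region_b"]))] = e["category"]
    return truth
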