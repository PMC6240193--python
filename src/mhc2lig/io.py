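"""File formats: FASTA proteomes, TSV peptide tables, JSON model containers
and run manifests.

Peptide tables are whitespace/TAB-separated with a header line::

    peptide  target  data_type  [context_up  context_down]  [source_protein_id]

'-' marks missing context (read back as 'XXX') and missing protein ids.
Numeric TSV output is fixed at six decimals so files diff stably.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .encoding import PeptideInstance
from .network import NetworkModel

FLOAT_FORMAT = "%.6f"


# -- FASTA ----------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Protein id -> sequence (uppercased), preserving file order."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


# -- peptide tables -------------------------------------------------------


def instances_to_frame(instances: list[PeptideInstance]) -> pd.DataFrame:
    return pd.DataFrame({
        "peptide": [p.sequence for p in instances],
        "target": [p.target for p in instances],
        "data_type": [p.data_type for p in instances],
        "context_up": [p.context_up if p.context_up != "XXX" else "-"
                       for p in instances],
        "context_down": [p.context_down if p.context_down != "XXX" else "-"
                         for p in instances],
        "source_protein_id": [p.source_protein_id or "-" for p in instances],
    })


def read_peptide_table(path) -> list[PeptideInstance]:
    from .estimator import instances_from_frame

    df = pd.read_csv(str(path), sep=r"\s+")
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: peptide table must have a 'peptide' column")
    return instances_from_frame(df)


def write_peptide_table(instances: list[PeptideInstance], path) -> None:
    instances_to_frame(instances).to_csv(
        str(path), sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic TSV writer with the package's fixed decimal format."""
    df.to_csv(str(path), sep="\t", index=False, float_format=FLOAT_FORMAT)


# -- model container ------------------------------------------------------


def save_models(models, path) -> None:
    """Serialize an ensemble to one JSON file.

    ``models`` is either a list of :class:`NetworkModel` or the fitted
    ``models_`` list of (fold, seed, hidden, model) tuples. Weights
    round-trip bit-exactly (JSON floats use shortest-repr encoding).
    """
    entries = []
    for m in models:
        if isinstance(m, NetworkModel):
            fold = seed = hidden = None
            net = m
        else:
            fold, seed, hidden, net = m
        d = net.to_dict()
        d["fold"] = fold
        entries.append(d)
    payload = {"format": "mhc2lig-ensemble/1", "version": __version__,
               "networks": entries}
    Path(path).write_text(json.dumps(payload))


def load_models(path) -> list[tuple]:
    """Inverse of :func:`save_models`; returns (fold, seed, hidden, model)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mhc2lig-ensemble/1":
        raise ValueError(f"{path}: unrecognized ensemble container")
    out = []
    for d in payload["networks"]:
        net = NetworkModel.from_dict(d)
        out.append((d.get("fold"), net.config.seed, net.config.hidden_units, net))
    return out


# -- run manifest ---------------------------------------------------------


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, config: dict, inputs: list = (), seed=None) -> Path:
    """Record everything needed to replay a run bit-exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "mhc2lig",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
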