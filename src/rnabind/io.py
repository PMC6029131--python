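"""File formats: FASTA, structure-FASTA, label/prediction TSV, checkpoints.

Structure-FASTA is an ordinary FASTA file whose record "sequences" are
six-state strings (F/H/I/M/S/T) with identifiers matching the sequence
FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPLITS = ("train", "validation", "test")


@dataclass
class LabeledDataset:
    """Aligned records: id, sequence, optional structure, label, split."""

    ids: list[str]
    sequences: list[str]
    structures: list[str] | None
    labels: np.ndarray
    splits: list[str]

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.sequences) == self.labels.shape[0] == len(self.splits) == n):
            raise ValueError("field lengths differ")
        if self.structures is not None:
            if len(self.structures) != n:
                raise ValueError("field lengths differ")
            for s, t in zip(self.sequences, self.structures):
                if len(s) != len(t):
                    raise ValueError("sequence/structure length mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            [self.ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            None if self.structures is None else [self.structures[i] for i in idx],
            self.labels[idx],
            [self.splits[i] for i in idx],
        )

    def split(self, name: str) -> "LabeledDataset":
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return self.subset(np.array([s == name for s in self.splits]))

    def positives(self) -> "LabeledDataset":
        return self.subset(self.labels == 1)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError("label TSV needs 'id' and 'label' columns")
    return df


def load_dataset(
    fasta: str | Path,
    labels_tsv: str | Path,
    struct_fasta: str | Path | None = None,
) -> LabeledDataset:
    """Assemble a dataset from a sequence FASTA, a label TSV (columns id,
    label and optionally split) and an optional structure FASTA."""
    from .encoding import normalize_sequence

    seqs = read_fasta(fasta)
    structs = read_fasta(struct_fasta) if struct_fasta is not None else None
    df = read_labels(labels_tsv)
    ids, sequences, structures, labels, splits = [], [], [], [], []
    for _, row in df.iterrows():
        rid = str(row["id"])
        if rid not in seqs:
            raise KeyError(f"id {rid!r} in labels but not in FASTA")
        ids.append(rid)
        sequences.append(normalize_sequence(seqs[rid]))
        if structs is not None:
            if rid not in structs:
                raise KeyError(f"id {rid!r} has no structure record")
            structures.append(structs[rid])
        labels.append(int(row["label"]))
        splits.append(str(row["split"]) if "split" in df.columns else "train")
    return LabeledDataset(ids, sequences, structures if structs is not None else None,
                          np.array(labels), splits)


def write_dataset(ds: LabeledDataset, out_dir: str | Path, prefix: str = "data") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out / f"{prefix}.fa", "labels": out / f"{prefix}.labels.tsv"}
    write_fasta(paths["fasta"], dict(zip(ds.ids, ds.sequences)))
    df = pd.DataFrame({"id": ds.ids, "label": ds.labels, "split": ds.splits})
    df.to_csv(paths["labels"], sep="\t", index=False)
    if ds.structures is not None:
        paths["struct"] = out / f"{prefix}.struct.fa"
        write_fasta(paths["struct"], dict(zip(ds.ids, ds.structures)))
    return paths


def write_predictions(path: str | Path, ids: list[str], probs: np.ndarray) -> None:
    pd.DataFrame({"id": ids, "probability": probs}).to_csv(path, sep="\t", index=False)


def save_checkpoint(path: str | Path, params: dict, bn_state: dict, config: dict,
                    extra: dict | None = None) -> None:
    """Serialize a trained network as JSON (text, portable)."""
    blob = {
        "config": config,
        "params": {k: v.tolist() for k, v in params.items()},
        "bn_state": {k: v.tolist() for k, v in bn_state.items()},
        "alphabets": {"sequence": "ACGU", "structure": "FHIMST"},
    }
    if extra:
        blob.update(extra)
    Path(path).write_text(json.dumps(blob))


def load_checkpoint(path: str | Path) -> dict:
    blob = json.loads(Path(path).read_text())
    blob["params"] = {k: np.asarray(v, dtype=float) for k, v in blob["params"].items()}
    blob["bn_state"] = {k: np.asarray(v, dtype=float) for k, v in blob["bn_state"].items()}
    return blob
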