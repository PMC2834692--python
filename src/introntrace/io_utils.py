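"""File adapters: FASTA, aligned FASTA, newick, TSV, JSON.

Sequence ids follow the ``gene_id|species_id`` convention. All writers are
deterministic (sorted keys, fixed float formatting) so reruns are
byte-identical.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

LOC_STATES = {"M", "N", "U"}


def split_seq_id(seq_id: str) -> tuple[str, str]:
    """Split 'gene|species'; a bare id maps to (id, '')."""
    gene, _, species = seq_id.partition("|")
    return gene, species


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id -> sequence map; wrapped and unwrapped records are identical."""
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValidationError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_localization_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """gene_id -> {species_id -> state}; states must be M, N or U."""
    path = Path(path)
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "species_id", "state"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            state = row["state"].strip()
            if state not in LOC_STATES:
                raise ValidationError(
                    f"{path}: line {i}: unknown state token {state!r} "
                    f"(gene {row['gene_id']!r}, species {row['species_id']!r})"
                )
            gene = out.setdefault(row["gene_id"], {})
            sp = row["species_id"]
            if sp in gene and gene[sp] != state:
                raise ValidationError(
                    f"{path}: line {i}: species {sp!r} has conflicting states "
                    f"for gene {row['gene_id']!r}"
                )
            gene[sp] = state
    return out


def write_tsv(path: str | Path, rows: list[dict], columns: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([_fmt(row.get(c, "")) for c in columns])


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (list, tuple)):
        return ",".join(str(x) for x in v)
    return str(v)


def read_grouping_tsv(path: str | Path) -> dict[str, str]:
    """species_id -> group."""
    out = {}
    for i, row in enumerate(read_tsv(path), start=2):
        if "species_id" not in row or "group" not in row:
            raise ValidationError(f"{path}: line {i}: need species_id and group")
        out[row["species_id"]] = row["group"]
    if not out:
        raise ValidationError(f"{path}: empty grouping table")
    return out


def write_json(path: str | Path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
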