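"""File readers/writers for the interaction-table pipeline.

All user-facing positions are 1-based inclusive; internal indices are
0-based half-open.  Every writer has a reader that round-trips valid data.
"""

from __future__ import annotations

import csv
import json
import platform
from pathlib import Path
from typing import Iterable, Sequence

from .encoding import InteractionRecord, kd_to_pkd
from .explain_eval import AnnotatedSites

__all__ = ["read_interactions", "write_interactions", "read_fasta",
           "read_smi", "read_sites", "write_sites", "write_manifest",
           "write_assignment_csv", "write_explain_results"]

INTERACTION_COLUMNS = ["protein_id", "protein_seq", "compound_id", "smiles", "kd_nM"]


def read_interactions(path) -> list[InteractionRecord]:
    """Parse the interaction CSV; pKd is computed from the Kd column.

    Malformed rows raise errors naming the row number.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in INTERACTION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for rowno, row in enumerate(reader, start=2):
            try:
                kd = float(row["kd_nM"])
            except ValueError:
                raise ValueError(
                    f"{path}: row {rowno}: non-numeric kd_nM {row['kd_nM']!r}"
                ) from None
            try:
                pkd = kd_to_pkd(kd)
            except ValueError as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from None
            records.append(InteractionRecord(
                protein_id=row["protein_id"], protein_seq=row["protein_seq"],
                compound_id=row["compound_id"], smiles=row["smiles"],
                kd_nM=kd, pkd=pkd,
            ))
    return records


def write_interactions(path, records: Sequence[InteractionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTERACTION_COLUMNS)
        for r in records:
            writer.writerow([r.protein_id, r.protein_seq, r.compound_id,
                             r.smiles, repr(float(r.kd_nM))])


def read_fasta(path) -> dict[str, str]:
    """id -> sequence from a FASTA file (Biopython parser)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_smi(path) -> dict[str, str]:
    """id -> SMILES from a .smi file (``SMILES whitespace id`` per line)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'SMILES id'")
            out[parts[1]] = parts[0]
    return out


def read_sites(path) -> dict[str, AnnotatedSites]:
    """pair_id -> annotated sites from a TSV of ``pair_id<TAB>p1,p2,...``."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pair_id", "positions"]:
            raise ValueError(f"{path}: expected header 'pair_id\\tpositions'")
        kind_col = header.index("kind") if "kind" in header else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                positions = tuple(int(x) for x in parts[1].split(",") if x)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position") from None
            kind = parts[kind_col] if kind_col is not None else "binding"
            out[parts[0]] = AnnotatedSites(pair_id=parts[0], positions=positions,
                                           kind=kind)
    return out


def write_sites(path, sites: Iterable[AnnotatedSites]) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tpositions\tkind\n")
        for s in sites:
            fh.write(f"{s.pair_id}\t{','.join(str(p) for p in s.positions)}\t{s.kind}\n")


def write_assignment_csv(path, records, assignment) -> None:
    """Persist a fold assignment: record_index,protein_id,compound_id,pkd,group,fold."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_index", "protein_id", "compound_id", "pkd",
                         "group", "fold"])
        for i, r in enumerate(records):
            writer.writerow([i, r.protein_id, r.compound_id, repr(float(r.pkd)),
                             assignment.group_of[i], assignment.fold_of[i]])


def write_explain_results(path, rows: Iterable[dict]) -> None:
    """Long-format statistics CSV: pair_id, kind, s_w, lambda, statistic, value."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "kind", "s_w", "lambda", "statistic", "value"])
        for row in rows:
            writer.writerow([row.get("pair_id", "ALL"), row["kind"], row["s_w"],
                             row.get("lambda", "NA"), row["statistic"], row["value"]])


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Run manifest: configuration, seed and library versions."""
    import numpy

    versions = {"python": platform.python_version(), "numpy": numpy.__version__}
    try:
        import rdkit

        versions["rdkit"] = rdkit.__version__
    except ImportError:
        pass
    manifest = {"config": config, "seed": seed, "versions": versions}
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n")
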