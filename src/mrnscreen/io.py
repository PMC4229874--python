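"""Readers and writers for the interchange formats.

All tables are UTF-8 TSV with a header row; lines starting with '#' are
comments.  Alignments are aligned FASTA whose header line carries the
species tag and a mammal flag (``>tag mammal=1``); trees are Newick.
Validation failures name the file and row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO

from .gvgd import ProteinAlignment
from .variants import (
    DEFAULT_POPULATIONS,
    DomainAnnotation,
    ReferenceFrequencies,
    Subject,
    VariantObservation,
)

__all__ = [
    "TableValidationError",
    "read_subjects",
    "write_subjects",
    "read_variant_observations",
    "write_variant_observations",
    "read_reference_frequencies",
    "read_domains",
    "read_splice_scores",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_tree",
    "load_config",
    "provenance_header",
]


class TableValidationError(ValueError):
    """A table failed schema validation; message names file and row."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")
    return df


def _norm_status(raw: str, path, row) -> str:
    s = raw.strip().lower()
    if s not in ("case", "control"):
        raise TableValidationError(f"{path}:row {row}: unknown status {raw!r}")
    return s


def read_subjects(path: str | Path) -> list[Subject]:
    df = _read_tsv(path, ["subject_id", "status", "ethnicity", "center"])
    subjects = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        subjects.append(
            Subject(
                subject_id=rec["subject_id"],
                status=_norm_status(rec["status"], path, i),
                ethnicity=rec["ethnicity"],
                center=rec["center"],
                age_band=rec.get("age_band") or None,
            )
        )
    return subjects


def write_subjects(subjects: Iterable[Subject], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "status": s.status,
            "ethnicity": s.ethnicity,
            "center": s.center,
            "age_band": s.age_band or "",
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_BOOL = {"true": True, "1": True, "false": False, "0": False}


def read_variant_observations(path: str | Path) -> list[VariantObservation]:
    df = _read_tsv(path, ["subject_id", "gene", "cdna_change", "raw_class"])
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        raw_class = rec["raw_class"].strip().lower()
        last_exon_raw = str(rec.get("last_exon", "")).strip().lower()
        last_exon = _BOOL.get(last_exon_raw) if last_exon_raw else None
        if raw_class in ("frameshift", "nonsense") and last_exon is None:
            raise TableValidationError(
                f"{path}:row {i}: {raw_class} variant requires a last_exon flag"
            )
        pos_raw = str(rec.get("protein_position", "")).strip()
        try:
            out.append(
                VariantObservation(
                    subject_id=rec["subject_id"],
                    gene=rec["gene"],
                    cdna_change=rec["cdna_change"],
                    raw_class=raw_class,
                    protein_position=int(float(pos_raw)) if pos_raw else None,
                    ref_aa=rec.get("ref_aa") or None,
                    alt_aa=rec.get("alt_aa") or None,
                    last_exon=last_exon,
                    splice_region_kind=rec.get("splice_region_kind") or "none",
                )
            )
        except ValueError as e:
            raise TableValidationError(f"{path}:row {i}: {e}") from e
    return out


def write_variant_observations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_reference_frequencies(
    path: str | Path, populations: Sequence[str] = DEFAULT_POPULATIONS
) -> ReferenceFrequencies:
    df = _read_tsv(path, ["variant_key", "population", "frequency"])
    ref = ReferenceFrequencies(populations)
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            ref.add(rec["variant_key"], rec["population"], float(rec["frequency"]))
        except ValueError as e:
            raise TableValidationError(f"{path}:row {i}: {e}") from e
    return ref


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    df = _read_tsv(path, ["gene", "domain_name", "start", "end", "is_key"])
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            out.append(
                DomainAnnotation(
                    gene=rec["gene"],
                    domain_name=rec["domain_name"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    is_key=_BOOL[str(rec["is_key"]).strip().lower()],
                )
            )
        except (ValueError, KeyError) as e:
            raise TableValidationError(f"{path}:row {i}: {e}") from e
    return out


def read_splice_scores(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene", "junction_id", "site_kind", "wt_score"])
    for col in ("wt_score", "variant_score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="raise")
    return df


# FASTA header grammar: ">tag mammal=0|1"; tag 'human' marks the reference.
def read_alignment_fasta(path: str | Path, gene: str = "") -> ProteinAlignment:
    sequences: dict[str, str] = {}
    flags: dict[str, bool] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tag = rec.id
        mammal = False
        for tok in rec.description.split()[1:]:
            if tok.startswith("mammal="):
                mammal = tok.split("=", 1)[1] in ("1", "true")
        sequences[tag] = str(rec.seq)
        flags[tag] = mammal
    if not sequences:
        raise TableValidationError(f"{path}: no FASTA records")
    return ProteinAlignment(
        gene=gene or Path(path).stem,
        sequences=sequences,
        mammal_flags=flags,
        human_tag="human" if "human" in sequences else next(iter(sequences)),
    )


def write_alignment_fasta(alignment: ProteinAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag, seq in alignment.sequences.items():
            flag = 1 if alignment.mammal_flags.get(tag, False) else 0
            fh.write(f">{tag} mammal={flag}\n{seq}\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableValidationError(f"{path}: config must be a mapping")
    return cfg


def provenance_header(config: dict | None, seed: int | None) -> str:
    """'# provenance ...' comment carrying the config hash and seed."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return f"# provenance: config_sha256={digest} seed={seed}\n"
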