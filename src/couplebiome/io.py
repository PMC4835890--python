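"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython, Newick to scikit-bio, and
tables to pandas; this module adds the validation layer (strict alphabet,
labelled tips, non-negative branch lengths, metadata enums) so that
malformed input fails loudly at the boundary instead of deep in an
analysis.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

from .types import (
    OtuTable,
    SequenceRead,
    SpecimenRecord,
    ValidationError,
    VALID_GROUPS,
    VALID_SITES,
)


class ParseError(ValidationError):
    """A file could not be parsed as its declared format."""


class SchemaError(ValidationError):
    """A table is missing required columns or contains invalid values."""


_FASTQ_FORMATS = {33: "fastq", 64: "fastq-illumina"}

METADATA_COLUMNS = (
    "specimen_id",
    "subject_id",
    "couple_id",
    "site",
    "group",
    "circumcised",
)


def _find_header_line(path: str | os.PathLike, header: str) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.rstrip("\n") == header:
                return lineno
    return None


def read_fasta(path: str | os.PathLike) -> list[SequenceRead]:
    """Read a FASTA file into reads with uppercased bases and no quality."""
    reads = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - malformed beyond Biopython
        raise ParseError(f"{path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            lineno = _find_header_line(path, f">{rec.description}")
            where = f"line {lineno}" if lineno else f"record {rec.id!r}"
            raise ParseError(f"{path}: empty sequence at {where}")
        try:
            reads.append(SequenceRead(rec.id, seq))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return reads


def read_fastq(path: str | os.PathLike, quality_offset: int = 33) -> list[SequenceRead]:
    """Read a FASTQ file (Phred+33 by default) into quality-carrying reads."""
    if quality_offset not in _FASTQ_FORMATS:
        raise ValueError(f"unsupported quality offset {quality_offset}; use 33 or 64")
    reads = []
    try:
        for rec in SeqIO.parse(str(path), _FASTQ_FORMATS[quality_offset]):
            quality = tuple(rec.letter_annotations["phred_quality"])
            try:
                reads.append(SequenceRead(rec.id, str(rec.seq).upper(), quality))
            except ValidationError as exc:
                raise ParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fasta(reads: Sequence[SequenceRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.bases}\n")


def write_fastq(
    reads: Sequence[SequenceRead], path: str | os.PathLike, quality_offset: int = 33
) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.quality is None:
                raise ValidationError(
                    f"read {r.read_id!r} has no quality track; write FASTA instead"
                )
            qual = "".join(chr(q + quality_offset) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check tip labelling and branch-length invariants; return the tree."""
    tips = list(tree.tips())
    labels = [t.name for t in tips]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValidationError("tree has unlabelled tips")
    if len(set(labels)) != len(labels):
        raise ValidationError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at node {node.name!r}"
            )
    return tree


def read_newick(path: str | os.PathLike) -> TreeNode:
    """Read a single rooted Newick tree and validate its invariants."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as Newick: {exc}") from exc
    return validate_tree(tree)


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    validate_tree(tree)
    tree.write(str(path), format="newick")


def _parse_circumcised(value, specimen_id: str) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none"):
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(
        f"specimen {specimen_id!r}: cannot interpret circumcised={value!r}"
    )


def read_metadata(path: str | os.PathLike) -> list[SpecimenRecord]:
    """Read the per-specimen metadata TSV into specimen stubs (no reads)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        if row.site not in VALID_SITES:
            raise SchemaError(
                f"specimen {row.specimen_id!r}: invalid site {row.site!r} "
                f"(expected one of {VALID_SITES})"
            )
        if row.group not in VALID_GROUPS:
            raise SchemaError(
                f"specimen {row.specimen_id!r}: invalid group {row.group!r} "
                f"(expected one of {VALID_GROUPS})"
            )
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                subject_id=row.subject_id,
                couple_id=row.couple_id,
                site=row.site,
                group=row.group,
                circumcised=_parse_circumcised(row.circumcised, row.specimen_id),
            )
        )
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate specimen ids")
    return records


def write_metadata(specimens: Sequence[SpecimenRecord], path: str | os.PathLike) -> None:
    from .types import metadata_frame

    df = metadata_frame(specimens).copy()
    df["circumcised"] = df["circumcised"].map(
        lambda v: "" if v is None else str(bool(v)).lower()
    )
    df.to_csv(path, sep="\t", index=False)


def write_otu_table(table: OtuTable, path: str | os.PathLike) -> None:
    """Write the count table as TSV, taxa as rows, specimens as columns."""
    df = table.to_dataframe()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def read_otu_table(path: str | os.PathLike) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return OtuTable.from_dataframe(df)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """Write the square labelled distance matrix as TSV."""
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "specimen_id"
    df.to_csv(path, sep="\t", float_format="%.10f")


def read_distance_matrix(path: str | os.PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: row and column ids differ")
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))
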