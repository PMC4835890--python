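"""Core data types shared across the pipeline.

The pipeline's in-memory currency is small and explicit: sequence reads,
specimen records with couple metadata, a taxa-by-specimens count table,
and (from scikit-bio) rooted trees and distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SITES = ("vagina", "penile_skin", "urethra")
VALID_GROUPS = ("BV", "normal")
MALE_SITES = ("penile_skin", "urethra")

_BASES = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when an input violates a type invariant."""


@dataclass(frozen=True)
class SequenceRead:
    """One amplicon read, optionally with per-base Phred quality scores.

    ``quality`` is absent (None) for FASTA input; when present it has the
    same length as ``bases``.
    """

    read_id: str
    bases: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValidationError("read_id must be non-empty")
        if not self.bases:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.bases) - _BASES
        if bad:
            raise ValidationError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)} "
                "(bases must be A/C/G/T/N)"
            )
        if self.quality is not None:
            if len(self.quality) != len(self.bases):
                raise ValidationError(
                    f"read {self.read_id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if any(q < 0 for q in self.quality):
                raise ValidationError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class SpecimenRecord:
    """One genital specimen: identity, couple metadata, and its reads.

    ``circumcised`` applies to male sites only and must be None for
    vaginal specimens. ``group`` is the couple's clinical status (the
    woman's diagnosis) and is shared by both partners.
    """

    specimen_id: str
    subject_id: str
    couple_id: str
    site: str
    group: str
    circumcised: bool | None = None
    reads: list[SequenceRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: site {self.site!r} not in {VALID_SITES}"
            )
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: group {self.group!r} not in {VALID_GROUPS}"
            )
        if self.site == "vagina" and self.circumcised is not None:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: circumcised must be absent for vaginal specimens"
            )

    def with_reads(self, reads: list[SequenceRead]) -> "SpecimenRecord":
        return replace(self, reads=reads)


class OtuTable:
    """Taxa-by-specimens matrix of non-negative integer counts.

    Rows are taxon labels (species- or genus-level OTUs), columns are
    specimen ids; column sums equal the number of classified reads per
    specimen.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        specimen_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        taxa = list(taxa)
        specimen_ids = list(specimen_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(taxa), len(specimen_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(taxa)} taxa x {len(specimen_ids)} specimens"
            )
        if len(set(taxa)) != len(taxa):
            raise ValidationError("taxon labels must be unique")
        if len(set(specimen_ids)) != len(specimen_ids):
            raise ValidationError("specimen ids must be unique")
        if counts.size and (not np.issubdtype(counts.dtype, np.integer)):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.taxa = taxa
        self.specimen_ids = specimen_ids
        self.counts = counts
        self._taxon_index = {t: i for i, t in enumerate(taxa)}
        self._specimen_index = {s: j for j, s in enumerate(specimen_ids)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    def specimen_counts(self, specimen_id: str) -> np.ndarray:
        """Count vector (over taxa) for one specimen."""
        return self.counts[:, self._specimen_index[specimen_id]]

    def depths(self) -> np.ndarray:
        """Per-specimen total classified reads (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised matrix; all-zero columns stay zero."""
        depths = self.depths().astype(float)
        safe = np.where(depths > 0, depths, 1.0)
        return self.counts / safe

    def subset_specimens(self, specimen_ids: Iterable[str]) -> "OtuTable":
        ids = list(specimen_ids)
        idx = [self._specimen_index[s] for s in ids]
        return OtuTable(self.taxa, ids, self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.specimen_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.specimen_ids == other.specimen_ids
            and np.array_equal(self.counts, other.counts)
        )


def metadata_frame(specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Tabulate specimen metadata (one row per specimen, reads omitted)."""
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "subject_id": [s.subject_id for s in specimens],
            "couple_id": [s.couple_id for s in specimens],
            "site": [s.site for s in specimens],
            "group": [s.group for s in specimens],
            "circumcised": [s.circumcised for s in specimens],
        }
    )
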