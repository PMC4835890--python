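"""Read quality control.

Four exclusion rules, applied per read in a fixed order so each rejected
read is attributed to exactly one rule:

1. ``min_length`` — shorter than 200 bases (a 200-base read passes);
2. ``ambiguous`` — one or more ambiguous bases (N);
3. ``low_quality`` — mean Phred quality below 25 (exactly 25.0 passes;
   the rule is skipped for reads without a quality track, e.g. FASTA
   input already quality-filtered upstream);
4. ``homopolymer`` — a run of one base longer than six nucleotides (a
   run of exactly six passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Sequence

from .types import SequenceRead, SpecimenRecord

RULE_ORDER = ("min_length", "ambiguous", "low_quality", "homopolymer")


@dataclass(frozen=True)
class QcParams:
    """Thresholds for the four exclusion rules."""

    min_length: int = 200
    max_ambiguous: int = 0
    min_mean_quality: float = 25.0
    max_homopolymer: int = 6

    def __post_init__(self) -> None:
        if min(self.min_length, self.max_ambiguous, self.max_homopolymer) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if self.min_mean_quality < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class SpecimenQc:
    reads_in: int
    reads_kept: int
    rejected: dict[str, int]

    def __post_init__(self) -> None:
        assert self.reads_kept + sum(self.rejected.values()) == self.reads_in


@dataclass
class QcReport:
    """Per-specimen accounting of kept and rejected reads."""

    per_specimen: dict[str, SpecimenQc] = field(default_factory=dict)

    def totals(self) -> SpecimenQc:
        rejected = {rule: 0 for rule in RULE_ORDER}
        reads_in = kept = 0
        for qc in self.per_specimen.values():
            reads_in += qc.reads_in
            kept += qc.reads_kept
            for rule, n in qc.rejected.items():
                rejected[rule] += n
        return SpecimenQc(reads_in, kept, rejected)


def mean_quality(read: SequenceRead) -> float | None:
    """Arithmetic mean Phred score, or None when the read has no quality."""
    if read.quality is None:
        return None
    return sum(read.quality) / len(read.quality)


def max_homopolymer(bases: str) -> int:
    """Length of the longest run of a single character (N included)."""
    if not bases:
        raise ValueError("empty sequence has no homopolymer length")
    return max(sum(1 for _ in run) for _, run in groupby(bases))


def passes_filters(
    read: SequenceRead, params: QcParams = QcParams()
) -> tuple[bool, str | None]:
    """Apply the four rules in fixed order; report the first failure."""
    if len(read) < params.min_length:
        return False, "min_length"
    if read.bases.count("N") > params.max_ambiguous:
        return False, "ambiguous"
    mq = mean_quality(read)
    if mq is not None and mq < params.min_mean_quality:
        return False, "low_quality"
    if max_homopolymer(read.bases) > params.max_homopolymer:
        return False, "homopolymer"
    return True, None


def filter_reads(
    reads: Sequence[SequenceRead], params: QcParams = QcParams()
) -> tuple[list[SequenceRead], SpecimenQc]:
    kept = []
    rejected = {rule: 0 for rule in RULE_ORDER}
    for read in reads:
        ok, rule = passes_filters(read, params)
        if ok:
            kept.append(read)
        else:
            rejected[rule] += 1
    return kept, SpecimenQc(len(reads), len(kept), rejected)


def filter_cohort(
    specimens: Sequence[SpecimenRecord], params: QcParams = QcParams()
) -> tuple[list[SpecimenRecord], QcReport]:
    """Filter every specimen's reads; account for every input read."""
    report = QcReport()
    filtered = []
    for spec in specimens:
        kept, qc = filter_reads(spec.reads, params)
        report.per_specimen[spec.specimen_id] = qc
        filtered.append(spec.with_reads(kept))
    return filtered, report


def write_qc_report(report: QcReport, path) -> None:
    import pandas as pd

    rows = [
        {
            "specimen_id": sid,
            "reads_in": qc.reads_in,
            "reads_kept": qc.reads_kept,
            **{f"rejected_{rule}": qc.rejected[rule] for rule in RULE_ORDER},
        }
        for sid, qc in report.per_specimen.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
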