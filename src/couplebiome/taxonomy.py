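"""Two-tier taxonomic assignment.

Tier 1 assigns each read to the species of its best percent-identity hit
against a curated local reference database, requiring at least 97 %
identity (and, by default, 80 % query coverage). Reads that miss the
identity threshold fall back to tier 2: a word-based naive-Bayes genus
classifier with bootstrap confidence, using the published Ribosomal
Database Project estimator, requiring 80 % confidence. Reads failing
both tiers are excluded and counted.

Percent identity is computed on a semi-global alignment (free end gaps,
terminal-gap columns excluded from the denominator), which approximates
near-full-length BLAST identity on amplicon reads. An edit-distance
prescreen (edlib) narrows the candidate references before the exact
alignment; it is a pure optimisation and can be disabled.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from Bio import Align

from .types import OtuTable, SequenceRead, SpecimenRecord, ValidationError

SPECIES_PREFIX = "s__"
GENUS_PREFIX = "g__"

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    sequence: str
    species: str
    genus: str

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _DNA:
            raise ValidationError(
                f"reference {self.ref_id!r}: sequence must be non-empty over A/C/G/T"
            )


class ReferenceDb:
    """Curated local database of labelled 16S sequences."""

    def __init__(self, entries: Sequence[ReferenceEntry]) -> None:
        entries = list(entries)
        ids = [e.ref_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("reference ids must be unique")
        self.entries = entries
        self.by_id = {e.ref_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.genus)
        return list(seen)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species)
        return list(seen)

    def write(self, fasta_path, taxonomy_path) -> None:
        with open(fasta_path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.ref_id}\n{e.sequence}\n")
        with open(taxonomy_path, "w") as fh:
            fh.write("ref_id\tgenus\tspecies\n")
            for e in self.entries:
                fh.write(f"{e.ref_id}\t{e.genus}\t{e.species}\n")

    @classmethod
    def read(cls, fasta_path, taxonomy_path) -> "ReferenceDb":
        import pandas as pd
        from Bio import SeqIO

        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
        for col in ("ref_id", "genus", "species"):
            if col not in tax.columns:
                raise ValidationError(f"{taxonomy_path}: missing column {col!r}")
        labels = {r.ref_id: (r.genus, r.species) for r in tax.itertuples(index=False)}
        entries = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in labels:
                raise ValidationError(f"reference {rec.id!r} missing from taxonomy table")
            genus, species = labels[rec.id]
            entries.append(ReferenceEntry(rec.id, str(rec.seq).upper(), species, genus))
        return cls(entries)


@dataclass(frozen=True)
class Assignment:
    """The outcome for one read: identity-tier species, Bayes-tier genus,
    or exclusion (Bayes confidence below threshold)."""

    read_id: str
    tier: str  # "identity" | "bayes" | "excluded"
    label: str | None
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # free end gaps on both sequences (semi-global)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _alignment_stats(query: str, reference: str) -> tuple[float, int, float]:
    """(percent identity, aligned columns, query coverage) of the optimal
    semi-global alignment, with terminal-gap columns excluded."""
    aln = _ALIGNER.align(reference, query)[0]
    row_ref, row_q = str(aln[0]), str(aln[1])
    n = len(row_ref)
    start = 0
    while row_ref[start] == "-" or row_q[start] == "-":
        start += 1
        if start >= n:  # degenerate: no overlap
            return 0.0, 0, 0.0
    end = n
    while row_ref[end - 1] == "-" or row_q[end - 1] == "-":
        end -= 1
    # interior gaps (between start and end) still count as columns
    cols = end - start
    matches = sum(
        1 for a, b in zip(row_ref[start:end], row_q[start:end]) if a == b and a != "-"
    )
    q_in_window = sum(1 for c in row_q[start:end] if c != "-")
    coverage = q_in_window / len(query)
    return 100.0 * matches / cols, cols, coverage


def percent_identity(query: str, reference: str) -> float:
    """Percent identity of the optimal semi-global alignment.

    Matches over aligned columns, terminal-gap columns excluded; symmetric
    in its arguments.
    """
    if not query or not reference:
        raise ValidationError("percent_identity requires non-empty sequences")
    pid, _, _ = _alignment_stats(query, reference)
    return pid


def _prescreen_order(read: str, db: ReferenceDb) -> list[int]:
    """Rank references by edit distance of the contained alignment
    (cheap bit-parallel screen); candidates near the minimum first."""
    dists = []
    for i, e in enumerate(db.entries):
        if len(read) <= len(e.sequence):
            r = edlib.align(read, e.sequence, mode="HW", task="distance")
        else:
            r = edlib.align(e.sequence, read, mode="HW", task="distance")
        dists.append((r["editDistance"], i))
    dists.sort()
    best = dists[0][0]
    margin = max(3, int(0.01 * len(read)))
    return [i for d, i in dists if d <= best + margin]


def best_reference_hit(
    read: SequenceRead | str,
    db: ReferenceDb,
    min_identity: float = 97.0,
    min_coverage: float = 0.80,
    prescreen: bool = True,
) -> tuple[ReferenceEntry, float] | None:
    """Best percent-identity reference at or above the identity threshold.

    Ties at equal identity break by greater aligned length, then by
    lexicographically smallest ref_id. Returns None when no reference
    reaches ``min_identity`` (with coverage at least ``min_coverage``).
    """
    seq = read.bases if isinstance(read, SequenceRead) else read
    if not db.entries:
        raise ValidationError("empty reference database")
    candidates = _prescreen_order(seq, db) if prescreen else range(len(db.entries))
    best: tuple[float, int, str, ReferenceEntry] | None = None
    for i in candidates:
        entry = db.entries[i]
        pid, cols, coverage = _alignment_stats(seq, entry.sequence)
        if coverage < min_coverage:
            continue
        key = (pid, cols, _NegStr(entry.ref_id))
        if best is None or key > (best[0], best[1], _NegStr(best[2])):
            best = (pid, cols, entry.ref_id, entry)
    if best is None or best[0] < min_identity:
        return None
    return best[3], best[0]


class _NegStr(str):
    """Orders strings descending inside an ascending-max comparison."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerModel:
    """Word-occurrence naive-Bayes genus model (RDP estimator).

    For word w and genus g with M_g training sequences of which m(w, g)
    contain w, and N total sequences of which n(w) contain w:

        prior  P_w     = (n(w) + 0.5) / (N + 1)
        P(w|g)         = (m(w, g) + P_w) / (M_g + 1)
    """

    def __init__(self, db: ReferenceDb, k: int = 8) -> None:
        genera = db.genera()
        if len(genera) < 2:
            raise ValidationError("naive-Bayes model needs at least 2 genera")
        self.k = k
        self.genera = genera
        g_index = {g: i for i, g in enumerate(genera)}
        n_total = len(db)
        m_per_genus = np.zeros(len(genera), dtype=np.int64)
        word_counts: dict[str, np.ndarray] = defaultdict(
            lambda: np.zeros(len(genera), dtype=np.int64)
        )
        for e in db.entries:
            gi = g_index[e.genus]
            m_per_genus[gi] += 1
            for w in _kmers(e.sequence, k):
                word_counts[w][gi] += 1
        if (m_per_genus == 0).any():
            raise ValidationError("every genus needs at least one training sequence")
        self.m_per_genus = m_per_genus
        denom = (m_per_genus + 1).astype(float)
        self._log_wg: dict[str, np.ndarray] = {}
        for w, m in word_counts.items():
            prior = (m.sum() + 0.5) / (n_total + 1)
            self._log_wg[w] = np.log((m + prior) / denom)
        unseen_prior = 0.5 / (n_total + 1)
        self._log_unseen = np.log(unseen_prior / denom)

    def word_log_probs(self, words: Sequence[str]) -> np.ndarray:
        """Matrix (len(words), n_genera) of log P(w|g)."""
        return np.array([self._log_wg.get(w, self._log_unseen) for w in words])

    def conditional_probability(self, word: str, genus: str) -> float:
        gi = self.genera.index(genus)
        return float(np.exp(self._log_wg.get(word, self._log_unseen)[gi]))


def train_kmer_model(db: ReferenceDb, k: int = 8) -> KmerModel:
    return KmerModel(db, k=k)


def classify_bayes(
    read: SequenceRead | str,
    model: KmerModel,
    n_bootstrap: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[str, float]:
    """Bootstrap genus classification.

    Each bootstrap draw samples ``V // 8`` of the read's V distinct words
    with replacement and scores every genus by the summed log word
    probabilities; confidence is the fraction of draws won by the modal
    genus.
    """
    rng = np.random.default_rng() if rng is None else rng
    seq = read.bases if isinstance(read, SequenceRead) else read
    if len(seq) < model.k:
        raise ValidationError(f"read shorter than word size {model.k}")
    words = sorted(_kmers(seq, model.k))
    log_probs = model.word_log_probs(words)  # V x G
    n_words = max(1, len(words) // 8)
    idx = rng.integers(0, len(words), size=(n_bootstrap, n_words))
    scores = log_probs[idx].sum(axis=1)  # n_bootstrap x G
    winners = np.argmax(scores, axis=1)
    counts = np.bincount(winners, minlength=len(model.genera))
    modal = int(np.argmax(counts))
    return model.genera[modal], counts[modal] / n_bootstrap


def assign_all(
    specimens: Sequence[SpecimenRecord],
    db: ReferenceDb,
    model: KmerModel | None = None,
    rng: np.random.Generator | None = None,
    min_identity: float = 97.0,
    min_confidence: float = 0.80,
    n_bootstrap: int = 100,
    prescreen: bool = True,
) -> tuple[dict[str, list[Assignment]], OtuTable, dict[str, int]]:
    """Assign every read of every specimen; build the OTU table.

    Tier-1 species labels are prefixed ``s__`` and tier-2 genus labels
    ``g__`` so the two namespaces cannot collide. Returns per-specimen
    assignments, the OTU table, and per-specimen exclusion counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    model = train_kmer_model(db) if model is None else model
    assignments: dict[str, list[Assignment]] = {}
    excluded: dict[str, int] = {}
    counts: dict[str, Counter] = {}
    for spec in specimens:
        spec_assign = []
        tally: Counter = Counter()
        n_excluded = 0
        for read in spec.reads:
            hit = best_reference_hit(
                read, db, min_identity=min_identity, prescreen=prescreen
            )
            if hit is not None:
                entry, pid = hit
                label = SPECIES_PREFIX + entry.species
                spec_assign.append(Assignment(read.read_id, "identity", label, pid))
                tally[label] += 1
                continue
            genus, conf = classify_bayes(read, model, n_bootstrap=n_bootstrap, rng=rng)
            if conf >= min_confidence:
                label = GENUS_PREFIX + genus
                spec_assign.append(Assignment(read.read_id, "bayes", label, conf))
                tally[label] += 1
            else:
                spec_assign.append(Assignment(read.read_id, "excluded", None, conf))
                n_excluded += 1
        assignments[spec.specimen_id] = spec_assign
        excluded[spec.specimen_id] = n_excluded
        counts[spec.specimen_id] = tally
    taxa = sorted({t for tally in counts.values() for t in tally})
    specimen_ids = [s.specimen_id for s in specimens]
    matrix = np.zeros((len(taxa), len(specimen_ids)), dtype=np.int64)
    t_index = {t: i for i, t in enumerate(taxa)}
    for j, sid in enumerate(specimen_ids):
        for t, n in counts[sid].items():
            matrix[t_index[t], j] = n
    return assignments, OtuTable(taxa, specimen_ids, matrix), excluded


def map_taxa_to_tips(
    table: OtuTable, db: ReferenceDb, drop_genus_rows: bool = False
) -> OtuTable:
    """Re-key OTU-table rows to phylogeny tip labels (species names).

    Species rows map to their own tip. Genus rows map to the genus's most
    abundant species tip across the cohort (ties by label), or are dropped
    when ``drop_genus_rows`` is set. Raises for labels without prefix.
    """
    species_totals: dict[str, int] = defaultdict(int)
    for taxon, row_sum in zip(table.taxa, table.counts.sum(axis=1)):
        if taxon.startswith(SPECIES_PREFIX):
            species_totals[taxon[len(SPECIES_PREFIX) :]] += int(row_sum)
    genus_to_species: dict[str, list[str]] = defaultdict(list)
    for e in db.entries:
        if e.species not in genus_to_species[e.genus]:
            genus_to_species[e.genus].append(e.species)
    tip_counts: dict[str, np.ndarray] = {}
    for i, taxon in enumerate(table.taxa):
        if taxon.startswith(SPECIES_PREFIX):
            tip = taxon[len(SPECIES_PREFIX) :]
        elif taxon.startswith(GENUS_PREFIX):
            if drop_genus_rows:
                continue
            genus = taxon[len(GENUS_PREFIX) :]
            members = genus_to_species.get(genus)
            if not members:
                raise ValidationError(f"genus {genus!r} not present in reference db")
            tip = max(members, key=lambda s: (species_totals.get(s, 0), s))
        else:
            raise ValidationError(f"taxon {taxon!r} lacks a s__/g__ prefix")
        tip_counts[tip] = tip_counts.get(tip, 0) + table.counts[i]
    tips = sorted(tip_counts)
    matrix = np.vstack([tip_counts[t] for t in tips]) if tips else np.zeros((0, table.n_specimens), dtype=np.int64)
    return OtuTable(tips, table.specimen_ids, matrix)
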