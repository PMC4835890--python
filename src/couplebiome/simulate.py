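"""Synthetic couple-cohort generator.

Emulates the statistical structure of a couples-based genital microbiome
study so that every downstream stage (QC, taxonomy, diversity, the
partner/non-partner distance test) is exercisable without real data:

* a reference database of 16S-like sequences evolved along a random
  birth tree, with within-genus identity far above between-genus
  identity, plus the matching rooted phylogeny;
* vaginal communities drawn from Dirichlet distributions — normal
  communities dominated by one or two *Lactobacillus*-analogue species,
  BV communities spread over many anaerobe-analogue species;
* male penile-skin and urethral communities that mix a male-site
  baseline with a tunable fraction (kappa) of the partner's vaginal
  composition — kappa is the homogenisation effect the partner-distance
  test is designed to detect;
* reads copied from reference sequences with per-base substitution
  errors, Phred qualities, and the four QC defect classes injected at
  configured rates (mutually exclusive per read, so QC accounting has an
  exact ground truth).

All randomness flows through one ``numpy`` generator seeded from the
config, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .qc import QcParams, passes_filters
from .taxonomy import ReferenceDb, ReferenceEntry
from .types import OtuTable, SequenceRead, SpecimenRecord, ValidationError

LACTOBACILLUS_GENUS = "Lactobacillus"
SKIN_GENERA = ("Staphylococcus", "Corynebacterium", "Cutibacterium", "Finegoldia")
BV_GENERA = (
    "Gardnerella",
    "Atopobium",
    "Prevotella",
    "Sneathia",
    "Megasphaera",
    "Mobiluncus",
    "Dialister",
    "Eggerthella",
    "Leptotrichia",
    "Peptoniphilus",
    "Anaerococcus",
    "Aerococcus",
    "Veillonella",
    "Fusobacterium",
    "Porphyromonas",
    "Parvimonas",
)

DEFECT_CLASSES = ("short", "ambiguous", "low_quality", "homopolymer")

SITE_SUFFIX = {"vagina": "V", "penile_skin": "P", "urethra": "U"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level simulation parameters.

    Couple counts, read depths, and circumcision probabilities default to
    the study design being emulated (65 BV couples, 31 normal couples;
    mean depths 6053/5074/5350 reads for vagina/penile skin/urethra;
    54 %/74 % circumcision in the BV/normal groups). kappa_bv and
    kappa_normal are the homogenisation weights for penile skin; the
    urethra receives a scaled-down kappa, much smaller for circumcised
    men, so that only uncircumcised men show an appreciable urethral
    effect.
    """

    n_bv_couples: int = 65
    n_normal_couples: int = 31
    n_genera: int = 16
    n_species_per_genus: int = 3
    seq_length: int = 500
    kappa_bv: float = 0.5
    kappa_normal: float = 0.0
    urethra_kappa_scale_uncircumcised: float = 0.6
    urethra_kappa_scale_circumcised: float = 0.15
    depth_mean: Mapping[str, float] = field(
        default_factory=lambda: {"vagina": 6053.0, "penile_skin": 5074.0, "urethra": 5350.0}
    )
    error_rate: float = 0.005
    defect_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "short": 0.01,
            "ambiguous": 0.01,
            "low_quality": 0.01,
            "homopolymer": 0.01,
        }
    )
    p_circumcised_bv: float = 0.54
    p_circumcised_normal: float = 0.74
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.kappa_bv,
            self.kappa_normal,
            self.urethra_kappa_scale_uncircumcised,
            self.urethra_kappa_scale_circumcised,
            self.error_rate,
            self.p_circumcised_bv,
            self.p_circumcised_normal,
            *self.defect_rates.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if sum(self.defect_rates.values()) > 1.0:
            raise ValidationError("defect rates must sum to at most 1")
        if min(self.depth_mean.values()) < 1:
            raise ValidationError("mean depths must be at least 1")
        if self.n_bv_couples < 0 or self.n_normal_couples < 0:
            raise ValidationError("couple counts must be non-negative")
        if self.n_genera < 2 or self.n_species_per_genus < 1:
            raise ValidationError("need at least 2 genera and 1 species per genus")


@dataclass
class SpeciesRoles:
    """Index arrays partitioning reference species into ecological roles."""

    species: list[str]
    lacto: np.ndarray
    skin: np.ndarray
    bv: np.ndarray


@dataclass
class CohortTruth:
    """Ground truth retained for every synthetic specimen."""

    reference: ReferenceDb
    tree: TreeNode
    species: list[str]
    compositions: dict[str, np.ndarray]
    # per specimen: parallel lists (read_id, source species, defect class or "none")
    read_sources: dict[str, list[str]] = field(default_factory=dict)
    read_defects: dict[str, list[str]] = field(default_factory=dict)


def _genus_names(n_genera: int) -> list[str]:
    names = [LACTOBACILLUS_GENUS]
    names += list(SKIN_GENERA[: max(0, min(len(SKIN_GENERA), n_genera - 1))])
    for g in BV_GENERA:
        if len(names) >= n_genera:
            break
        names.append(g)
    i = 1
    while len(names) < n_genera:
        names.append(f"Genus{i}")
        i += 1
    return names[:n_genera]


def _random_sequence(length: int, rng: np.random.Generator, max_run: int = 4) -> list[str]:
    bases = "ACGT"
    seq: list[str] = []
    run = 0
    for _ in range(length):
        choices = bases if run < max_run else bases.replace(seq[-1], "")
        b = choices[rng.integers(len(choices))]
        if seq and b == seq[-1]:
            run += 1
        else:
            run = 1
        seq.append(b)
    return seq


def _mutate(seq: list[str], n_sub: int, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    if n_sub == 0:
        return out
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in positions:
        alternatives = "ACGT".replace(out[p], "")
        out[p] = alternatives[rng.integers(3)]
    return out


def _break_long_runs(seq: list[str], max_run: int, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    run_start = 0
    for i in range(1, len(out) + 1):
        if i == len(out) or out[i] != out[run_start]:
            if i - run_start > max_run:
                mid = (run_start + i) // 2
                out[mid] = "ACGT".replace(out[mid], "")[rng.integers(3)]
            run_start = i
    return out


def _random_topology(items: list, rng: np.random.Generator) -> object:
    """Random binary bracketing of items (each split uniform)."""
    if len(items) == 1:
        return items[0]
    k = int(rng.integers(1, len(items)))
    return (_random_topology(items[:k], rng), _random_topology(items[k:], rng))


def simulate_reference(
    n_genera: int,
    n_species_per_genus: int,
    seq_length: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceDb, TreeNode]:
    """Evolve a reference database and matching phylogeny.

    Genera diverge along a random binary tree with long branches;
    species within a genus diverge along short terminal branches, so
    within-genus identity stays well above between-genus identity (and
    above the 97 % species-assignment threshold relative to sequencing
    error).
    """
    if n_genera < 2:
        raise ValidationError("need at least 2 genera")
    if seq_length < 250:
        raise ValidationError("reference sequences must be at least 250 bases")
    rng = np.random.default_rng() if rng is None else rng
    genera = _genus_names(n_genera)
    topology = _random_topology(list(range(n_genera)), rng)
    root_seq = _random_sequence(seq_length, rng)

    def build(node, parent_seq: list[str]) -> TreeNode:
        length = float(rng.uniform(0.04, 0.08))
        n_sub = int(rng.binomial(seq_length, length))
        seq = _mutate(parent_seq, n_sub, rng)
        if isinstance(node, tuple):
            tn = TreeNode(length=length)
            tn.extend([build(child, seq) for child in node])
            return tn
        genus = genera[node]
        gn = TreeNode(name=None, length=length)
        for s in range(n_species_per_genus):
            # congeneric 16S divergence ~4-9 % (two branches of 0.02-0.045)
            sp_len = float(rng.uniform(0.02, 0.045))
            # at least 2 substitutions so sibling species never coincide
            n_sub = max(2, int(rng.binomial(seq_length, sp_len)))
            sp_seq = _break_long_runs(_mutate(seq, n_sub, rng), 4, rng)
            tip = TreeNode(name=f"{genus}_sp{s + 1}", length=sp_len)
            tip._sequence = "".join(sp_seq)  # stashed for entry construction
            gn.append(tip)
        return gn

    root = TreeNode(length=None)
    if isinstance(topology, tuple):
        root.extend([build(child, root_seq) for child in topology])
    else:  # single genus (excluded by validation, kept for safety)
        root.append(build(topology, root_seq))
    entries = []
    for tip in root.tips():
        genus = tip.name.rsplit("_sp", 1)[0]
        entries.append(
            ReferenceEntry(f"ref_{tip.name}", tip._sequence, tip.name, genus)
        )
    seqs = [e.sequence for e in entries]
    if len(set(seqs)) != len(seqs):
        raise ValidationError(
            "simulated parameters produced identical sequences for distinct species; "
            "increase seq_length or divergence"
        )
    db = ReferenceDb(entries)
    db.root_sequence = "".join(root_seq)  # retained for outgroup simulation
    return db, root


def simulate_novel_genus(
    db: ReferenceDb,
    n_species: int = 3,
    divergence: float = 0.35,
    rng: np.random.Generator | None = None,
    genus_name: str = "NovelGenus",
) -> list[ReferenceEntry]:
    """A lineage absent from the database: diverged from the root long
    before the reference radiation, so it is roughly equidistant from
    every reference genus (the situation in which a genus-level
    classifier should refuse to assign)."""
    rng = np.random.default_rng() if rng is None else rng
    root = getattr(db, "root_sequence", None)
    if root is None:
        raise ValidationError("database lacks a stored ancestral sequence")
    seq_length = len(root)
    stem = _mutate(list(root), int(rng.binomial(seq_length, divergence)), rng)
    out = []
    for s in range(n_species):
        n_sub = max(2, int(rng.binomial(seq_length, 0.03)))
        sp = _break_long_runs(_mutate(stem, n_sub, rng), 4, rng)
        out.append(
            ReferenceEntry(
                f"ref_{genus_name}_sp{s + 1}", "".join(sp),
                f"{genus_name}_sp{s + 1}", genus_name,
            )
        )
    return out


def reads_from_sequences(
    sequences: Sequence[str],
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    read_prefix: str = "r",
    qc_params: QcParams = QcParams(),
) -> tuple[list[SequenceRead], list[int]]:
    """Clean reads drawn uniformly from arbitrary template sequences.

    Returns the reads and, per read, the index of its source template."""
    if depth < 1:
        raise ValidationError("depth must be at least 1")
    idx = rng.integers(0, len(sequences), size=depth)
    reads = []
    for i in range(depth):
        bases, quality = _clean_read(sequences[int(idx[i])], rng, error_rate, qc_params)
        reads.append(
            SequenceRead(f"{read_prefix}_{i:05d}", bases, tuple(int(q) for q in quality))
        )
    return reads, [int(k) for k in idx]


def species_roles(db: ReferenceDb) -> SpeciesRoles:
    """Partition species into Lactobacillus-analogue, skin, and BV roles."""
    species = db.species()
    genus_of = {e.species: e.genus for e in db.entries}
    lacto, skin, bv = [], [], []
    for i, sp in enumerate(species):
        g = genus_of[sp]
        if g == LACTOBACILLUS_GENUS:
            lacto.append(i)
        elif g in SKIN_GENERA:
            skin.append(i)
        else:
            bv.append(i)
    if not lacto or not bv:
        raise ValidationError("reference must contain Lactobacillus and BV-role genera")
    return SpeciesRoles(
        species, np.array(lacto), np.array(skin or bv[:1]), np.array(bv)
    )


def _carry(
    idx: np.ndarray, p: float, rng: np.random.Generator, min_carry: int = 0
) -> np.ndarray:
    """Random subset of ``idx``: each member independently with
    probability p, re-drawn until at least ``min_carry`` are present."""
    for _ in range(100):
        mask = rng.random(len(idx)) < p
        if mask.sum() >= min_carry:
            return idx[mask]
    order = rng.permutation(idx)
    return order[:min_carry]


def _stratified_bv_carriage(
    roles: SpeciesRoles, rng: np.random.Generator, p_species: float = 0.55
) -> np.ndarray:
    """Carried BV-analogue species: within every BV genus, each species
    independently with probability p, at least one per genus.

    BV-associated genera are near-universal in BV while composition
    varies at the species level; spanning every genus also keeps the
    phylogenetic eccentricity of women's communities nearly constant,
    which the paired partner test needs to stay calibrated under the
    null (see docs/methods.md)."""
    by_genus: dict[str, list[int]] = {}
    for i in roles.bv:
        genus = roles.species[i].rsplit("_sp", 1)[0]
        by_genus.setdefault(genus, []).append(i)
    carried: list[int] = []
    for idxs in by_genus.values():
        idxs = np.array(idxs)
        mask = rng.random(len(idxs)) < p_species
        if not mask.any():
            mask[rng.integers(len(idxs))] = True
        carried.extend(idxs[mask])
    return np.array(carried)


def simulate_vaginal_composition(
    state: str, roles: SpeciesRoles, rng: np.random.Generator
) -> np.ndarray:
    """Draw one vaginal community composition.

    Taxa a subject does not carry have exactly zero abundance — the
    sparsity that presence/absence (unweighted UniFrac) analyses rely on.
    Normal: one dominant (sometimes two) Lactobacillus-analogue species
    plus a small random set of minor taxa, dominant share well above 0.7
    in expectation. BV: a per-woman species subset spanning every
    BV-analogue genus (>= 10 species), Dirichlet-spread, with residual
    Lactobacillus.
    """
    n = len(roles.species)
    alpha = np.zeros(n)
    if state == "normal":
        dominant = rng.choice(roles.lacto)
        alpha[dominant] = 50.0
        if len(roles.lacto) > 1 and rng.random() < 0.3:
            second = rng.choice(roles.lacto[roles.lacto != dominant])
            alpha[second] = 8.0
        n_minor = int(rng.integers(2, 7))
        minor = rng.choice(
            np.concatenate([roles.bv, roles.skin]), size=n_minor, replace=False
        )
        alpha[minor] = 0.3
    elif state == "BV":
        alpha[_stratified_bv_carriage(roles, rng)] = 0.8
        alpha[rng.choice(roles.lacto)] = 0.3
    else:
        raise ValidationError(f"unknown vaginal state {state!r}")
    return _dirichlet_sparse(alpha, rng)


def _dirichlet_sparse(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw over the non-zero alphas; zero alphas stay zero."""
    out = np.zeros_like(alpha, dtype=float)
    nz = alpha > 0
    out[nz] = rng.dirichlet(alpha[nz])
    return out


def male_baseline(site: str, roles: SpeciesRoles, rng: np.random.Generator) -> np.ndarray:
    """Draw a male-site baseline composition.

    Penile skin: most skin-role species plus a modest random set of
    BV-analogue taxa (men carry some BV-associated organisms at
    baseline). Urethra: sparse draw over skin and BV roles with low
    concentration, giving high between-specimen variance.
    """
    n = len(roles.species)
    alpha = np.zeros(n)
    if site == "penile_skin":
        alpha[_carry(roles.skin, 0.8, rng, min_carry=2)] = 3.0
        alpha[_carry(roles.bv, 0.4, rng)] = 0.5
        alpha[_carry(roles.lacto, 0.1, rng)] = 0.2
    elif site == "urethra":
        alpha[_carry(roles.skin, 0.5, rng, min_carry=1)] = 0.5
        alpha[_carry(roles.bv, 0.3, rng)] = 0.5
        alpha[_carry(roles.lacto, 0.15, rng)] = 0.3
    else:
        raise ValidationError(f"unknown male site {site!r}")
    return _dirichlet_sparse(alpha, rng)


def simulate_male_composition(
    site: str,
    baseline: np.ndarray,
    partner_composition: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    concentration: float = 60.0,
) -> np.ndarray:
    """Mix a specimen-level draw around the baseline with the partner's
    vaginal composition: (1 - kappa) * draw + kappa * partner."""
    if not (0.0 <= kappa <= 1.0):
        raise ValidationError(f"kappa must be in [0, 1], got {kappa}")
    if site not in ("penile_skin", "urethra"):
        raise ValidationError(f"unknown male site {site!r}")
    draw = rng.dirichlet(baseline * concentration + 1e-6)
    comp = (1.0 - kappa) * draw + kappa * partner_composition
    return comp / comp.sum()


def _clean_read(
    ref_seq: str,
    rng: np.random.Generator,
    error_rate: float,
    qc: QcParams,
    length_mean: float = 455.0,
    length_sd: float = 40.0,
) -> tuple[str, np.ndarray]:
    """A read that passes every QC filter: reference prefix with
    substitution errors and high-quality Phred scores."""
    max_len = len(ref_seq)
    for _ in range(20):
        length = int(np.clip(round(rng.normal(length_mean, length_sd)), 250, max_len))
        seq = list(ref_seq[:length])
        n_err = rng.binomial(length, error_rate)
        seq = _mutate(seq, int(n_err), rng)
        quality = rng.integers(28, 41, size=length)
        read = "".join(seq)
        ok, _ = passes_filters(SequenceRead("tmp", read, tuple(quality)), qc)
        if ok:
            return read, quality
    # pathological run structure: repair deterministically
    seq = _break_long_runs(seq, qc.max_homopolymer, rng)
    return "".join(seq), quality


def _inject_defect(
    bases: str, quality: np.ndarray, defect: str, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    if defect == "short":
        cut = int(rng.integers(50, 200))
        return bases[:cut], quality[:cut]
    if defect == "ambiguous":
        n = int(rng.integers(1, 4))
        pos = rng.choice(len(bases), size=n, replace=False)
        chars = list(bases)
        for p in pos:
            chars[p] = "N"
        return "".join(chars), quality
    if defect == "low_quality":
        return bases, rng.integers(10, 23, size=len(bases))
    if defect == "homopolymer":
        run_len = int(rng.integers(7, 10))
        base = "ACGT"[rng.integers(4)]
        pos = int(rng.integers(0, len(bases) + 1))
        new_bases = bases[:pos] + base * run_len + bases[pos:]
        new_quality = np.concatenate(
            [quality[:pos], rng.integers(28, 41, size=run_len), quality[pos:]]
        )
        return new_bases, new_quality
    raise ValidationError(f"unknown defect class {defect!r}")


def simulate_reads(
    composition: np.ndarray,
    depth: int,
    db: ReferenceDb,
    error_rate: float,
    defect_rates: Mapping[str, float],
    rng: np.random.Generator,
    read_prefix: str = "r",
    qc_params: QcParams = QcParams(),
) -> tuple[list[SequenceRead], list[str], list[str]]:
    """Draw reads multinomially from a composition over reference species.

    Returns (reads, true source species per read, defect class per read,
    "none" for clean reads). Defects are mutually exclusive per read.
    """
    if depth < 1:
        raise ValidationError("depth must be at least 1")
    species = db.species()
    if len(composition) != len(species):
        raise ValidationError("composition length does not match reference species")
    seq_of = {e.species: e.sequence for e in db.entries}
    p_defect = [defect_rates.get(d, 0.0) for d in DEFECT_CLASSES]
    p = np.array(p_defect + [1.0 - sum(p_defect)])
    source_idx = rng.choice(len(species), size=depth, p=composition)
    defect_idx = rng.choice(len(DEFECT_CLASSES) + 1, size=depth, p=p)
    reads, sources, defects = [], [], []
    for i in range(depth):
        sp = species[int(source_idx[i])]
        bases, quality = _clean_read(seq_of[sp], rng, error_rate, qc_params)
        d = int(defect_idx[i])
        defect = DEFECT_CLASSES[d] if d < len(DEFECT_CLASSES) else "none"
        if defect != "none":
            bases, quality = _inject_defect(bases, quality, defect, rng)
        reads.append(SequenceRead(f"{read_prefix}_{i:05d}", bases, tuple(int(q) for q in quality)))
        sources.append(sp)
        defects.append(defect)
    return reads, sources, defects


def _couple_frame(config: GeneratorConfig, rng: np.random.Generator):
    """Per-couple group and circumcision assignments, in a fixed order."""
    couples = []
    for i in range(config.n_bv_couples + config.n_normal_couples):
        group = "BV" if i < config.n_bv_couples else "normal"
        p_circ = (
            config.p_circumcised_bv if group == "BV" else config.p_circumcised_normal
        )
        couples.append(
            {
                "couple_id": f"C{i + 1:03d}",
                "group": group,
                "circumcised": bool(rng.random() < p_circ),
            }
        )
    return couples


def _specimen_id(couple_id: str, site: str) -> str:
    return f"{couple_id}{SITE_SUFFIX[site]}"


def _site_kappa(config: GeneratorConfig, site: str, group: str, circumcised: bool) -> float:
    kappa = config.kappa_bv if group == "BV" else config.kappa_normal
    if site == "urethra":
        scale = (
            config.urethra_kappa_scale_circumcised
            if circumcised
            else config.urethra_kappa_scale_uncircumcised
        )
        kappa *= scale
    return kappa


def simulate_compositions(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[SpecimenRecord], CohortTruth]:
    """Simulate the cohort down to true compositions (no reads).

    Three specimens per couple (vagina, penile skin, urethra); the male
    sites mix the site baseline with the partner's vaginal composition at
    the group- and site-specific kappa.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    db, tree = simulate_reference(
        config.n_genera, config.n_species_per_genus, config.seq_length, rng
    )
    roles = species_roles(db)
    truth = CohortTruth(db, tree, roles.species, {})
    specimens: list[SpecimenRecord] = []
    for c in _couple_frame(config, rng):
        cid, group, circ = c["couple_id"], c["group"], c["circumcised"]
        vaginal = simulate_vaginal_composition(group, roles, rng)
        comps = {"vagina": vaginal}
        for site in ("penile_skin", "urethra"):
            kappa = _site_kappa(config, site, group, circ)
            comps[site] = simulate_male_composition(
                site, male_baseline(site, roles, rng), vaginal, kappa, rng
            )
        for site in ("vagina", "penile_skin", "urethra"):
            sid = _specimen_id(cid, site)
            subject = f"{cid}{'F' if site == 'vagina' else 'M'}"
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    subject_id=subject,
                    couple_id=cid,
                    site=site,
                    group=group,
                    circumcised=None if site == "vagina" else circ,
                )
            )
            truth.compositions[sid] = comps[site]
    return specimens, truth


def simulate_count_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[SpecimenRecord], OtuTable, CohortTruth]:
    """Cohort as an OTU count table (multinomial reads per specimen,
    without simulating sequences). Taxa are reference species labels,
    matching the phylogeny tips."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    specimens, truth = simulate_compositions(config, rng)
    counts = np.zeros((len(truth.species), len(specimens)), dtype=np.int64)
    for j, spec in enumerate(specimens):
        depth = max(1, int(rng.poisson(config.depth_mean[spec.site])))
        counts[:, j] = rng.multinomial(depth, truth.compositions[spec.specimen_id])
    table = OtuTable(truth.species, [s.specimen_id for s in specimens], counts)
    return specimens, table, truth


def simulate_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[SpecimenRecord], CohortTruth]:
    """Full cohort with simulated reads attached to every specimen."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    specimens, truth = simulate_compositions(config, rng)
    out = []
    for spec in specimens:
        depth = max(1, int(rng.poisson(config.depth_mean[spec.site])))
        reads, sources, defects = simulate_reads(
            truth.compositions[spec.specimen_id],
            depth,
            truth.reference,
            config.error_rate,
            config.defect_rates,
            rng,
            read_prefix=spec.specimen_id,
        )
        truth.read_sources[spec.specimen_id] = sources
        truth.read_defects[spec.specimen_id] = defects
        out.append(spec.with_reads(reads))
    return out, truth
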