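"""Replicated-cohort experiments on the count-level generator.

These harnesses answer calibration and power questions about the
partner/non-partner test by simulating many independent cohorts at the
configured study conditions: the type-I error rate at kappa = 0, the
frequency of the expected significance pattern at the default effect
size, and the monotonicity of the partner-distance effect in kappa.

Each replicate regenerates the full cohort (reference phylogeny,
compositions, multinomial counts), rarefies to a common depth, computes
the unweighted UniFrac matrix, and runs the partner test — the same code
path a real analysis would use, minus read-level simulation and
classification (compositions feed counts directly).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .alpha import TreeIndex, default_rarefaction_depth
from .beta import all_pairs_unifrac
from .couples import (
    paired_partner_test,
    partner_nonpartner,
    stratified_partner_analysis,
)
from .seeding import derive_rng, derive_seed
from .simulate import GeneratorConfig, simulate_count_cohort
from .types import metadata_frame


def cohort_unifrac(config: GeneratorConfig, depth_fraction: float = 0.9):
    """Simulate one count cohort and return (metadata, UniFrac matrix)."""
    specimens, table, truth = simulate_count_cohort(config)
    depth = default_rarefaction_depth(table, depth_fraction)
    rng = derive_rng(config.seed, "rarefaction")
    dm = all_pairs_unifrac(table, TreeIndex(truth.tree), depth, rng)
    return metadata_frame(specimens), dm


def partner_test_rejection_rate(
    n_cohorts: int,
    master_seed: int,
    config: GeneratorConfig | None = None,
    site: str = "penile_skin",
    group: str = "BV",
    alpha: float = 0.05,
    shuffle_partners: bool = False,
) -> float:
    """Fraction of replicate cohorts in which the paired partner test
    rejects at level ``alpha`` for one site and group (unstratified).

    With ``config`` at kappa = 0 this measures type-I error; at positive
    kappa it measures power. ``shuffle_partners`` randomly reassigns
    couples before testing (a negative control that destroys the couple
    structure while keeping the communities).
    """
    base = config if config is not None else GeneratorConfig()
    rejections = 0
    for i in range(n_cohorts):
        cfg = replace(base, seed=derive_seed(master_seed, f"cohort-{i}"))
        meta, dm = cohort_unifrac(cfg)
        if shuffle_partners:
            rng = derive_rng(cfg.seed, "shuffle-partners")
            meta = _shuffle_couples(meta, group, rng)
        records = partner_nonpartner(dm, meta, male_site=site, group=group)
        result = paired_partner_test(records)
        rejections += result.p <= alpha
    return rejections / n_cohorts


def _shuffle_couples(meta, group: str, rng: np.random.Generator):
    """Permute which woman counts as each man's partner within a group."""
    meta = meta.copy()
    mask = (meta["group"] == group) & (meta["site"] != "vagina")
    couples = meta.loc[mask, "couple_id"].unique()
    permuted = dict(zip(couples, rng.permutation(couples)))
    meta.loc[mask, "couple_id"] = meta.loc[mask, "couple_id"].map(permuted)
    return meta


def significance_pattern_rate(
    n_cohorts: int,
    master_seed: int,
    config: GeneratorConfig | None = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicate cohorts reproducing the expected stratified
    pattern: both BV penile-skin strata significant and every normal
    stratum non-significant."""
    base = config if config is not None else GeneratorConfig()
    successes = 0
    for i in range(n_cohorts):
        cfg = replace(base, seed=derive_seed(master_seed, f"pattern-cohort-{i}"))
        meta, dm = cohort_unifrac(cfg)
        results = stratified_partner_analysis(dm, meta)
        by_stratum = {(r.group, r.site, r.circumcised): r.p for r in results}
        bv_ps = [by_stratum.get(("BV", "penile_skin", c)) for c in (True, False)]
        normal_ps = [p for (g, _, _), p in by_stratum.items() if g == "normal"]
        ok = all(p is not None and p <= alpha for p in bv_ps) and all(
            p > alpha for p in normal_ps
        )
        successes += ok
    return successes / n_cohorts


def mean_partner_effect(
    n_cohorts: int,
    master_seed: int,
    kappa: float,
    config: GeneratorConfig | None = None,
    site: str = "penile_skin",
    group: str = "BV",
) -> float:
    """Mean of (partner distance - non-partner distance) across replicate
    cohorts at one homogenisation level; negative values mean partners
    are closer."""
    base = config if config is not None else GeneratorConfig()
    base = replace(base, kappa_bv=kappa) if group == "BV" else replace(base, kappa_normal=kappa)
    effects = []
    for i in range(n_cohorts):
        cfg = replace(base, seed=derive_seed(master_seed, f"effect-{kappa}-{i}"))
        meta, dm = cohort_unifrac(cfg)
        records = partner_nonpartner(dm, meta, male_site=site, group=group)
        effects.append(
            float(
                np.mean([r.partner_distance - r.nonpartner_distance for r in records])
            )
        )
    return float(np.mean(effects))
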