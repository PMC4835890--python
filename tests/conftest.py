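"""Shared fixtures: a small seeded reference database and cohorts, plus
random-tree helpers used by the oracle tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from skbio import TreeNode

from couplebiome.simulate import (
    GeneratorConfig,
    simulate_cohort,
    simulate_reference,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    """A 16-genus, 3-species reference database with its phylogeny."""
    rng = np.random.default_rng(20240501)
    return simulate_reference(16, 3, 500, rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3-couple cohort with reads at low depth, defects injected."""
    config = GeneratorConfig(
        n_bv_couples=2,
        n_normal_couples=1,
        depth_mean={"vagina": 80.0, "penile_skin": 60.0, "urethra": 70.0},
        defect_rates={"short": 0.05, "ambiguous": 0.05, "low_quality": 0.05,
                      "homopolymer": 0.05},
        seed=1729,
    )
    return config, *simulate_cohort(config)


def random_tree(rng: np.random.Generator, n_tips: int) -> TreeNode:
    """Random rooted binary tree with uniform branch lengths in (0, 1]."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(length=None)
    root.extend(nodes)
    return root


def brute_force_unifrac(present_a: set, present_b: set, tree: TreeNode) -> float:
    """Independent oracle: explicit enumeration of every branch's
    descendant tip set, summing unique and union branch lengths."""
    unique = union = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        in_a = bool(tips & present_a)
        in_b = bool(tips & present_b)
        length = node.length or 0.0
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    return unique / union if union else 0.0
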