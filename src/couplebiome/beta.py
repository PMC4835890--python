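"""Beta diversity: unweighted UniFrac, principal coordinates, ANOSIM.

Unweighted UniFrac between two communities is the fraction of the branch
length of their joint subtree that leads to tips of exactly one of them;
branches with no descendant in either community are ignored. The
all-pairs matrix is computed from a branch-incidence representation of
the tree, so the whole matrix is a couple of dense matrix products.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .alpha import TreeIndex, rarefy
from .types import OtuTable, ValidationError


def unweighted_unifrac(
    present_a, present_b, tree: TreeNode | TreeIndex
) -> float:
    """Unweighted UniFrac distance between two presence sets of tree tips."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    a, b = set(present_a), set(present_b)
    if not a and not b:
        raise ValidationError("both communities are empty")
    n_tips = len(index.tip_names)
    vec = np.zeros((n_tips, 2), dtype=bool)
    vec[index.tip_positions(sorted(a)), 0] = True
    vec[index.tip_positions(sorted(b)), 1] = True
    branches = index.presence_to_branches(vec)  # branches x 2
    union = branches.any(axis=1)
    shared = branches.all(axis=1)
    total = index.lengths[union].sum()
    if total == 0:
        return 0.0
    return float(index.lengths[union & ~shared].sum() / total)


def presence_after_rarefaction(
    table: OtuTable, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Taxa x specimens presence matrix, each specimen rarefied to depth."""
    presence = np.zeros(table.counts.shape, dtype=bool)
    for j in range(table.n_specimens):
        presence[:, j] = rarefy(table.counts[:, j], depth, rng) > 0
    return presence


def all_pairs_unifrac(
    table: OtuTable,
    tree: TreeNode | TreeIndex,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> DistanceMatrix:
    """Unweighted UniFrac between every pair of specimens.

    Specimens are first rarefied to a common depth (presence is taken
    after rarefaction); pass ``depth=None`` to skip rarefaction and use
    raw presence.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if depth is not None:
        rng = np.random.default_rng() if rng is None else rng
        presence = presence_after_rarefaction(table, depth, rng)
    else:
        presence = table.counts > 0
    # reorder taxa rows into tree-tip space
    pos = index.tip_positions(table.taxa)
    tip_presence = np.zeros((len(index.tip_names), table.n_specimens), dtype=bool)
    tip_presence[pos] = presence
    branches = index.presence_to_branches(tip_presence)  # B x S
    weighted = branches * index.lengths[:, None]
    shared = weighted.T @ branches  # S x S: sum of lengths on both
    self_len = np.diag(shared).copy()
    union = self_len[:, None] + self_len[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, shared / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(dist, ids=table.specimen_ids)


class Ordination:
    """PCoA result: coordinates on positive axes, all eigenvalues."""

    def __init__(self, ids, coordinates, eigenvalues, proportion_explained):
        self.ids = list(ids)
        self.coordinates = coordinates
        self.eigenvalues = eigenvalues
        self.proportion_explained = proportion_explained


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the double-centred matrix -D^2/2. Negative
    eigenvalues are reported but their axes carry no coordinates (no
    Lingoes/Cailliez correction).
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = np.where(eigvals > 0, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return Ordination(dm.ids, coords, eigvals, proportion)


class AnosimResult:
    def __init__(self, r: float, p: float, n_permutations: int):
        self.r = r
        self.p = p
        self.n_permutations = n_permutations

    def __repr__(self) -> str:
        return f"AnosimResult(R={self.r:.4f}, p={self.p:.4g}, n_permutations={self.n_permutations})"


def anosim(
    dm: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks over all pairwise distances with average ties; p counts
    permuted R values at least as large as the observed one (observed
    included).
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(list(labels))
    n = len(dm.ids)
    if len(labels) != n:
        raise ValidationError("labels length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 members")
    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    n_ge = 1
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= r_obs - 1e-12:
            n_ge += 1
    return AnosimResult(float(r_obs), n_ge / (n_permutations + 1), n_permutations)
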