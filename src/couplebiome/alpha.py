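"""Alpha diversity: rarefaction plus Chao1, observed species, and
Faith's phylogenetic diversity, averaged over random subsamples.

Each specimen is rarefied (sub-sampled without replacement) to a common
depth; every metric is the mean over ``n_subsamples`` independent
rarefactions. Faith's PD uses whole-tree semantics: the branch path from
the present tips up to the root is included. Chao1 uses the
bias-corrected estimator, defined even when there are no doubletons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import TreeNode

from .types import OtuTable, ValidationError

logger = logging.getLogger(__name__)

METRICS = ("chao1", "observed_species", "pd_whole_tree")


@dataclass(frozen=True)
class AlphaResult:
    specimen_id: str
    metric: str
    value: float
    n_subsamples: int
    depth: int


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth``."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"rarefaction depth {depth} exceeds specimen depth {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S + F1(F1-1) / (2(F2+1)); the classic form
    S + F1^2 / (2 F2) is available but undefined at F2 = 0.
    """
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValidationError("counts must be non-negative")
    s = int((counts > 0).sum())
    if s == 0:
        return 0.0
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValidationError("classic Chao1 is undefined with no doubletons")
    return s + f1 * f1 / (2.0 * f2)


def observed_species(counts: np.ndarray) -> int:
    """Number of taxa with non-zero count."""
    return int((np.asarray(counts) > 0).sum())


class TreeIndex:
    """Branch incidence index of a rooted tree for fast PD and UniFrac.

    Row b of ``incidence`` flags the tips descending from branch b;
    ``lengths[b]`` is that branch's length. Metrics over presence vectors
    become matrix products.
    """

    def __init__(self, tree: TreeNode) -> None:
        tips = list(tree.tips())
        self.tip_names = [t.name for t in tips]
        tip_index = {t: i for i, t in enumerate(self.tip_names)}
        rows, lengths = [], []
        for node in tree.traverse(include_self=False):
            length = node.length or 0.0
            row = np.zeros(len(tips), dtype=bool)
            for tip in node.tips(include_self=True):
                row[tip_index[tip.name]] = True
            rows.append(row)
            lengths.append(length)
        self.incidence = np.array(rows) if rows else np.zeros((0, len(tips)), dtype=bool)
        self.lengths = np.array(lengths)
        self._tip_pos = tip_index

    def presence_to_branches(self, presence: np.ndarray) -> np.ndarray:
        """Branch x specimen boolean matrix: branch subtends a present tip."""
        return (self.incidence.astype(np.int64) @ presence.astype(np.int64)) > 0

    def tip_positions(self, names) -> np.ndarray:
        try:
            return np.array([self._tip_pos[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"taxon {exc.args[0]!r} is not a tip of the tree") from exc


def faith_pd(present_taxa, tree: TreeNode | TreeIndex) -> float:
    """Faith's PD: total branch length of the minimal subtree connecting
    the present tips and the root."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    present = list(present_taxa)
    if not present:
        return 0.0
    pos = index.tip_positions(present)
    vec = np.zeros(len(index.tip_names), dtype=bool)
    vec[pos] = True
    subtended = index.incidence[:, vec].any(axis=1)
    return float(index.lengths[subtended].sum())


def default_rarefaction_depth(table: OtuTable, fraction: float = 0.9) -> int:
    """Default common depth: ``fraction`` of the smallest specimen depth."""
    depths = table.depths()
    if not depths.size:
        raise ValidationError("empty OTU table")
    return max(1, int(fraction * depths.min()))


def alpha_summary(
    table: OtuTable,
    tree: TreeNode | TreeIndex,
    depth: int | None = None,
    n_subsamples: int = 10,
    rng: np.random.Generator | None = None,
) -> list[AlphaResult]:
    """All three metrics per specimen, averaged over rarefactions.

    Specimens whose total count is below ``depth`` are excluded with a
    logged warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    if depth is None:
        depth = default_rarefaction_depth(table)
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    taxa_pos = index.tip_positions(table.taxa)
    results = []
    for sid in table.specimen_ids:
        counts = table.specimen_counts(sid)
        if counts.sum() < depth:
            logger.warning(
                "specimen %s dropped: depth %d below rarefaction depth %d",
                sid, counts.sum(), depth,
            )
            continue
        acc = {m: 0.0 for m in METRICS}
        for _ in range(n_subsamples):
            sub = rarefy(counts, depth, rng)
            acc["chao1"] += chao1(sub)
            acc["observed_species"] += observed_species(sub)
            vec = np.zeros(len(index.tip_names), dtype=bool)
            vec[taxa_pos[sub > 0]] = True
            acc["pd_whole_tree"] += float(
                index.lengths[index.incidence[:, vec].any(axis=1)].sum()
            )
        results.extend(
            AlphaResult(sid, m, acc[m] / n_subsamples, n_subsamples, depth)
            for m in METRICS
        )
    return results


def group_compare(
    values_a,
    values_b,
    method: str = "permutation",
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sample comparison of alpha-diversity values.

    ``parametric`` is a Welch two-sample t-test. ``permutation`` uses the
    same statistic with a label-permutation p-value (observed counted, so
    the smallest attainable p with 999 permutations is 0.001).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 values per group")

    def welch_t(x, y):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        denom = np.sqrt(vx / len(x) + vy / len(y))
        if denom == 0:
            raise ValidationError("degenerate variance in both groups")
        return (x.mean() - y.mean()) / denom

    if method == "parametric":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t):
            raise ValidationError("degenerate variance in both groups")
        return float(t), float(p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng() if rng is None else rng
    pooled = np.concatenate([a, b])
    if pooled.var(ddof=1) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_obs = welch_t(a, b)
        n_extreme = 1  # the observed statistic
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            try:
                t_perm = welch_t(perm[: len(a)], perm[len(a):])
            except ValidationError:
                t_perm = 0.0
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                n_extreme += 1
    return float(t_obs), n_extreme / (n_permutations + 1)
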