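"""Pairwise MST overlap and the within-group similarity permutation test.

Two spanning trees on the same node set are compared by the overlap
sigma(a, b) = |E_a ∩ E_b| / (n - 1), the fraction of shared edges — a
similarity kernel in [0, 1] with sigma(a, a) = 1. A real group difference in
tree structure makes trees more similar within groups than across them, so the
test statistic is the within-group mean overlap and the null is built by
shuffling group labels (group sizes fixed). The one-sided p-value is the
fraction of permutations whose within-group similarity is at least the
observed one (null count / n_permutations, observed arrangement not added).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError, TreescapeError
from .trees import SpanningTree


@dataclass
class OverlapMatrix:
    subjects: list
    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = len(self.subjects)
        if self.sigma.shape != (k, k):
            raise SchemaError("sigma must be subjects x subjects")


@dataclass
class PermutationTestResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)


def overlap(a: SpanningTree, b: SpanningTree) -> float:
    """sigma(a, b) = |E_a ∩ E_b| / (n - 1), edges as unordered pairs."""
    if set(a.nodes) != set(b.nodes):
        raise SchemaError("trees must share the same node set")
    return len(a.edge_set() & b.edge_set()) / (a.n - 1)


def overlap_matrix(trees: list[SpanningTree], subjects=None) -> OverlapMatrix:
    k = len(trees)
    subjects = list(subjects) if subjects is not None else list(range(k))
    edge_sets = [t.edge_set() for t in trees]
    n1 = trees[0].n - 1
    sig = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sig[i, j] = sig[j, i] = len(edge_sets[i] & edge_sets[j]) / n1
    return OverlapMatrix(subjects, sig)


def _within_stats(sigma: np.ndarray, mask: np.ndarray):
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise TreescapeError("need >= 2 subjects per group")
    sub = sigma[np.ix_(idx, idx)]
    vals = sub[np.tril_indices(len(idx), k=-1)]
    return float(vals.mean()), float(vals.std())


def within_group_similarity(om: OverlapMatrix, groups) -> dict:
    """Mean and SD of pairwise overlap within each group (strict lower
    triangle, diagonal excluded)."""
    groups = np.asarray(groups)
    if len(groups) != len(om.subjects):
        raise SchemaError("groups length must match subjects")
    out = {}
    for g in np.unique(groups):
        mean, sd = _within_stats(om.sigma, groups == g)
        out[str(g)] = {"mean": mean, "sd": sd}
    return out


def similarity_permutation_test(
    trees_or_overlap,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
    weighted: bool = False,
) -> PermutationTestResult:
    """Permutation test of group structure on MST overlap.

    The statistic is the unweighted mean of the two within-group mean overlaps
    (``weighted=True`` weights by the pair counts instead). Group labels are
    shuffled with group sizes fixed; p = #{null >= observed} / n_perm.
    """
    if isinstance(trees_or_overlap, OverlapMatrix):
        om = trees_or_overlap
    else:
        om = overlap_matrix(list(trees_or_overlap))
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise TreescapeError(f"exactly two groups required, got {len(labels)}")
    if n_perm < 100:
        warnings.warn("n_perm < 100: p-value resolution is very coarse",
                      RuntimeWarning, stacklevel=2)

    sigma = om.sigma
    k = len(groups)
    masks = [groups == g for g in labels]
    sizes = [int(m.sum()) for m in masks]
    pair_counts = np.array([s * (s - 1) / 2 for s in sizes])

    def stat(perm_masks):
        means = np.array([_within_stats(sigma, m)[0] for m in perm_masks])
        if weighted:
            return float((means * pair_counts).sum() / pair_counts.sum())
        return float(means.mean())

    observed = stat(masks)
    gm = within_group_similarity(om, groups)

    rng = np.random.default_rng(seed)
    idx = np.arange(k)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        pm = [np.zeros(k, dtype=bool) for _ in labels]
        pm[0][perm[: sizes[0]]] = True
        pm[1][perm[sizes[0]:]] = True
        null[b] = stat(pm)
    p = float((null >= observed).sum() / n_perm)
    return PermutationTestResult(
        observed_stat=observed,
        null_stats=null,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        group_means={g: v["mean"] for g, v in gm.items()},
        group_sds={g: v["sd"] for g, v in gm.items()},
    )
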