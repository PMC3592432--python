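"""Step 2: mine the junction tree for the signal sub-paths.

A *path* runs from the root clique to a leaf clique of the junction tree.
Each clique carries a weight w — the p-value of its clique-level test —
which from here on is just a score (small = strongly phenotype-associated).
A clique is *meaningful* when w < alpha (strict). *Sub-paths* are the
contiguous portions of a path whose endpoints are meaningful and which
contain at most one non-meaningful clique; where a single non-meaningful
clique bridges two meaningful runs, both the bridged segment and the
all-meaningful runs are candidates.

Scoring walks the sub-path accumulating o_i = o_{i-1} + (1 - 2 w_i)
(o_0 = 0): the relevance r is the maximum of the o_i, attained first at
position m, and the standardized relevance r* = r / m makes sub-paths of
different lengths comparable. Per path the sub-path with maximal r* wins;
near-duplicate winners across paths are collapsed by average-linkage
clustering of the gene-set dissimilarity d(A,B) = min(|A\\B|/|A|,
|B\\A|/|B|) cut at height t.

All scoring formulas live on a single :class:`ScoringPolicy` object so an
alternative convention replaces one code site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .graphs import JunctionTree

__all__ = [
    "ScoringPolicy",
    "DEFAULT_POLICY",
    "CliquePath",
    "SubPath",
    "ClipperReport",
    "enumerate_paths",
    "extract_subpaths",
    "relevance",
    "standardized_relevance",
    "best_subpath",
    "subpath_dissimilarity",
    "prune_subpaths",
    "mine",
]


class ScoringPolicy:
    """Single quarantine site for the step-2 scoring conventions."""

    def increment(self, w: float) -> float:
        """Contribution of one clique of weight w to the running score."""
        return 1.0 - 2.0 * w

    def running_scores(self, weights) -> list[float]:
        o = []
        acc = 0.0
        for w in weights:
            acc += self.increment(w)
            o.append(acc)
        return o

    def standardize(self, r: float, m: int) -> float:
        return r / m

    def dissimilarity(self, A: frozenset, B: frozenset) -> float:
        if not A or not B:
            raise ValueError("sub-path gene sets must be non-empty")
        return min(len(A - B) / len(A), len(B - A) / len(B))


DEFAULT_POLICY = ScoringPolicy()


@dataclass
class CliquePath:
    """Root-to-leaf chain of clique indices with aligned weights."""

    path_id: int
    clique_ids: tuple[int, ...]
    weights: tuple[float, ...]
    genes_by_clique: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.clique_ids)


@dataclass
class SubPath:
    """Contiguous scored segment of a path."""

    path_id: int
    start: int  # 0-based offset within the parent path
    clique_ids: tuple[int, ...]
    weights: tuple[float, ...]
    genes_by_clique: tuple[tuple[str, ...], ...]
    o: tuple[float, ...] = field(default=())
    r: float = 0.0
    m: int = 1
    r_star: float = 0.0

    @property
    def length(self) -> int:
        return len(self.clique_ids)

    @property
    def genes(self) -> frozenset:
        return frozenset(g for c in self.genes_by_clique for g in c)


@dataclass
class ClipperReport:
    """Best sub-path per path, collapsed to representatives."""

    best_per_path: list[SubPath]
    representatives: list[SubPath]
    cluster_of: dict[int, int]  # index into best_per_path -> cluster label
    alpha: float
    t: float

    def top(self) -> SubPath | None:
        """Overall winner: maximal r*, ties to longer then earlier."""
        if not self.best_per_path:
            return None
        return max(
            self.best_per_path,
            key=lambda s: (s.r_star, s.length, -s.start, -s.path_id),
        )


def enumerate_paths(
    jt: JunctionTree, weights: list[float] | None = None
) -> list[CliquePath]:
    """One root-to-leaf path per leaf clique; a single-clique tree yields one
    degenerate path of length 1."""
    if weights is None:
        weights = [1.0] * len(jt.cliques)
    if len(weights) != len(jt.cliques):
        raise ValueError("one weight per clique required")
    paths = []
    if len(jt.cliques) == 1:
        ids = (jt.root,)
        return [
            CliquePath(0, ids, (weights[jt.root],), (jt.cliques[jt.root],))
        ]
    for pid, leaf in enumerate(jt.leaves()):
        ids = tuple(jt.path_between(jt.root, leaf))
        paths.append(
            CliquePath(
                pid,
                ids,
                tuple(weights[i] for i in ids),
                tuple(jt.cliques[i] for i in ids),
            )
        )
    return paths


def _score(sp: SubPath, policy: ScoringPolicy) -> SubPath:
    o = policy.running_scores(sp.weights)
    r = max(o)
    m = o.index(r) + 1  # first position attaining the maximum, 1-based
    sp.o = tuple(o)
    sp.r = r
    sp.m = m
    sp.r_star = policy.standardize(r, m)
    return sp


def extract_subpaths(
    path: CliquePath, alpha: float = 0.05, policy: ScoringPolicy = DEFAULT_POLICY
) -> list[SubPath]:
    """Candidate sub-paths of one path.

    Returns every maximal run of consecutive meaningful cliques, plus, for
    each pair of runs separated by exactly one non-meaningful clique, the
    bridged segment joining them. A path without meaningful cliques yields
    an empty list.
    """
    meaningful = [w < alpha for w in path.weights]
    runs: list[tuple[int, int]] = []  # [start, stop) half-open
    i = 0
    L = len(path)
    while i < L:
        if meaningful[i]:
            j = i
            while j < L and meaningful[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    segments: list[tuple[int, int]] = list(runs)
    for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
        if s2 - e1 == 1:  # exactly one non-meaningful clique between runs
            segments.append((s1, e2))
    out = []
    for s, e in sorted(set(segments)):
        sp = SubPath(
            path_id=path.path_id,
            start=s,
            clique_ids=path.clique_ids[s:e],
            weights=path.weights[s:e],
            genes_by_clique=path.genes_by_clique[s:e],
        )
        out.append(_score(sp, policy))
    return out


def relevance(
    weights, policy: ScoringPolicy = DEFAULT_POLICY
) -> tuple[float, int]:
    """Relevance of a weight sequence: (max running score, first argmax)."""
    weights = list(weights)
    if not weights:
        raise ValueError("empty sub-path")
    o = policy.running_scores(weights)
    r = max(o)
    return r, o.index(r) + 1


def standardized_relevance(
    r: float, m: int, policy: ScoringPolicy = DEFAULT_POLICY
) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return policy.standardize(r, m)


def best_subpath(subpaths: list[SubPath]) -> SubPath | None:
    """Winner by r*; ties broken by longer sub-path, then earlier start."""
    if not subpaths:
        return None
    return max(subpaths, key=lambda s: (s.r_star, s.length, -s.start))


def subpath_dissimilarity(
    A: SubPath, B: SubPath, policy: ScoringPolicy = DEFAULT_POLICY
) -> float:
    return policy.dissimilarity(A.genes, B.genes)


def prune_subpaths(
    best: list[SubPath],
    t: float = 0.2,
    alpha: float = 0.05,
    policy: ScoringPolicy = DEFAULT_POLICY,
) -> ClipperReport:
    """Collapse near-duplicate winners by average-linkage clustering.

    The pairwise dissimilarity tree is cut at height ``t``; each cluster is
    represented by its maximum-r* member (ties to longer, then earlier).
    """
    best = list(best)
    if not best:
        return ClipperReport([], [], {}, alpha, t)
    if len(best) == 1:
        return ClipperReport(best, list(best), {0: 1}, alpha, t)
    n = len(best)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = policy.dissimilarity(best[i].genes, best[j].genes)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=t, criterion="distance")
    reps = []
    for lab in sorted(set(labels)):
        members = [best[i] for i in range(n) if labels[i] == lab]
        reps.append(
            max(members, key=lambda s: (s.r_star, s.length, -s.start, -s.path_id))
        )
    # Average linkage bounds within-cluster dissimilarities but not every
    # cross-cluster pair; a greedy pass (best r* first) enforces that the
    # reported representatives are pairwise more dissimilar than t.
    reps.sort(key=lambda s: (-s.r_star, -s.length, s.start, s.path_id))
    kept: list[SubPath] = []
    for sp in reps:
        if all(policy.dissimilarity(sp.genes, k.genes) > t for k in kept):
            kept.append(sp)
    cluster_of = {i: int(labels[i]) for i in range(n)}
    return ClipperReport(best, kept, cluster_of, alpha, t)


def mine(
    jt: JunctionTree,
    weights: list[float],
    alpha: float = 0.05,
    t: float = 0.2,
    policy: ScoringPolicy = DEFAULT_POLICY,
) -> ClipperReport:
    """Full step 2 for one junction tree: paths -> sub-paths -> best -> prune."""
    best = []
    for path in enumerate_paths(jt, weights):
        winner = best_subpath(extract_subpaths(path, alpha=alpha, policy=policy))
        if winner is not None:
            best.append(winner)
    # identical winners can be reached from several paths; de-duplicate
    seen, uniq = set(), []
    for sp in best:
        key = sp.clique_ids
        if key not in seen:
            seen.add(key)
            uniq.append(sp)
    return prune_subpaths(uniq, t=t, alpha=alpha, policy=policy)
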