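"""Neighbor-Joining trees from group distance matrices, with bootstrap support.

The Saitou-Nei agglomeration is applied to the among-group Mahalanobis
matrix; on an additive matrix the tree metric reproduces the input
exactly.  Cluster reliability is assessed by stratified specimen
bootstrap: specimens are redrawn with replacement within each group, the
ordination -> Mahalanobis -> NJ chain is rerun per replicate, and each
internal edge of the observed tree is annotated with the percentage of
replicate trees containing the same leaf bipartition.

Negative branch lengths that NJ can produce on non-additive matrices are
reported as-is and flagged; a clamp-to-zero option exists for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .group_stats import GroupDistanceMatrix, mahalanobis_matrix
from .ordination import retain_for_variance, total_pca


@dataclass
class NJTree:
    """Unrooted tree: leaves carry group labels, edges carry lengths.

    Nodes 0..g-1 are leaves (in label order); higher ids are internal.
    ``supports`` maps internal-edge bipartitions (canonical frozenset of
    leaf labels on the side not containing the first label) to bootstrap
    percentages.
    """

    labels: tuple[str, ...]
    adjacency: dict[int, dict[int, float]]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def g(self) -> int:
        return len(self.labels)

    @property
    def has_negative_lengths(self) -> bool:
        return any(
            length < 0 for nbrs in self.adjacency.values() for length in nbrs.values()
        )

    def _leaves_behind(self, node: int, parent: int) -> frozenset:
        if node < self.g:
            return frozenset([self.labels[node]])
        out: set = set()
        for child in self.adjacency[node]:
            if child != parent:
                out |= self._leaves_behind(child, node)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset]:
        """Canonical nontrivial leaf bipartitions, one per internal edge.

        Each bipartition is the side not containing the lexicographically
        smallest label, so the representation is label-permutation stable.
        """
        anchor = min(self.labels)
        out = set()
        seen = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                side = self._leaves_behind(v, u)
                if 1 < len(side) < self.g - 1:  # internal edges only
                    out.add(side if anchor not in side else frozenset(self.labels) - side)
        return out

    def terminal_branch_lengths(self) -> dict[str, float]:
        out = {}
        for leaf in range(self.g):
            ((_, length),) = self.adjacency[leaf].items()
            out[self.labels[leaf]] = length
        return out

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        start = self.labels.index(label_a)
        goal = self.labels.index(label_b)
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length in self.adjacency[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + length))
        raise ValueError("disconnected tree")

    def cophenetic_matrix(self) -> GroupDistanceMatrix:
        g = self.g
        D = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                D[i, j] = D[j, i] = self.path_length(self.labels[i], self.labels[j])
        return GroupDistanceMatrix(labels=self.labels, D=D)


def neighbor_joining(dist: GroupDistanceMatrix) -> NJTree:
    """Saitou-Nei Neighbor-Joining on a symmetric zero-diagonal matrix.

    Deterministic: Q-matrix ties are broken by the lexicographically smallest
    active-node index pair.  Exactly recovers additive matrices.
    """
    labels = dist.labels
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two taxa")
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(g)}
    if g == 2:
        warnings.warn("fewer than 3 taxa: returning the trivial single-edge tree")
        d = float(dist.D[0, 1])
        adjacency[0][1] = d
        adjacency[1][0] = d
        return NJTree(labels=labels, adjacency=adjacency)

    D = {
        (i, j): float(dist.D[i, j])
        for i in range(g)
        for j in range(g)
        if i != j
    }
    active = list(range(g))
    next_id = g

    def _join(i: int, j: int, li: float, lj: float) -> int:
        nonlocal next_id
        u = next_id
        next_id += 1
        adjacency[u] = {}
        adjacency[u][i] = li
        adjacency.setdefault(i, {})[u] = li
        adjacency[u][j] = lj
        adjacency.setdefault(j, {})[u] = lj
        return u

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[(i, j)] - R[i] - R[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and (i, j) < best
                ):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = D[(i, j)]
        li = dij / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        u = _join(i, j, li, lj)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
            D[(u, k)] = D[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = sorted(active)
    li = 0.5 * (D[(i, j)] + D[(i, k)] - D[(j, k)])
    lj = 0.5 * (D[(i, j)] + D[(j, k)] - D[(i, k)])
    lk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
    u = next_id
    adjacency[u] = {}
    for node, length in ((i, li), (j, lj), (k, lk)):
        adjacency[u][node] = length
        adjacency.setdefault(node, {})[u] = length
    return NJTree(labels=labels, adjacency=adjacency)


def clamp_negative_lengths(tree: NJTree) -> NJTree:
    """Copy of the tree with negative branch lengths truncated to zero (display)."""
    adjacency = {
        u: {v: max(length, 0.0) for v, length in nbrs.items()}
        for u, nbrs in tree.adjacency.items()
    }
    return NJTree(labels=tree.labels, adjacency=adjacency, supports=dict(tree.supports))


def to_newick(tree: NJTree, decimals: int = 6) -> str:
    """Newick string with branch lengths; bootstrap supports label internal nodes."""
    if tree.g == 2:
        d = tree.adjacency[0][1]
        return (
            f"({tree.labels[0]}:{d / 2:.{decimals}f},"
            f"{tree.labels[1]}:{d / 2:.{decimals}f});"
        )
    root = max(tree.adjacency)  # last-created internal node

    def render(node: int, parent: int) -> str:
        if node < tree.g:
            label = tree.labels[node]
        else:
            children = [
                render(child, node)
                for child in sorted(tree.adjacency[node])
                if child != parent
            ]
            side = tree._leaves_behind(node, parent) if parent >= 0 else None
            support = ""
            if side is not None and 1 < len(side) < tree.g - 1:
                canon = (
                    side
                    if min(tree.labels) not in side
                    else frozenset(tree.labels) - side
                )
                if canon in tree.supports:
                    support = str(int(round(tree.supports[canon])))
            label = f"({','.join(children)}){support}"
        if parent < 0:
            return label
        length = tree.adjacency[parent][node]
        return f"{label}:{length:.{decimals}f}"

    return render(root, -1) + ";"


BootstrapResampler = Callable[[np.random.Generator], GroupDistanceMatrix]


def bootstrap_supports(
    dist: GroupDistanceMatrix,
    resampler: BootstrapResampler,
    n_reps: int = 1000,
    seed: int | None = None,
) -> NJTree:
    """NJ tree of ``dist`` with bootstrap support on each internal edge.

    The resampler produces one replicate distance matrix per call; the
    support of an internal edge is the percentage of replicate NJ trees
    containing the same leaf bipartition.  Replicates whose distance matrix
    cannot be computed (singular covariance) are skipped and counted, with a
    warning when more than 5% are skipped.
    """
    observed = neighbor_joining(dist)
    target = observed.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    done = 0
    for _ in range(n_reps):
        try:
            rep_dist = resampler(rng)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        rep_tree = neighbor_joining(rep_dist)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1
    if skipped > 0.05 * n_reps:
        warnings.warn(f"{skipped}/{n_reps} bootstrap replicates skipped")
    if done == 0:
        raise ValueError("all bootstrap replicates failed")
    observed.supports = {bp: 100.0 * c / done for bp, c in counts.items()}
    return observed


def stratified_score_resampler(
    tangent: np.ndarray,
    groups: Sequence[str],
    variance_threshold: float = 0.95,
) -> BootstrapResampler:
    """Specimen bootstrap for the ordination -> Mahalanobis chain.

    Specimens are redrawn with replacement within each group (preserving
    group sizes), then total PCA, variance-based PC retention and the
    Mahalanobis matrix are recomputed on the replicate.  The Procrustes
    alignment is treated as fixed preprocessing.
    """
    tangent = np.asarray(tangent, dtype=float)
    groups = np.asarray(groups)
    by_group = {g: np.where(groups == g)[0] for g in np.unique(groups)}

    def resample(rng: np.random.Generator) -> GroupDistanceMatrix:
        idx = np.concatenate(
            [rng.choice(members, size=len(members), replace=True)
             for members in by_group.values()]
        )
        rep_tangent = tangent[idx]
        rep_groups = groups[idx]
        scores = retain_for_variance(total_pca(rep_tangent), variance_threshold)
        return mahalanobis_matrix(scores, rep_groups)

    return resample
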