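"""Neighbor-Joining construction, Newick export, bootstrap supports."""

import itertools

import numpy as np
import pytest

from craniomorph.group_stats import (
    GroupDistanceMatrix,
    load_published_cultural_distances,
    mahalanobis_matrix,
)
from craniomorph.nj_trees import (
    bootstrap_supports,
    clamp_negative_lengths,
    neighbor_joining,
    stratified_score_resampler,
    to_newick,
)


def random_additive_matrix(rng, n_taxa):
    """Distance matrix generated from a random binary tree with random lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # build a random unrooted binary tree by sequential leaf insertion
    adjacency = {0: {1: rng.uniform(0.5, 3)}, 1: {0: 0.0}}
    adjacency[1][0] = adjacency[0][1]
    next_node = n_taxa
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        mid, next_node = next_node, next_node + 1
        old = adjacency[u].pop(v)
        adjacency[v].pop(u)
        split = rng.uniform(0.2, 0.8) * old
        adjacency.setdefault(mid, {})
        adjacency[u][mid] = split
        adjacency[mid][u] = split
        adjacency[mid][v] = old - split
        adjacency[v][mid] = old - split
        lw = rng.uniform(0.5, 3)
        adjacency[mid][leaf] = lw
        adjacency.setdefault(leaf, {})[mid] = lw
        edges = [
            (a, b) for a in adjacency for b in adjacency[a] if a < b
        ]
    D = np.zeros((n_taxa, n_taxa))

    def path(start, goal):
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length in adjacency[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + length))

    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = path(i, j)
    return GroupDistanceMatrix(labels=tuple(labels), D=D)


class TestNeighborJoining:
    def test_four_taxon_additive_roundtrip(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix -> exact recovery
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dist = GroupDistanceMatrix(labels=("A", "B", "C", "D"), D=D)
        tree = neighbor_joining(dist)
        np.testing.assert_allclose(tree.cophenetic_matrix().D, D, atol=1e-9)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        terms = tree.terminal_branch_lengths()
        assert terms == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(GroupDistanceMatrix(labels=("A", "B", "C"), D=D))
        terms = tree.terminal_branch_lengths()
        np.testing.assert_allclose(terms["A"], 1.0, atol=1e-12)  # (3+4-5)/2
        np.testing.assert_allclose(terms["B"], 2.0, atol=1e-12)
        np.testing.assert_allclose(terms["C"], 3.0, atol=1e-12)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_consistency(self, n_taxa):
        for seed in range(5):
            rng = np.random.default_rng(100 * n_taxa + seed)
            dist = random_additive_matrix(rng, n_taxa)
            tree = neighbor_joining(dist)
            np.testing.assert_allclose(tree.cophenetic_matrix().D, dist.D, atol=1e-9)

    def test_skbio_oracle_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        dist = random_additive_matrix(rng, 6)
        tree = neighbor_joining(dist)
        dm = skbio.DistanceMatrix(dist.D, ids=list(dist.labels))
        ref = skbio.tree.nj(dm)
        ref_bps = set()
        for node in ref.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(dist.labels) - 1:
                ref_bps.add(
                    tips
                    if min(dist.labels) not in tips
                    else frozenset(dist.labels) - tips
                )
        assert tree.bipartitions() == ref_bps

    def test_label_permutation_equivariance(self, rng):
        dist = random_additive_matrix(rng, 6)
        perm = rng.permutation(6)
        permuted = GroupDistanceMatrix(
            labels=tuple(np.array(dist.labels)[perm]),
            D=dist.D[np.ix_(perm, perm)],
        )
        assert neighbor_joining(dist).bipartitions() == neighbor_joining(
            permuted
        ).bipartitions()

    def test_negative_lengths_flagged_not_truncated(self):
        D = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 0.2], [6, 6, 0.2, 0]], dtype=float
        )
        tree = neighbor_joining(GroupDistanceMatrix(labels=("a", "b", "c", "d"), D=D))
        if tree.has_negative_lengths:
            clamped = clamp_negative_lengths(tree)
            assert not clamped.has_negative_lengths


class TestPublishedCranialTree:
    """The printed cranial distance matrix is a fixed in-study input."""

    @staticmethod
    def _brute_force_best(dist):
        # least-squares branch lengths over all 15 five-taxon topologies
        labels = dist.labels
        pairs = list(itertools.combinations(labels, 2))
        d = np.array([dist.to_frame().loc[a, b] for a, b in pairs])
        best = None
        seen = set()
        for lone in labels:
            rest = [l for l in labels if l != lone]
            for cherry in itertools.combinations(rest, 2):
                other = tuple(sorted(set(rest) - set(cherry)))
                key = frozenset([frozenset(cherry), frozenset(other)])
                if (lone, key) in seen:
                    continue
                seen.add((lone, key))
                edge_of = {l: i for i, l in enumerate(labels)}
                X, Y = 5, 6
                rows = []
                in_a, in_b = set(cherry), set(other)
                for p, q in pairs:
                    vec = np.zeros(7)
                    vec[edge_of[p]] = vec[edge_of[q]] = 1
                    if (p in in_a) != (q in in_a):
                        vec[X] = 1
                    if (p in in_b) != (q in in_b):
                        vec[Y] = 1
                    rows.append(vec)
                A = np.array(rows)
                sol, *_ = np.linalg.lstsq(A, d, rcond=None)
                rss = np.sum((A @ sol - d) ** 2)
                if best is None or rss < best[0]:
                    best = (rss, lone, cherry, other, sol)
        return best

    def test_hunter_gatherer_terminal_branch_longest(self):
        dist = load_published_cultural_distances("cranium")
        tree = neighbor_joining(dist)
        terms = tree.terminal_branch_lengths()
        assert max(terms, key=terms.get) == "Mesolithic"
        # same claim in the brute-force least-squares best tree
        rss, lone, cherry, other, sol = self._brute_force_best(dist)
        term_ls = dict(zip(dist.labels, sol[:5]))
        assert max(term_ls, key=term_ls.get) == "Mesolithic"

    def test_a_group_nearest_farmer_is_c_group(self):
        dist = load_published_cultural_distances("cranium")
        tree = neighbor_joining(dist)
        farmers = ["C-group", "Meroitic", "Pharaonic"]
        paths = {f: tree.path_length("A-group", f) for f in farmers}
        assert min(paths, key=paths.get) == "C-group"

    def test_mandible_tree_same_displaced_leaf(self):
        dist = load_published_cultural_distances("mandible")
        terms = neighbor_joining(dist).terminal_branch_lengths()
        assert max(terms, key=terms.get) == "Mesolithic"


class TestNewick:
    def test_three_taxon_string_roundtrip(self):
        dendropy = pytest.importorskip("dendropy")
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        tree = neighbor_joining(GroupDistanceMatrix(labels=("A", "B", "C"), D=D))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == {"A", "B", "C"}
        for leaf in parsed.leaf_node_iter():
            np.testing.assert_allclose(leaf.edge.length, 1.0, atol=1e-9)

    def test_random_tree_bipartitions_roundtrip(self, rng):
        dendropy = pytest.importorskip("dendropy")
        dist = random_additive_matrix(rng, 7)
        tree = neighbor_joining(dist)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        parsed_bps = set()
        for edge in parsed.preorder_edge_iter():
            head = edge.head_node
            if head and not head.is_leaf() and head.parent_node:
                tips = frozenset(t.taxon.label for t in head.leaf_iter())
                if 1 < len(tips) < 7 - 1:
                    parsed_bps.add(
                        tips
                        if min(dist.labels) not in tips
                        else frozenset(dist.labels) - tips
                    )
        assert parsed_bps == tree.bipartitions()

    def test_supports_only_on_internal_edges(self):
        dist = load_published_cultural_distances("cranium")
        tree = bootstrap_supports(dist, lambda rng: dist, n_reps=5, seed=0)
        nwk = to_newick(tree)
        # leaves carry no support labels: every leaf is immediately followed
        # by a colon, and supports only appear after ')'
        for label in dist.labels:
            assert f"{label}:" in nwk
        assert len(tree.supports) == len(tree.bipartitions())


class TestBootstrap:
    def test_degenerate_resampler_gives_100(self):
        dist = load_published_cultural_distances("cranium")
        tree = bootstrap_supports(dist, lambda rng: dist, n_reps=50, seed=1)
        assert all(v == 100.0 for v in tree.supports.values())

    def test_huge_separation_saturates(self, rng):
        # 4 groups separated by ~20 within-group SDs: every edge at 100%
        centers = np.array(
            [[0, 0], [20, 0], [100, 80], [120, 80]], dtype=float
        )
        scores = np.vstack(
            [rng.standard_normal((25, 2)) + c for c in centers]
        )
        groups = np.repeat(["a", "b", "c", "d"], 25)
        dist = mahalanobis_matrix(scores, groups)
        res = stratified_score_resampler(scores, groups, variance_threshold=1.0)
        tree = bootstrap_supports(dist, res, n_reps=100, seed=3)
        assert all(v == 100.0 for v in tree.supports.values())

    def test_null_homogeneous_cloud_low_support(self):
        # random labels on one cloud: supports well below saturation
        medians = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            scores = r.standard_normal((100, 5))
            groups = np.repeat(["a", "b", "c", "d", "e"], 20)
            dist = mahalanobis_matrix(scores, groups)
            res = stratified_score_resampler(scores, groups, variance_threshold=1.0)
            tree = bootstrap_supports(dist, res, n_reps=100, seed=seed)
            medians.append(np.median(list(tree.supports.values())))
        assert np.median(medians) < 70

    def test_reproducible_given_seed(self, rng):
        scores = rng.standard_normal((60, 4))
        scores[:20] += [3, 0, 0, 0]
        groups = np.repeat(["a", "b", "c"], 20)
        dist = mahalanobis_matrix(scores, groups)
        res = stratified_score_resampler(scores, groups)
        t1 = bootstrap_supports(dist, res, n_reps=60, seed=9)
        t2 = bootstrap_supports(dist, res, n_reps=60, seed=9)
        assert t1.supports == t2.supports
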