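"""Chord distance, neighbor-joining, bootstrap support, Newick, PCA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import sebpanel as sp
from conftest import matrix_from_rows
from sebpanel.divergence import (
    DistanceMatrix,
    GroupFrequencyTable,
    TreeNode,
    chord_distance,
    chord_distance_matrix,
    newick_string,
    nj_tree,
)

CHORD_MAX = (2.0 / math.pi) * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# chord distance
# ---------------------------------------------------------------------------

class TestChordDistance:
    def test_identical_tables_give_zero(self):
        freqs = [{"A": 0.3, "C": 0.7}, {"G": 1.0}]
        assert chord_distance(freqs, freqs) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_closed_form(self):
        d = chord_distance([{"A": 1.0}], [{"C": 1.0}])
        assert d == pytest.approx(CHORD_MAX, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
           st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    def test_symmetry_on_random_tables(self, ps, qs):
        n = min(len(ps), len(qs))
        fx = [{"A": p, "C": 1.0 - p} for p in ps[:n]]
        fy = [{"A": q, "C": 1.0 - q} for q in qs[:n]]
        assert chord_distance(fx, fy) == pytest.approx(chord_distance(fy, fx))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_frequency_gap_single_locus(self, p, q1, q2):
        """Moving the second group's frequency further from the first's
        (on the same side) can only increase the chord distance."""
        assume((q1 - p) * (q2 - p) >= 0)  # same side of p
        near, far = sorted((q1, q2), key=lambda q: abs(p - q))
        d_near = chord_distance([{"A": p, "C": 1 - p}], [{"A": near, "C": 1 - near}])
        d_far = chord_distance([{"A": p, "C": 1 - p}], [{"A": far, "C": 1 - far}])
        assert d_near <= d_far + 1e-9

    def test_pooled_aggregate_averages_inside_sqrt(self):
        fx = [{"A": 1.0}, {"A": 1.0}]
        fy = [{"C": 1.0}, {"A": 1.0}]  # one maximal locus, one identical
        mean = chord_distance(fx, fy, aggregate="mean")
        pooled = chord_distance(fx, fy, aggregate="pooled")
        assert mean == pytest.approx(CHORD_MAX / 2)
        assert pooled == pytest.approx((2 / math.pi) * math.sqrt(2 * 0.5))

    def test_mismatched_locus_lists_raise(self):
        with pytest.raises(ValueError):
            chord_distance([{"A": 1.0}], [{"A": 1.0}, {"C": 1.0}])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def tree_distance_matrix(tree: TreeNode, labels):
    got_labels, dist = tree.pairwise_leaf_distances()
    order = [got_labels.index(l) for l in labels]
    return dist[np.ix_(order, order)]


def random_additive_matrix(labels, rng):
    """Distance matrix of a random binary tree over *labels* (path-length
    additive by construction); returns (matrix, bipartitions of the tree)."""
    nodes = [TreeNode(name=l) for l in labels]
    lengths = {}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes.pop(j), nodes.pop(i)
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.05, 1.0))
        root.children.append(child)
    dist = tree_distance_matrix(root, labels)
    return dist, root.bipartitions()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
        tree = nj_tree(d)
        lengths = {child.name: child.length for child in tree.children}
        assert lengths == {"A": pytest.approx(2.0), "B": pytest.approx(3.0),
                           "C": pytest.approx(7.0)}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-drawn tree: ((A:2,B:3):1,C:4,D:5) -> additive distances
        values = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 0, 0],
        ], float)
        values[3, 2] = values[2, 3] = 9
        d = DistanceMatrix(["A", "B", "C", "D"], values)
        tree = nj_tree(d)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        np.testing.assert_allclose(
            tree_distance_matrix(tree, ["A", "B", "C", "D"]), values, atol=1e-12
        )

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (6, 1), (6, 2), (8, 3)])
    def test_additive_matrices_reproduce_path_lengths(self, n_taxa, seed):
        labels = [f"t{k}" for k in range(n_taxa)]
        rng = np.random.default_rng(seed)
        values, bipartitions = random_additive_matrix(labels, rng)
        tree = nj_tree(DistanceMatrix(labels, values))
        assert tree.bipartitions() == bipartitions
        np.testing.assert_allclose(
            tree_distance_matrix(tree, labels), values, atol=1e-9
        )

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        labels = [f"t{k}" for k in range(7)]
        rng = np.random.default_rng(9)
        values, _ = random_additive_matrix(labels, rng)
        mine = tree_distance_matrix(nj_tree(DistanceMatrix(labels, values)), labels)
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(values, ids=labels))
        ref = ref_tree.tip_tip_distances(labels).data
        np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_six_taxa_least_squares_optimal_among_all_topologies(self):
        """On a noisy near-additive matrix, the NJ topology attains the
        minimal least-squares residual over all 105 unrooted 6-leaf
        topologies (exhaustive enumeration)."""
        labels = [f"t{k}" for k in range(6)]
        rng = np.random.default_rng(5)
        values, _ = random_additive_matrix(labels, rng)
        noise = rng.normal(0.0, 0.01, size=values.shape)
        noisy = values + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        noisy = np.clip(noisy, 0.0, None)
        tree = nj_tree(DistanceMatrix(labels, noisy))
        best_res, best_parts, count = _best_topology_by_least_squares(labels, noisy)
        assert count == 105
        assert tree.bipartitions() == best_parts

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["A", "B"], np.array([[1.0, 0], [0, 0]]))


def _all_unrooted_topologies(labels):
    """Yield every unrooted binary topology as a set of bipartitions,
    built by inserting leaves onto every edge of smaller trees."""
    first = TreeNode(children=[TreeNode(name=l) for l in labels[:3]])

    def clone(node):
        out = TreeNode(name=node.name)
        out.children = [clone(c) for c in node.children]
        return out

    def edges(node):
        for child in node.children:
            yield node, child
            yield from edges(child)

    trees = [first]
    for leaf in labels[3:]:
        nxt = []
        for tree in trees:
            n_edges = len(list(edges(tree)))
            for e_idx in range(n_edges):
                t = clone(tree)
                parent, child = list(edges(t))[e_idx]
                mid = TreeNode(children=[child, TreeNode(name=leaf)])
                parent.children[parent.children.index(child)] = mid
                nxt.append(t)
        trees = nxt
    return [t.bipartitions() for t in trees]


def _best_topology_by_least_squares(labels, values):
    """Fit non-negative branch lengths to every topology; return the
    minimal residual, its bipartition set, and the number of topologies."""
    from scipy.optimize import nnls

    pairs = list(itertools.combinations(range(len(labels)), 2))
    target = np.array([values[i, j] for i, j in pairs])
    best = (math.inf, None)
    topologies = _all_unrooted_topologies(labels)
    for parts in topologies:
        # edges: one per leaf (trivial split) + one per bipartition
        splits = [frozenset({l}) for l in labels] + [set(p) for p in parts]
        design = np.zeros((len(pairs), len(splits)))
        for row, (i, j) in enumerate(pairs):
            for col, split in enumerate(splits):
                if (labels[i] in split) != (labels[j] in split):
                    design[row, col] = 1.0
        _, residual = nnls(design, target)
        if residual < best[0]:
            best = (residual, parts)
    return best[0], best[1], len(topologies)


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def fully_separated_matrix(n_groups=4, n_per_group=5, n_loci=30):
    """Each group fixed for its own allele at every locus: every replicate
    reproduces the same separation."""
    rows = {}
    for gi in range(n_groups):
        allele = "ACGT"[gi]
        for k in range(n_per_group):
            rows[f"g{gi}_{k}"] = [allele * 2] * n_loci
    return matrix_from_rows(rows, group_of=lambda ind: ind.split("_")[0])


class TestBootstrap:
    def test_full_support_on_fully_separated_groups(self):
        matrix, groups = fully_separated_matrix()
        tree = sp.bootstrap_support(matrix, groups, n_boot=100, seed=0)
        supports = [n.support for n in tree.walk() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_four_taxa_have_exactly_one_internal_bipartition(self):
        matrix, groups = fully_separated_matrix()
        tree = sp.bootstrap_support(matrix, groups, n_boot=10, seed=0)
        assert len(tree.bipartitions()) == 1

    def test_same_seed_reproduces_supports(self, clean_cohort):
        matrix, groups, _ = clean_cohort
        t1 = sp.bootstrap_support(matrix, groups, n_boot=50, seed=3)
        t2 = sp.bootstrap_support(matrix, groups, n_boot=50, seed=3)
        assert newick_string(t1) == newick_string(t2)

    def test_supports_invariant_to_locus_and_individual_order(self, clean_cohort):
        matrix, groups, _ = clean_cohort
        rng = np.random.default_rng(4)
        shuffled = matrix.subset_loci([int(j) for j in rng.permutation(matrix.n_loci)])
        shuffled = shuffled.subset_individuals(
            list(rng.permutation(matrix.individuals)))
        t1 = sp.bootstrap_support(matrix, groups, n_boot=50, seed=3)
        t2 = sp.bootstrap_support(shuffled, groups, n_boot=50, seed=3)
        assert newick_string(t1) == newick_string(t2)

    def test_n_boot_validation(self, clean_cohort):
        matrix, groups, _ = clean_cohort
        with pytest.raises(ValueError):
            sp.bootstrap_support(matrix, groups, n_boot=0)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

class TestNewick:
    def test_three_leaf_star_shape(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        s = newick_string(nj_tree(d))
        assert s == "(A:1.000000,B:1.000000,C:1.000000);"

    def test_support_written_as_internal_label(self, tmp_path):
        matrix, groups = fully_separated_matrix()
        tree = sp.bootstrap_support(matrix, groups, n_boot=100, seed=0)
        for node in tree.walk():
            if node.support is not None:
                node.support = 87.0
        path = tmp_path / "t.nwk"
        sp.write_newick(tree, path)
        assert ")87:" in path.read_text()

    def test_write_read_write_is_byte_stable(self, clean_cohort, tmp_path):
        matrix, groups, _ = clean_cohort
        tree = sp.bootstrap_support(matrix, groups, n_boot=20, seed=1)
        path = tmp_path / "t.nwk"
        sp.write_newick(tree, path)
        text1 = path.read_text()
        back = sp.read_newick(path)
        sp.write_newick(back, path)
        assert path.read_text() == text1


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_percent_variance_sums_to_100(self, clean_cohort):
        matrix, _, _ = clean_cohort
        result = sp.pca(matrix)
        assert result.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(result.explained_pct) <= 1e-9).all()

    def test_duplicated_individual_gets_identical_coordinates(self):
        rows = {"a": ["CC", "CT", "TT"], "b": ["CT", "TT", "CC"],
                "c": ["TT", "CC", "CT"]}
        rows["a_copy"] = list(rows["a"])
        matrix = matrix_from_rows(rows)
        result = sp.pca(matrix)
        ia = result.individuals.index("a")
        ib = result.individuals.index("a_copy")
        np.testing.assert_allclose(result.coordinates[ia],
                                   result.coordinates[ib], atol=1e-9)

    def test_two_fixed_groups_are_rank_one(self):
        rows = {f"a{k}": ["CC"] * 10 for k in range(6)}
        rows.update({f"b{k}": ["TT"] * 10 for k in range(6)})
        matrix = matrix_from_rows(rows)
        result = sp.pca(matrix)
        assert result.explained_pct[0] == pytest.approx(100.0, abs=1e-9)
        pc1 = result.coordinates[:, 0]
        a_side = pc1[:6]
        b_side = pc1[6:]
        assert (a_side.max() < b_side.min()) or (b_side.max() < a_side.min())

    def test_matches_sklearn_up_to_sign(self, clean_cohort):
        sklearn = pytest.importorskip("sklearn.decomposition")
        matrix, _, _ = clean_cohort
        result = sp.pca(matrix)
        # rebuild the imputed dosage matrix independently
        from sebpanel.model import MISSING_CODE
        cols = []
        for j in range(matrix.n_loci):
            calls = matrix.locus_calls(j)
            typed = calls[:, 0] != MISSING_CODE
            first = int(calls[typed].min())
            dose = (calls == first).sum(axis=1).astype(float)
            dose[~typed] = dose[typed].mean()
            cols.append(dose)
        x = np.column_stack(cols)
        ref = sklearn.PCA(n_components=3).fit(x)
        ref_coords = ref.transform(x)
        for k in range(3):
            mine = result.coordinates[:, k]
            theirs = ref_coords[:, k]
            agreement = max(abs(np.corrcoef(mine, theirs)[0, 1]), 0.0)
            assert agreement > 1 - 1e-9

    def test_all_missing_locus_dropped_with_warning(self):
        matrix = matrix_from_rows({"a": ["CC", "NN"], "b": ["CT", "NN"],
                                   "c": ["TT", "NN"]})
        with pytest.warns(UserWarning, match="dropped"):
            result = sp.pca(matrix)
        assert result.loci == ["L1"]

    def test_group_frequency_table_from_matrix(self, clean_cohort):
        matrix, groups, truth = clean_cohort
        table = GroupFrequencyTable.from_matrix(matrix, groups)
        t = truth.loci[0]  # a diagnostic locus: fixed in both pair groups
        g1, g2 = t.pair
        a1 = next(a for a, p in t.freqs[g1].items() if p == 1.0)
        assert table.freqs[g1][t.locus_id] == {a1: 1.0}
        d = chord_distance_matrix(table)
        assert d.get(g1, g2) > 0
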