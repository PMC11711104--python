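"""Between-group divergence: chord distance, neighbor-joining, PCA.

The divergence pipeline summarises a cohort as per-group allele
frequencies, measures pairwise separation with the Cavalli-Sforza &
Edwards chord distance

    f_l  = sum_j sqrt(x_lj * y_lj)          (per-locus cosine of the angle
    d_l  = (2/pi) * sqrt(2 * (1 - f_l))      between sqrt-frequency vectors)
    D_CE = mean_l d_l

builds an unrooted tree with the canonical Saitou-Nei neighbor-joining
agglomeration, and attaches node support from bootstrap resampling over
loci. Published chord-distance software differs in whether the average
over loci is taken outside (default here, ``aggregate="mean"``) or inside
the square root (``aggregate="pooled"``); both are provided.

Individual-level structure is summarised by PCA on the mean-imputed,
column-centred allele-dosage matrix, with percent variance per axis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import MISSING_CODE, GenotypeMatrix, GroupLabels
from .stats import allele_freqs

__all__ = [
    "GroupFrequencyTable",
    "DistanceMatrix",
    "TreeNode",
    "chord_distance",
    "chord_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "pca",
    "PCAResult",
    "write_newick",
    "read_newick",
    "newick_string",
]


# ---------------------------------------------------------------------------
# Group allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class GroupFrequencyTable:
    """Per-group, per-locus allele frequencies with typed counts."""

    groups: list[str]
    loci: list[str]
    freqs: dict[str, dict[str, dict[str, float]]]  # group -> locus -> allele -> f
    counts: dict[str, dict[str, int]]              # group -> locus -> typed N

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix, groups: GroupLabels
                    ) -> "GroupFrequencyTable":
        groups.validate_against(matrix)
        names = groups.group_names
        freqs: dict[str, dict[str, dict[str, float]]] = {g: {} for g in names}
        counts: dict[str, dict[str, int]] = {g: {} for g in names}
        for g in names:
            rows = groups.indices(matrix, g)
            for j, locus in enumerate(matrix.loci):
                calls = matrix.calls[rows, j]
                typed = calls[calls[:, 0] != MISSING_CODE]
                counts[g][locus.id] = typed.shape[0]
                freqs[g][locus.id] = (
                    allele_freqs(typed) if typed.shape[0] else {}
                )
        return cls(list(names), [l.id for l in matrix.loci], freqs, counts)

    def vectors(self, group: str, loci: Sequence[str] | None = None
                ) -> list[dict[str, float]]:
        ids = self.loci if loci is None else list(loci)
        return [self.freqs[group][lid] for lid in ids]


# ---------------------------------------------------------------------------
# Chord distance
# ---------------------------------------------------------------------------

def chord_distance(
    freqs_x: Sequence[Mapping[str, float]],
    freqs_y: Sequence[Mapping[str, float]],
    aggregate: str = "mean",
) -> float:
    """Chord distance between two groups from per-locus frequency vectors.

    ``aggregate="mean"`` averages the per-locus chord distances;
    ``"pooled"`` averages the per-locus cosines inside the square root.
    Loci where either group has no frequencies (all calls missing) are
    skipped.
    """
    if len(freqs_x) != len(freqs_y):
        raise ValueError("frequency tables cover different locus lists")
    if aggregate not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    cosines = []
    for fx, fy in zip(freqs_x, freqs_y):
        if not fx or not fy:
            continue
        f = sum(math.sqrt(fx[a] * fy.get(a, 0.0)) for a in fx)
        cosines.append(min(max(f, 0.0), 1.0))
    if not cosines:
        raise ValueError("no locus is typed in both groups")
    if aggregate == "pooled":
        fbar = sum(cosines) / len(cosines)
        return (2.0 / math.pi) * math.sqrt(2.0 * (1.0 - fbar))
    return sum(
        (2.0 / math.pi) * math.sqrt(2.0 * (1.0 - f)) for f in cosines
    ) / len(cosines)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.diag(self.values).any():
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def chord_distance_matrix(
    table: GroupFrequencyTable,
    loci: Sequence[str] | None = None,
    aggregate: str = "mean",
) -> DistanceMatrix:
    """Pairwise chord distances between all groups of a frequency table."""
    names = list(table.groups)
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = chord_distance(
            table.vectors(names[i], loci), table.vectors(names[j], loci), aggregate
        )
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an unrooted tree (stored with an arbitrary trifurcating
    root). ``length`` is the branch to the parent (None at the root);
    ``support`` a bootstrap percentage on internal nodes."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge, each
        canonicalised as the side not containing the smallest leaf label."""
        all_leaves = frozenset(self.leaves())
        smallest = min(all_leaves)
        parts: set[frozenset] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            parts.add(all_leaves - side if smallest in side else side)
        return parts

    def pairwise_leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Path lengths between all leaf pairs (uses raw branch lengths)."""
        labels = sorted(self.leaves())
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def collect(node: TreeNode) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[node.name], 0.0)]
            groups = []
            for child in node.children:
                sub = collect(child)
                length = child.length or 0.0
                groups.append([(i, d + length) for i, d in sub])
            for ga, gb in itertools.combinations(groups, 2):
                for i, da in ga:
                    for j, db in gb:
                        dist[i, j] = dist[j, i] = da + db
            return [pair for g in groups for pair in g]

        collect(self)
        return labels, dist


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor-joining (Saitou & Nei) on a distance matrix.

    At each step the pair minimising ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``
    is joined; ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf). Branch
    lengths may come out negative on non-additive input; they are kept
    raw here and floored at zero only when writing Newick.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if (dist.values < 0).any():
        raise ValueError("distances must be non-negative")

    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dist.labels]
    labels: list[str] = list(dist.labels)  # tie-break label per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple | None = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            pair_key = tuple(sorted((labels[active[ai]], labels[active[aj]])))
            key = (q, pair_key)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = dij - vi
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        parent = TreeNode(children=[ni, nj_])
        # distances from the new cluster to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = TreeNode()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        nodes[a].length = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        root.children.append(nodes[a])
    _sort_children(root)
    return root


def _sort_children(node: TreeNode) -> str:
    """Canonical child order (by smallest descendant leaf); returns it."""
    if node.is_leaf:
        return node.name or ""
    keys = [_sort_children(child) for child in node.children]
    order = sorted(range(len(keys)), key=keys.__getitem__)
    node.children = [node.children[o] for o in order]
    return min(keys)


def bootstrap_support(
    matrix: GenotypeMatrix,
    groups: GroupLabels,
    n_boot: int = 1000,
    seed: int = 0,
    aggregate: str = "mean",
) -> TreeNode:
    """NJ tree from full-data chord distances with locus-bootstrap support.

    Each replicate resamples loci with replacement (same count), rebuilds
    the chord-distance matrix and NJ tree, and each internal edge of the
    full-data tree is annotated with the percentage of replicates whose
    tree contains the same leaf bipartition. Loci are resampled in sorted-id
    order, so supports do not depend on the column order of the matrix.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(groups.group_names) < 3:
        raise ValueError("a tree needs at least 3 groups")
    if matrix.n_loci < 2:
        raise ValueError("bootstrapping needs at least 2 loci")

    table = GroupFrequencyTable.from_matrix(matrix, groups)
    locus_ids = sorted(table.loci)
    tree = nj_tree(chord_distance_matrix(table, locus_ids, aggregate))

    counts: dict[frozenset, int] = {part: 0 for part in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    L = len(locus_ids)
    for _ in range(n_boot):
        resample = [locus_ids[t] for t in rng.integers(0, L, size=L)]
        rep = nj_tree(chord_distance_matrix(table, resample, aggregate))
        for part in rep.bipartitions():
            if part in counts:
                counts[part] += 1

    all_leaves = frozenset(tree.leaves())
    smallest = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        part = all_leaves - side if smallest in side else side
        node.support = 100.0 * counts[part] / n_boot
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree: TreeNode) -> str:
    """Canonical Newick: children sorted, branch lengths floored at zero
    and printed with 6 decimals, integer support as internal labels."""
    _sort_children(tree)

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(child) for child in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            body = f"({inner}){label}"
        if node.length is None:
            return body
        return f"{body}:{max(node.length, 0.0):.6f}"

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree (via Bio.Phylo) into a :class:`TreeNode`."""
    from Bio import Phylo

    clade_tree = Phylo.read(str(path), "newick")

    def convert(clade) -> TreeNode:
        node = TreeNode(
            name=clade.name,
            length=None if clade.branch_length is None else float(clade.branch_length),
            support=None if clade.confidence is None else float(clade.confidence),
        )
        node.children = [convert(c) for c in clade.clades]
        return node

    return convert(clade_tree.root)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of the centred dosage matrix."""

    individuals: list[str]
    coordinates: np.ndarray      # (n_individuals, n_axes)
    explained_pct: np.ndarray    # percent variance per axis, sums to 100
    loci: list[str]              # loci retained (all-missing ones dropped)


def pca(matrix: GenotypeMatrix) -> PCAResult:
    """PCA on allele dosages (0/1/2 copies of the lexicographically first
    observed allele per locus), with mean imputation of missing calls and
    column centring (no variance scaling).

    Axis signs are fixed by making each axis' largest-magnitude locus
    loading positive, so coordinates are reproducible across runs.
    """
    if matrix.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    dosages = []
    kept = []
    for j, locus in enumerate(matrix.loci):
        calls = matrix.locus_calls(j)
        typed = calls[:, 0] != MISSING_CODE
        if not typed.any():
            warnings.warn(f"locus {locus.id}: all calls missing, dropped from PCA",
                          stacklevel=2)
            continue
        first = int(calls[typed].min())  # lexicographically first observed allele
        dose = (calls == first).sum(axis=1).astype(float)
        dose[~typed] = dose[typed].mean()
        dosages.append(dose)
        kept.append(locus.id)
    if not kept:
        raise ValueError("no typed loci for PCA")
    x = np.column_stack(dosages)
    x -= x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s ** 2).sum()
    if total == 0:
        raise ValueError("zero total variance: all individuals identical")
    # sign convention: largest-magnitude loading positive per axis
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u * s
    pct = 100.0 * (s ** 2) / total
    return PCAResult(list(matrix.individuals), coords, pct, kept)
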