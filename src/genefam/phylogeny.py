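"""Distance-based phylogenies: p-distances, NJ, UPGMA, bootstrap supports, Newick IO.

The alignment itself is an input (constructed upstream); trees are built from
pairwise amino-acid distances after complete deletion of gapped/ambiguous
columns, matching the common distance-tree workflow for protein families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = set("-.")
AMBIGUOUS_CHARS = set("X*?")


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled taxa."""
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhylogenyError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise PhylogenyError("duplicate taxon labels")
        if not np.all(np.isfinite(self.d)):
            raise PhylogenyError("non-finite distances")
        if np.any(self.d < 0):
            raise PhylogenyError("negative distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhylogenyError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise PhylogenyError("diagonal not zero")

    def __len__(self):
        return len(self.labels)


@dataclass
class Clade:
    name: str | None = None
    branch_length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    """Rooted or unrooted tree with branch lengths and bootstrap supports."""
    root: Clade
    rooted: bool = True

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    # -- Newick ------------------------------------------------------------
    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += f"{node.support:g}"
                elif node.name:
                    label += node.name
            if node.branch_length is not None:
                label += f":{node.branch_length:.{decimals}f}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Tree":
        s = text.strip()
        if not s.endswith(";"):
            raise PhylogenyError("newick string must end with ';'")
        s = s[:-1]
        pos = 0

        def parse_clade() -> Clade:
            nonlocal pos
            node = Clade()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse_clade())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise PhylogenyError(f"newick syntax error at {pos}")
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if label:
                if node.children:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
                else:
                    node.name = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",();":
                    pos += 1
                node.branch_length = float(s[start:pos])
            return node

        root = parse_clade()
        if pos != len(s):
            raise PhylogenyError(f"trailing characters at {pos}")
        return cls(root=root, rooted=rooted)

    # -- topology ----------------------------------------------------------
    def clade_leafsets(self) -> set[frozenset[str]]:
        """Leaf sets of internal non-root clades (rooted-tree view)."""
        out = set()

        def walk(node: Clade, is_root: bool):
            if not node.is_leaf:
                if not is_root:
                    out.add(node.leaf_names())
                for c in node.children:
                    walk(c, False)

        walk(self.root, True)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side excluding the
        lexicographically smallest leaf (unrooted-tree view)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out = set()

        def walk(node: Clade, is_root: bool):
            if not node.is_leaf:
                if not is_root:
                    side = node.leaf_names()
                    if anchor in side:
                        side = all_leaves - side
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(side)
                for c in node.children:
                    walk(c, False)

        walk(self.root, True)
        return out

    def internal_nodes(self) -> list[Clade]:
        out = []

        def walk(node: Clade, is_root: bool):
            if not node.is_leaf:
                if not is_root:
                    out.append(node)
                for c in node.children:
                    walk(c, False)

        walk(self.root, True)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []

        def walk(node: Clade, depth: float):
            depth += node.branch_length or 0.0
            if node.is_leaf:
                depths.append(depth)
            for c in node.children:
                walk(c, depth)

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol


def p_distance(alignment: dict[str, str] | list[tuple[str, str]],
               deletion_mode: str = "complete") -> DistanceMatrix:
    """Pairwise p-distances after complete deletion of gap/ambiguity columns."""
    if deletion_mode != "complete":
        raise PhylogenyError(f"unsupported deletion mode {deletion_mode!r}")
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    if len(items) < 2:
        raise PhylogenyError("need at least two taxa")
    labels = [k for k, _ in items]
    seqs = [v.upper() for _, v in items]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise PhylogenyError("aligned sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    bad = GAP_CHARS | AMBIGUOUS_CHARS
    keep = ~np.any(np.isin(arr, list(bad)), axis=0)
    retained = int(keep.sum())
    if retained == 0:
        raise PhylogenyError("complete deletion removed every column")
    arr = arr[:, keep]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(labels=labels, d=d)


def poisson_distance(alignment, deletion_mode: str = "complete") -> DistanceMatrix:
    """Poisson-corrected amino-acid distance, d = -ln(1 - p)."""
    dm = p_distance(alignment, deletion_mode)
    p = dm.d
    if np.any(p >= 1.0):
        raise PhylogenyError("p-distance of 1 cannot be Poisson-corrected")
    return DistanceMatrix(labels=dm.labels, d=-np.log(1.0 - p) * (p > 0))


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative branch length: clamp to 0, move the deficit to the sister edge
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root node).

    Ties on the Q criterion go to the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with the deficit moved to the sister
    edge. The topology is deterministic given the input order.
    """
    n = len(dm)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    nodes = [Clade(name=l) for l in dm.labels]
    d = dm.d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        rs = d.sum(axis=1)
        q = (m - 2) * d - rs[:, None] - rs[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) with i < j among minima
        qmin = q.min()
        ii, jj = min((i, j) for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))) if i < j)
        li = d[ii, jj] / 2.0 + (rs[ii] - rs[jj]) / (2.0 * (m - 2))
        lj = d[ii, jj] - li
        li, lj = _clamp_pair(li, lj)
        a, b = nodes[ii], nodes[jj]
        a.branch_length, b.branch_length = li, lj
        new = Clade(children=[a, b])
        dnew = 0.5 * (d[ii] + d[jj] - d[ii, jj])
        keep = [k for k in range(m) if k not in (ii, jj)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d2
    # resolve the final three nodes with the three-point formulas
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    return Tree(root=Clade(children=[a, b, c]), rooted=False)


def upgma_tree(dm: DistanceMatrix) -> Tree:
    """UPGMA dendrogram (arithmetic-average linkage); rooted and ultrametric.

    Ties on the minimum distance merge the lowest-index pair.
    """
    n = len(dm)
    if n < 2:
        raise PhylogenyError("UPGMA needs at least 2 taxa")
    nodes = [Clade(name=l) for l in dm.labels]
    heights = [0.0] * n
    sizes = [1] * n
    d = dm.d.copy().astype(float)
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                val = d[active[ai], active[aj]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, ai, aj)
        val, ai, aj = best
        i, j = active[ai], active[aj]
        h = val / 2.0
        left, right = nodes[i], nodes[j]
        left.branch_length = h - heights[i]
        right.branch_length = h - heights[j]
        new = Clade(children=[left, right])
        # grand-average linkage: weight by cluster sizes
        wi, wj = sizes[i], sizes[j]
        newrow = (wi * d[i] + wj * d[j]) / (wi + wj)
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.append(newrow, 0.0)[:, None]])
        nodes.append(new)
        heights.append(h)
        sizes.append(wi + wj)
        k = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]
    return Tree(root=nodes[active[0]], rooted=True)


def _resample_columns(seqs: list[str], idx: np.ndarray) -> list[str]:
    return ["".join(s[i] for i in idx) for s in seqs]


def bootstrap_supports(alignment: dict[str, str] | list[tuple[str, str]],
                       builder: str = "nj", replicates: int = 100,
                       seed: int = 0, distance: str = "p") -> Tree:
    """Point-estimate tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement (within the complete-deletion
    column set, so every replicate uses the same site universe); the support
    of an internal edge is the percentage of replicates whose tree contains
    the same bipartition (NJ) or clade (UPGMA). Reproducible for fixed seed.
    """
    if replicates < 1:
        raise PhylogenyError("replicates must be >= 1")
    if builder not in ("nj", "upgma"):
        raise PhylogenyError(f"unknown builder {builder!r}")
    dist_fn = p_distance if distance == "p" else poisson_distance
    build = nj_tree if builder == "nj" else upgma_tree
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    labels = [k for k, _ in items]
    seqs = [v.upper() for _, v in items]
    # restrict to complete-deletion columns once
    bad = GAP_CHARS | AMBIGUOUS_CHARS
    arr = np.array([list(s) for s in seqs])
    keep = ~np.any(np.isin(arr, list(bad)), axis=0)
    if not keep.any():
        raise PhylogenyError("complete deletion removed every column")
    seqs = ["".join(row) for row in arr[:, keep]]
    ncols = len(seqs[0])

    point = build(dist_fn(list(zip(labels, seqs))))
    key = (lambda t: t.bipartitions()) if builder == "nj" else (lambda t: t.clade_leafsets())
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        rep_tree = build(dist_fn(list(zip(labels, _resample_columns(seqs, idx)))))
        for split in key(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in point.internal_nodes():
        side = node.leaf_names()
        if builder == "nj":
            if anchor in side:
                side = all_leaves - side
            if not (1 < len(side) < len(all_leaves) - 1):
                continue  # trivial split
        node.support = round(100.0 * counts.get(side, 0) / replicates, 1)
    return point


def assign_subfamilies(tree: Tree, anchors: dict[str, str]) -> dict[str, str]:
    """Label each leaf by the smallest enclosing clade containing anchors of one label.

    A leaf whose smallest anchored clade mixes anchor labels is "unassigned".
    """
    leaves = set(tree.leaf_names())
    for a in anchors:
        if a not in leaves:
            raise PhylogenyError(f"anchor leaf {a!r} absent from tree")
    parents: dict[int, Clade | None] = {id(tree.root): None}
    node_of_leaf: dict[str, Clade] = {}

    def walk(node: Clade):
        for c in node.children:
            parents[id(c)] = node
            walk(c)
        if node.is_leaf:
            node_of_leaf[node.name] = node

    walk(tree.root)
    labels = {}
    for leaf in leaves:
        if leaf in anchors:
            labels[leaf] = anchors[leaf]
            continue
        node: Clade | None = node_of_leaf[leaf]
        assigned = "unassigned"
        while node is not None:
            present = {anchors[a] for a in anchors if a in node.leaf_names()}
            if present:
                assigned = present.pop() if len(present) == 1 else "unassigned"
                break
            node = parents[id(node)]
        labels[leaf] = assigned
    return labels
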