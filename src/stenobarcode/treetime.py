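"""Distance-based surrogate phylogeny and simplified strict-clock dating.

A neighbor-joining (NJ) tree built from the pairwise distance matrix serves
as an exploratory phylogeny.  After rooting (midpoint, or on the edge
separating designated outgroups) the tree is made ultrametric by a
least-squares-style height fit: each internal node's height is the mean of
the root-to-tip path lengths of its subtended tips measured from that node,
with the child < parent constraint enforced.  Node heights in
substitutions/site are then converted to ages in Ma by a strict molecular
clock, age = height / rate, with uncertainty intervals obtained by drawing
the rate from a normal distribution truncated at zero (default mean 0.0016
substitutions/site/Ma, SD 0.0010).  A root-age prior (default 200 +- 50 Ma)
is used only as a sanity check: a warning is emitted if the estimated root
age falls outside mean +- 3 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.stats import truncnorm

from .distmat import DistanceMatrix

__all__ = [
    "ClockConfig",
    "DatedTree",
    "nj_tree",
    "midpoint_root",
    "outgroup_root",
    "ultrametricize",
    "clock_dates",
    "node_heights",
    "tree_from_newick",
    "tree_to_newick",
    "write_dated_tree",
]


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a complete distance matrix.

    Classic agglomeration: at each step the pair (i, j) minimizing
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j is joined (r = active clusters,
    R_i = row sum), with ties broken deterministically by cluster creation
    order (initially the matrix's label order).  Negative branch-length
    estimates, which NJ can produce on non-additive matrices, are clamped
    to zero with a warning reporting their count.  Undefined (NaN) entries
    are an error: NJ needs a complete matrix.
    """
    if matrix.n < 3:
        raise ValueError("nj_tree needs at least 3 labels")
    if matrix.undefined_pairs():
        raise ValueError(
            f"matrix has undefined entries: {matrix.undefined_pairs()}"
        )
    taxa = dendropy.TaxonNamespace(matrix.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab))
             for lab in matrix.labels]
    d = matrix.d.astype(float).copy()
    active = list(range(matrix.n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        # np.argmin is row-major: first minimal (i, j) in creation order
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        li = 0.5 * sub[i_s, j_s] + (R[i_s] - R[j_s]) / (2.0 * (r - 2))
        lj = sub[i_s, j_s] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new])
        d = np.hstack([d, np.append(new, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    a, b, c = active
    for x in active:
        tree.seed_node.add_child(nodes[x])
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        nodes[x].edge.length = float(
            0.5 * (d[x, y] + d[x, z] - d[y, z])
        )
    n_neg = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative NJ branch length(s) to 0",
                      stacklevel=2)
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _tip_path_lengths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths keyed by tip label."""
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = leaf.distance_from_root()
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of ``tree`` at the midpoint of its longest tip-to-tip path.

    A zero-diameter tree has no midpoint; the root is then placed on an
    arbitrary (first) edge with a warning.
    """
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2 and len(t.leaf_nodes()) > 2:
        # a degree-2 seed node misleads midpoint placement on tied paths
        t.deroot()
    pdm = t.phylogenetic_distance_matrix()
    diameter = max(
        (pdm.patristic_distance(a, b)
         for a, b in pdm.distinct_taxon_pair_iter()),
        default=0.0,
    )
    if diameter == 0.0:
        warnings.warn("zero-diameter tree: rooting at an arbitrary edge",
                      stacklevel=2)
        edge = next(
            e for e in t.preorder_edge_iter()
            if e.head_node is not t.seed_node
        )
        t.reroot_at_edge(edge, update_bipartitions=False)
    else:
        t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def outgroup_root(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root a copy of ``tree`` on the edge separating outgroups from ingroup.

    If no single edge achieves the separation (the outgroup is not
    monophyletic on the unrooted tree), the edge misclassifying the fewest
    tips is chosen deterministically and a warning is emitted.  The chosen
    edge is split at its midpoint.
    """
    outgroup = set(outgroup_labels)
    tips = _leaf_labels(tree)
    missing = outgroup - tips
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if outgroup >= tips:
        raise ValueError("all labels are outgroup; nothing to root against")
    t = tree.clone(depth=1)
    best_edge, best_score, exact = None, -1, False
    for edge in t.preorder_edge_iter():
        node = edge.head_node
        if node is t.seed_node or edge.length is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        for og_side in (side, tips - side):
            # tips correctly placed when rooting so that og_side = outgroups
            score = len(og_side & outgroup) + len((tips - og_side) - outgroup)
            if score > best_score:
                best_edge, best_score = edge, score
                exact = og_side == outgroup
    if not exact:
        warnings.warn(
            "outgroup not separable by a single edge; rooting at the edge "
            "maximizing ingroup/outgroup separation", stacklevel=2,
        )
    half = (best_edge.length or 0.0) / 2.0
    t.reroot_at_edge(best_edge, length1=half, length2=half,
                     update_bipartitions=False)
    t.is_rooted = True
    return t


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of every node above the tips (max path to a subtended tip)."""
    heights: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(
                heights[ch] + (ch.edge.length or 0.0)
                for ch in node.child_nodes()
            )
    return heights


def ultrametricize(tree: dendropy.Tree, epsilon: float = 1e-12) -> dendropy.Tree:
    """Fit clock-like node heights to a rooted tree, preserving topology.

    Each node's height is the mean of the path lengths from the node to its
    subtended tips; tips sit at height 0.  Where the fit violates the
    child < parent constraint the parent is projected to
    ``max(children) + epsilon`` with a warning.  An already-ultrametric tree
    is a fixed point (up to numerical tolerance).
    """
    if not tree.is_rooted:
        raise ValueError("ultrametricize needs a rooted tree")
    t = tree.clone(depth=1)
    mean_h: dict[dendropy.Node, float] = {}
    n_tips: dict[dendropy.Node, int] = {}
    violations = 0
    for node in t.postorder_node_iter():
        if node.is_leaf():
            mean_h[node], n_tips[node] = 0.0, 1
            continue
        children = node.child_nodes()
        total = sum(
            (mean_h[ch] + (ch.edge.length or 0.0)) * n_tips[ch]
            for ch in children
        )
        n_tips[node] = sum(n_tips[ch] for ch in children)
        h = total / n_tips[node]
        h_min = max(mean_h[ch] for ch in children)
        if h <= h_min:
            h = h_min + epsilon
            violations += 1
        mean_h[node] = h
    if violations:
        warnings.warn(
            f"projected {violations} node height(s) onto the child<parent "
            "constraint", stacklevel=2,
        )
    for node in t.preorder_node_iter():
        for ch in node.child_nodes():
            ch.edge.length = mean_h[node] - mean_h[ch]
    return t


@dataclass(frozen=True)
class ClockConfig:
    """Strict-clock settings.

    ``rate`` is the substitution rate in substitutions/site/Ma (default
    0.0016 with SD 0.0010, an arthropod nuclear-rRNA estimate); the root-age
    prior (default 200 +- 50 Ma) is a plausibility check only.  ``n_draws``
    truncated-normal rate draws (truncation at zero) give each node's
    2.5-97.5 percentile age interval.
    """

    rate: float = 0.0016
    rate_sd: float = 0.0010
    root_age_prior_mean: float = 200.0
    root_age_prior_sd: float = 50.0
    n_draws: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.rate_sd < 0:
            raise ValueError("rate must be > 0 and rate_sd >= 0")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")

    def draw_rates(self) -> np.ndarray:
        """Seeded truncated-normal rate draws (truncated at 0)."""
        if self.rate_sd == 0:
            return np.full(self.n_draws, self.rate)
        a = (0.0 - self.rate) / self.rate_sd
        return truncnorm.rvs(
            a, np.inf, loc=self.rate, scale=self.rate_sd,
            size=self.n_draws,
            random_state=np.random.default_rng(self.seed),
        )


@dataclass(frozen=True)
class NodeAge:
    """One dated node: point age and rate-uncertainty interval, in Ma."""

    node_id: str
    age: float
    lo: float
    hi: float
    tip_labels: tuple[str, ...]


@dataclass
class DatedTree:
    """Rooted ultrametric tree with node ages in Ma.

    ``tree`` carries branch lengths in Ma; ``table`` lists every node with
    its point age and (when computed from rate draws) its age interval.
    """

    tree: dendropy.Tree
    table: list[NodeAge] = field(default_factory=list)

    @property
    def root_age(self) -> float:
        return max((row.age for row in self.table), default=0.0)

    def age_of(self, node_id: str) -> NodeAge:
        for row in self.table:
            if row.node_id == node_id:
                return row
        raise KeyError(node_id)


def dated_tree_from_ultrametric(tree_ma: dendropy.Tree) -> DatedTree:
    """Wrap an ultrametric tree whose branch lengths are already in Ma."""
    heights = node_heights(tree_ma)
    table, k = [], 0
    for node in tree_ma.preorder_node_iter():
        if node.is_leaf():
            nid = node.taxon.label
            tips = (node.taxon.label,)
        else:
            nid, k = f"n{k}", k + 1
            tips = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
        h = heights[node]
        table.append(NodeAge(node_id=nid, age=h, lo=h, hi=h, tip_labels=tips))
    return DatedTree(tree=tree_ma, table=table)


def clock_dates(tree: dendropy.Tree, clock: ClockConfig) -> DatedTree:
    """Convert an ultrametric tree (subs/site) to node ages in Ma.

    Point age = node height / rate; each node's interval is the 2.5-97.5
    percentile range of height / rate over the clock's rate draws.  The
    returned tree's branch lengths are rescaled to Ma.  A warning is emitted
    if the root age falls outside the root-age prior's mean +- 3 SD.
    """
    if not tree.is_rooted:
        raise ValueError("clock_dates needs a rooted (ultrametric) tree")
    heights = node_heights(tree)
    rates = clock.draw_rates()
    t = tree.clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / clock.rate
    table, k = [], 0
    for node, node_ma in zip(tree.preorder_node_iter(), t.preorder_node_iter()):
        h = heights[node]
        ages = h / rates
        lo, hi = (float(np.percentile(ages, 2.5)),
                  float(np.percentile(ages, 97.5)))
        if node.is_leaf():
            nid = node.taxon.label
            tips = (node.taxon.label,)
        else:
            nid, k = f"n{k}", k + 1
            tips = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            node_ma.label = nid
        table.append(
            NodeAge(node_id=nid, age=h / clock.rate, lo=lo, hi=hi,
                    tip_labels=tips)
        )
    dated = DatedTree(tree=t, table=table)
    mu, sd = clock.root_age_prior_mean, clock.root_age_prior_sd
    if abs(dated.root_age - mu) > 3 * sd:
        warnings.warn(
            f"root age {dated.root_age:.1f} Ma outside the prior plausibility "
            f"window {mu} +- {3 * sd} Ma", stacklevel=2,
        )
    return dated


# ---------------------------------------------------------------------------
# newick I/O

def tree_from_newick(src: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Read a newick tree from a path or a newick string."""
    try:
        is_file = Path(str(src)).exists()
    except OSError:
        is_file = False
    text = Path(src).read_text() if is_file else str(src)
    tree = dendropy.Tree.get(data=text, schema="newick")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def tree_to_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=False)
    if path is not None:
        Path(path).write_text(s)
    return s


def write_dated_tree(dated: DatedTree, newick_path: str | Path,
                     table_path: str | Path) -> None:
    """Newick (branch lengths in Ma, internal node ids as labels) + age TSV."""
    tree_to_newick(dated.tree, newick_path)
    with open(table_path, "w") as fh:
        fh.write("node_id\tage_ma\tage_lo_ma\tage_hi_ma\tn_tips\ttips\n")
        for row in dated.table:
            fh.write(
                f"{row.node_id}\t{row.age:.6g}\t{row.lo:.6g}\t{row.hi:.6g}\t"
                f"{len(row.tip_labels)}\t{';'.join(row.tip_labels)}\n"
            )
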