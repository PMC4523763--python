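"""Synthetic data with known ground truth for every pipeline stage.

Two generators are provided.  ``simulate_yule_tree`` + ``evolve_k2p``
produce clock-like alignments: a pure-birth (Yule) species tree with node
ages in Ma, and sequences evolved along it under the Kimura-2-parameter
model at a strict clock rate (defaults: 10 tips, birth rate 0.04/Ma giving
a root age around 45 Ma, rate 0.0016 substitutions/site/Ma, kappa 4,
5000 sites), using exact per-branch K2P transition probabilities rather
than event-by-event simulation.  ``make_planted_matrix`` produces
gap-structured distance matrices with a known species partition:
within-species distances drawn uniformly from one interval and
between-species distances from a higher disjoint interval, emulating the
bimodal distribution in which a barcoding gap appears.  Planted matrices
need not satisfy the triangle inequality; delimitation is graph-based and
does not require metricity (tree-building tests use additive, tree-derived
matrices instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .barcodegap import SpeciesPartition
from .distmat import DistanceMatrix
from .seqio import Alignment, SpecimenInfo, write_fasta
from .treetime import DatedTree, dated_tree_from_ultrametric, tree_to_newick

__all__ = [
    "SimParams",
    "PlantedPartitionSpec",
    "simulate_yule_tree",
    "evolve_k2p",
    "k2p_transition_probs",
    "make_planted_matrix",
    "write_bundle",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Settings for the Yule-tree / K2P sequence simulator.

    ``birth_rate`` is per Ma; ``clock_rate`` in substitutions/site/Ma;
    ``kappa`` is the transition/transversion *rate* ratio; ``L`` the number
    of sites.
    """

    n_tips: int = 10
    birth_rate: float = 0.04
    clock_rate: float = 0.0016
    kappa: float = 4.0
    L: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.kappa <= 0 or self.clock_rate <= 0 or self.birth_rate <= 0:
            raise ValueError("rates and kappa must be positive")


def simulate_yule_tree(params: SimParams) -> DatedTree:
    """Pure-birth tree grown to ``n_tips``, with true node ages in Ma.

    Starting from one lineage, with k lineages the waiting time to the next
    split is Exp(k * birth_rate) and a uniformly chosen lineage splits; the
    process stops just before the (n+1)-th birth, i.e. the n-tip tree is
    observed after one further Exp(n * birth_rate) wait.  Tips are
    contemporaneous (age 0) and the root age is the sum of the waits while
    2..n lineages existed, with expectation (1/birth_rate) * sum_{k=2}^{n} 1/k.
    """
    rng = np.random.default_rng(params.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    active = [tree.seed_node]
    # birth time of each active lineage's subtending node
    birth = {tree.seed_node: 0.0}
    t = 0.0
    while len(active) < params.n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * params.birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.time = t  # type: ignore[attr-defined]
        for _ in range(2):
            child = node.new_child()
            birth[child] = t
            active.append(child)
    # observe the n-tip tree during the wait before the (n+1)-th birth
    t += rng.exponential(1.0 / (params.n_tips * params.birth_rate))
    for i, leaf in enumerate(active):
        leaf.time = t  # type: ignore[attr-defined]
    tree.seed_node.time = getattr(tree.seed_node, "time", t)
    # Edge lengths from split times; leaves end at the stop time t.
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    return dated_tree_from_ultrametric(tree)


def k2p_transition_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after distance ``d``.

    ``d`` is the expected number of substitutions per site; with transition
    rate alpha and per-type transversion rate beta (kappa = alpha/beta,
    total rate alpha + 2 beta), the K2P chain gives closed-form
    probabilities via beta*t = d/(kappa+2), alpha*t = kappa*d/(kappa+2).
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = math.exp(-4.0 * bt)
    e2ab = math.exp(-2.0 * (at + bt))
    p_tv_each = 0.25 * (1.0 - e4b)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def _evolve_branch(
    parent_seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    p_same, p_ts, p_tv = k2p_transition_probs(d, kappa)
    u = rng.random(parent_seq.size)
    child = parent_seq.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    # with A,C,G,T -> 0..3: transition partner x^2; transversions x^1, x^3
    child[ts] ^= 2
    child[tv1] ^= 1
    child[tv2] ^= 3
    return child


def evolve_k2p(tree: DatedTree, params: SimParams) -> Alignment:
    """Evolve an alignment along a dated tree under a strict K2P clock.

    The root sequence is uniform over {A,C,G,T}; along each branch of
    duration t Ma the expected divergence is clock_rate * t and sites evolve
    independently with exact K2P transition probabilities.  Tip metadata is
    filled in (region "simulated", all ingroup) so synthetic bundles run
    through the whole pipeline.
    """
    rng = np.random.default_rng(params.seed)
    root = tree.tree.seed_node
    seqs: dict = {root: rng.integers(0, 4, size=params.L, dtype=np.int8)}
    records = []
    for node in tree.tree.preorder_node_iter():
        if node is not root:
            d = params.clock_rate * (node.edge.length or 0.0)
            seqs[node] = _evolve_branch(seqs[node.parent_node], d,
                                        params.kappa, rng)
        if node.is_leaf():
            seq = "".join(_BASES[c] for c in seqs[node])
            records.append((node.taxon.label, seq))
    metadata = {
        lab: SpecimenInfo(region="simulated", group="ingroup")
        for lab, _ in records
    }
    return Alignment(records=records, metadata=metadata, aligned=True)


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Gap-structured matrix spec: species sizes and two distance bands.

    Within-species distances are drawn uniformly from ``within_range``
    = (0, a); between-species distances from ``between_range`` = (b, c),
    a < b <= c.  Units are percent, matching published-table conventions.
    """

    sizes: tuple[int, ...]
    within_range: tuple[float, float] = (0.0, 1.0)
    between_range: tuple[float, float] = (10.0, 28.0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes) or len(self.sizes) < 1:
            raise ValueError("sizes must be positive")
        a0, a = self.within_range
        b, c = self.between_range
        if not (0 <= a0 < a < b <= c):
            raise ValueError("need 0 <= lo < a < b <= c")


def make_planted_matrix(
    spec: PlantedPartitionSpec, seed: int | None = None
) -> tuple[DistanceMatrix, SpeciesPartition]:
    """Random symmetric matrix with a known species partition planted in it."""
    rng = np.random.default_rng(seed)
    labels, species = [], []
    for s, size in enumerate(spec.sizes):
        for m in range(size):
            labels.append(f"sp{s + 1}_{m + 1}")
            species.append(s)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = (
                spec.within_range if species[i] == species[j]
                else spec.between_range
            )
            d[i, j] = d[j, i] = rng.uniform(lo, hi)
    dm = DistanceMatrix(labels=labels, d=d, model="p", units="percent")
    truth = SpeciesPartition(
        assignment={lab: s for lab, s in zip(labels, species)},
        threshold=spec.within_range[1],
        linkage="single",
    )
    return dm, truth


def write_bundle(
    outdir: str | Path,
    params: SimParams,
) -> dict[str, Path]:
    """Simulate a full bundle (FASTA, metadata TSV, true tree, true partition).

    Everything the CLI needs to run end to end on synthetic data, plus the
    ground truth for checking it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_yule_tree(params)
    ali = evolve_k2p(tree, params)
    paths = {
        "fasta": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "true_tree": outdir / "true_tree.nwk",
        "true_partition": outdir / "true_partition.tsv",
    }
    write_fasta(ali, paths["fasta"])
    with open(paths["metadata"], "w") as fh:
        fh.write("label\tregion\tgroup\n")
        for lab in ali.labels:
            info = ali.metadata[lab]
            fh.write(f"{lab}\t{info.region}\t{info.group}\n")
    tree_to_newick(tree.tree, paths["true_tree"])
    with open(paths["true_partition"], "w") as fh:
        fh.write("label\tspecies\n")
        for lab in ali.labels:
            fh.write(f"{lab}\t{lab}\n")  # every tip its own lineage
    return paths
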