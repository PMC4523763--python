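"""Barcoding-gap detection and threshold-based species delimitation.

The barcoding gap is the interval expected to separate within-species from
between-species pairwise distances.  Operationally, gaps are the
zero-frequency intervals of the observed distance distribution: between each
pair of consecutive distinct observed values lies an interval containing no
observation, and candidates are ranked by width.  Putative species are then
the single-linkage clusters (connected components) obtained by linking every
specimen pair whose distance is at or below a threshold — here, the lower
endpoint of a chosen gap.  Counts can be restricted to a geographic region
set (e.g. the Italian region sensu lato).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distmat import DistanceMatrix
from .seqio import SpecimenInfo

__all__ = [
    "GapInterval",
    "GapReport",
    "SpeciesPartition",
    "GapScenario",
    "find_gaps",
    "delimit",
    "count_by_region",
    "delimit_under_gaps",
    "write_partition_tsv",
    "write_scenarios_json",
    "write_histogram_csv",
]


@dataclass(frozen=True)
class GapInterval:
    """An empty interval of the distance distribution.

    ``lo`` is the largest observed value below the gap and ``hi`` the
    smallest observed value above it; no observation lies strictly inside.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("gap requires lo < hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class GapReport:
    """Sorted observed distances plus empty intervals ranked by width.

    ``intervals`` holds every interval between consecutive distinct values,
    sorted by descending width with ties broken by smaller ``lo``; ``top(k)``
    returns the ``k`` widest.  ``histogram`` supports plotting only — gap
    detection itself works on exact values, not bins.
    """

    distances: np.ndarray
    intervals: list[GapInterval]
    units: str = "percent"

    def top(self, k: int) -> list[GapInterval]:
        return self.intervals[:k]

    def histogram(self, bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts) at the given bin width, starting at 0."""
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        hi = float(self.distances.max())
        edges = np.arange(0.0, hi + bin_width, bin_width)
        if edges[-1] <= hi:
            edges = np.append(edges, edges[-1] + bin_width)
        counts, _ = np.histogram(self.distances, bins=edges)
        return edges, counts


def find_gaps(matrix: DistanceMatrix, top_k: int | None = None) -> GapReport:
    """Rank the zero-frequency intervals of the pairwise-distance distribution.

    Distances are the upper-triangle values of ``matrix`` (undefined entries
    excluded); intervals lie between consecutive *distinct* sorted values and
    are ranked widest-first, ties broken by smaller lower endpoint.  All
    distances equal yields an empty interval list.
    """
    vals = matrix.upper_triangle()
    vals = np.sort(vals[~np.isnan(vals)])
    distinct = np.unique(vals)
    if distinct.size < 2:
        if vals.size < 2:
            raise ValueError("find_gaps needs at least 2 finite distances")
        return GapReport(distances=vals, intervals=[], units=matrix.units)
    intervals = [
        GapInterval(lo=float(a), hi=float(b))
        for a, b in zip(distinct[:-1], distinct[1:])
    ]
    intervals.sort(key=lambda g: (-g.width, g.lo))
    if top_k is not None:
        intervals = intervals[:top_k]
    return GapReport(distances=vals, intervals=intervals, units=matrix.units)


@dataclass
class SpeciesPartition:
    """Specimen-to-cluster assignment at a distance threshold.

    Cluster ids are 0-based, ordered by the matrix position of each
    cluster's first member, so partitions are deterministic.
    """

    assignment: dict[str, int]
    threshold: float
    linkage: str = "single"

    @property
    def n_species(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for lab, cid in self.assignment.items():
            out.setdefault(cid, []).append(lab)
        return [out[cid] for cid in sorted(out)]


def _canonical_ids(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by order of first appearance."""
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return out


def delimit(
    matrix: DistanceMatrix,
    threshold: float,
    linkage: str = "single",
) -> SpeciesPartition:
    """Cluster specimens at ``d <= threshold``.

    Single linkage (the default, and the delimitation rule of the barcoding
    procedure) takes the connected components of the graph linking pairs at
    or below the threshold; complete linkage is available as an alternative.
    Undefined (NaN) entries are treated as above-threshold with a warning.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d = matrix.d.copy()
    if np.isnan(d).any():
        warnings.warn(
            "undefined distances treated as above the threshold", stacklevel=2
        )
    if linkage == "single":
        with np.errstate(invalid="ignore"):
            adj = (d <= threshold) & ~np.isnan(d)
        np.fill_diagonal(adj, False)
        _, raw = connected_components(csr_matrix(adj), directed=False)
    elif linkage == "complete":
        big = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
        d[np.isnan(d)] = 2.0 * big + 1.0
        Z = _scipy_linkage(squareform(d, checks=False), method="complete")
        raw = fcluster(Z, t=threshold, criterion="distance")
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = _canonical_ids(np.asarray(raw))
    return SpeciesPartition(
        assignment={lab: int(c) for lab, c in zip(matrix.labels, ids)},
        threshold=float(threshold),
        linkage=linkage,
    )


def count_by_region(
    partition: SpeciesPartition,
    metadata: Mapping[str, SpecimenInfo],
    region_set: Iterable[str],
) -> int:
    """Number of clusters with at least one member sampled in ``region_set``."""
    regions = frozenset(region_set)
    missing = [lab for lab in partition.assignment if lab not in metadata]
    if missing:
        raise KeyError(f"no metadata for labels: {missing}")
    return len(
        {
            cid
            for lab, cid in partition.assignment.items()
            if metadata[lab].region in regions
        }
    )


@dataclass(frozen=True)
class GapScenario:
    """One delimitation scenario: a gap, its threshold and species counts."""

    gap: GapInterval
    threshold: float
    partition: SpeciesPartition
    n_species: int
    n_species_in_region: int


def delimit_under_gaps(
    matrix: DistanceMatrix,
    gap_report: GapReport,
    metadata: Mapping[str, SpecimenInfo],
    region_set: Iterable[str],
    top_k: int | None = None,
) -> list[GapScenario]:
    """Delimit species under each candidate gap of ``gap_report``.

    The clustering threshold for a gap is the gap's lower endpoint,
    inclusive (pairs with d <= lo are linked); scenarios are returned in the
    report's (width-ranked) order.
    """
    gaps = gap_report.intervals if top_k is None else gap_report.top(top_k)
    scenarios = []
    for gap in gaps:
        part = delimit(matrix, threshold=gap.lo)
        scenarios.append(
            GapScenario(
                gap=gap,
                threshold=gap.lo,
                partition=part,
                n_species=part.n_species,
                n_species_in_region=count_by_region(part, metadata, region_set),
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# writers

def write_partition_tsv(
    partition: SpeciesPartition,
    metadata: Mapping[str, SpecimenInfo],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("label\tcluster\tregion\n")
        for lab, cid in partition.assignment.items():
            region = metadata[lab].region if lab in metadata else ""
            fh.write(f"{lab}\t{cid}\t{region}\n")


def write_scenarios_json(scenarios: Sequence[GapScenario], path: str | Path) -> None:
    payload = [
        {
            "gap": {"lo": s.gap.lo, "hi": s.gap.hi, "width": s.gap.width},
            "threshold": s.threshold,
            "n_species": s.n_species,
            "n_species_in_region": s.n_species_in_region,
            "clusters": s.partition.clusters(),
        }
        for s in scenarios
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_histogram_csv(
    report: GapReport, path: str | Path, bin_width: float = 1.0
) -> None:
    edges, counts = report.histogram(bin_width)
    with open(path, "w") as fh:
        fh.write("bin_lo,bin_hi,count\n")
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{lo:g},{hi:g},{int(c)}\n")


def plot_histogram(
    report: GapReport, path: str | Path, bin_width: float = 1.0
) -> None:
    """Optional frequency-distribution plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, counts = report.histogram(bin_width)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(edges[:-1], counts, width=bin_width, align="edge", edgecolor="k")
    ax.set_xlabel(f"pairwise distance ({report.units})")
    ax.set_ylabel("number of pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
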