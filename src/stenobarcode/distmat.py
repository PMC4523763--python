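"""Pairwise p- and Kimura-2-parameter distances with bootstrap errors.

The K2P model separates transitions (A<->G, C<->T; proportion P of compared
sites) from transversions (proportion Q) and corrects for multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

The p-distance is simply (n_ts + n_tv) / L.  Sites where either sequence of a
pair carries a gap, N or an ambiguity code are always excluded; in addition a
"partial deletion" policy first drops alignment columns whose coverage across
all sequences falls below a cutoff (default 95%), mirroring the convention of
mainstream distance software.  Saturated pairs (log argument <= 0) are flagged
as undefined (NaN), never silently zeroed, and never abort the matrix.

Standard errors are estimated by bootstrap over alignment columns: columns are
resampled with replacement globally, every pairwise distance is recomputed on
each pseudoreplicate, and the SE is the standard deviation across replicates.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

from .seqio import Alignment

__all__ = [
    "PairSiteCounts",
    "DistanceMatrix",
    "PairwiseDeletion",
    "PartialDeletion",
    "encode_alignment",
    "site_mask",
    "pair_counts",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "bootstrap_se",
    "write_square_csv",
    "read_square_csv",
    "write_phylip",
    "write_combined_csv",
    "load_published_coi_matrices",
]

Model = Literal["p", "k2p"]

# A,G even / C,T odd so that a transition is a mismatch preserving parity.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PairwiseDeletion:
    """Exclude, per pair, only the sites missing in that pair."""

    name: str = field(default="pairwise-deletion", init=False)


@dataclass(frozen=True)
class PartialDeletion:
    """Keep only columns with coverage >= ``coverage`` across all sequences,
    then apply pairwise exclusion within the retained columns."""

    coverage: float = 0.95
    name: str = field(default="partial-deletion", init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")


Policy = PairwiseDeletion | PartialDeletion


@dataclass(frozen=True)
class PairSiteCounts:
    """Site counts for one sequence pair after deletion.

    ``L`` valid compared sites, of which ``n_ts`` transitions and ``n_tv``
    transversions.  ``P`` and ``Q`` are the corresponding proportions; all
    are undefined (``defined`` False) when L = 0.
    """

    L: int
    n_ts: int
    n_tv: int

    def __post_init__(self) -> None:
        if self.n_ts < 0 or self.n_tv < 0 or self.n_ts + self.n_tv > self.L:
            raise ValueError("inconsistent site counts")

    @property
    def defined(self) -> bool:
        return self.L > 0

    @property
    def P(self) -> float:
        return self.n_ts / self.L if self.L else math.nan

    @property
    def Q(self) -> float:
        return self.n_tv / self.L if self.L else math.nan


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Encode sequences as an int8 matrix: A,C,G,T -> 0..3, all else -> -1.

    Gaps, N and IUPAC ambiguity codes are treated as missing data.
    """
    n, L = len(alignment), alignment.length
    X = np.full((n, L), -1, dtype=np.int8)
    lut = np.full(128, -1, dtype=np.int8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    for i, (_, seq) in enumerate(alignment.records):
        X[i] = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return X


def site_mask(X: np.ndarray, policy: Policy) -> np.ndarray:
    """Boolean mask of alignment columns retained under ``policy``.

    Computed once per alignment: under partial deletion a column is kept when
    the fraction of non-missing states across all rows is at least the
    coverage cutoff; under pairwise deletion every column is kept (deletion
    then happens per pair).
    """
    if isinstance(policy, PairwiseDeletion):
        return np.ones(X.shape[1], dtype=bool)
    cov = (X >= 0).mean(axis=0)
    # ">= c" with a tolerance so that e.g. 19/20 passes c = 0.95 exactly.
    return cov >= policy.coverage - 1e-12


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> PairSiteCounts:
    valid = (a >= 0) & (b >= 0)
    diff = valid & (a != b)
    ts = diff & ((a & 1) == (b & 1))
    return PairSiteCounts(
        L=int(valid.sum()), n_ts=int(ts.sum()), n_tv=int(diff.sum() - ts.sum())
    )


def pair_counts(
    seq_a: str,
    seq_b: str,
    policy: Policy = PairwiseDeletion(),
    mask: np.ndarray | None = None,
) -> PairSiteCounts:
    """Count compared sites, transitions and transversions for one pair.

    ``mask`` is the alignment-wide retained-column mask from
    :func:`site_mask`; when ``policy`` is partial deletion and no mask is
    given, the mask is computed from the pair alone.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("pair_counts requires equal-length sequences")
    ali = Alignment(records=[("a", seq_a.upper()), ("b", seq_b.upper())])
    X = encode_alignment(ali)
    if mask is None:
        mask = site_mask(X, policy)
    return _counts_from_codes(X[0, mask], X[1, mask])


def p_distance(counts: PairSiteCounts) -> float:
    """Proportion of differing sites; NaN when the counts are undefined."""
    if not counts.defined:
        return math.nan
    return (counts.n_ts + counts.n_tv) / counts.L


def k2p_distance(counts: PairSiteCounts) -> float:
    """Kimura-2-parameter distance in substitutions/site.

    Returns NaN (flagged-undefined) when the counts are undefined or the
    pair is saturated (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if not counts.defined:
        return math.nan
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_DIST_FUN = {"p": p_distance, "k2p": k2p_distance}


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with optional bootstrap SEs.

    ``d`` is in substitutions/site when ``units == "fraction"`` or percent
    when loaded from a published table (``units == "percent"``).  Undefined
    entries are NaN; :meth:`undefined_pairs` lists them.
    """

    labels: list[str]
    d: np.ndarray
    model: Model
    units: Literal["fraction", "percent"] = "fraction"
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(np.diag(self.d), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = ~np.isnan(self.d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            np.where(finite, self.d, 0.0), np.where(finite, self.d, 0.0).T
        ):
            raise ValueError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.d[finite] < 0):
                raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def upper_triangle(self) -> np.ndarray:
        """Unordered-pair distances (row-major upper triangle), NaN included."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        bad = np.isnan(self.d[iu])
        return [
            (self.labels[i], self.labels[j])
            for i, j, b in zip(*iu, bad)
            if b
        ]

    def to_percent(self) -> "DistanceMatrix":
        if self.units == "percent":
            return self
        return DistanceMatrix(
            labels=list(self.labels),
            d=self.d * 100.0,
            model=self.model,
            units="percent",
            se=None if self.se is None else self.se * 100.0,
        )

    def to_fraction(self) -> "DistanceMatrix":
        if self.units == "fraction":
            return self
        return DistanceMatrix(
            labels=list(self.labels),
            d=self.d / 100.0,
            model=self.model,
            units="fraction",
            se=None if self.se is None else self.se / 100.0,
        )


def _matrix_from_codes(
    X: np.ndarray, labels: list[str], model: Model, mask: np.ndarray
) -> np.ndarray:
    n = X.shape[0]
    fun = _DIST_FUN[model]
    d = np.zeros((n, n), dtype=float)
    Xm = X[:, mask]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fun(_counts_from_codes(Xm[i], Xm[j]))
    return d


def distance_matrix(
    alignment: Alignment,
    model: Model = "k2p",
    policy: Policy = PartialDeletion(),
) -> DistanceMatrix:
    """Compute all pairwise distances of an alignment under one model.

    Undefined (saturated or zero-overlap) pairs are recorded as NaN with a
    warning rather than aborting.
    """
    if len(alignment) < 2:
        raise ValueError("distance_matrix needs at least 2 sequences")
    if model not in _DIST_FUN:
        raise ValueError(f"unknown model {model!r}")
    X = encode_alignment(alignment)
    mask = site_mask(X, policy)
    d = _matrix_from_codes(X, alignment.labels, model, mask)
    dm = DistanceMatrix(labels=alignment.labels, d=d, model=model)
    if dm.undefined_pairs():
        warnings.warn(
            f"{len(dm.undefined_pairs())} pair(s) with undefined {model} "
            "distance (saturation or no shared sites)",
            stacklevel=2,
        )
    return dm


def bootstrap_se(
    alignment: Alignment,
    model: Model = "k2p",
    policy: Policy = PartialDeletion(),
    B: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Bootstrap standard errors of every pairwise distance.

    Columns of the alignment are resampled with replacement ``B`` times
    (global site resampling; per-pair deletion is then applied within each
    pseudoreplicate).  Per pair, the SE is the standard deviation of the
    distance over the replicates in which it is defined; pairs undefined in
    every replicate get NaN.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    rng = np.random.default_rng(seed)
    X = encode_alignment(alignment)
    mask = site_mask(X, policy)
    Xm = X[:, mask]
    n, L = Xm.shape
    if L == 0:
        raise ValueError("no sites retained under the deletion policy")
    fun = _DIST_FUN[model]
    reps = np.empty((B, n, n), dtype=float)
    for b in range(B):
        cols = rng.integers(0, L, size=L)
        Xb = Xm[:, cols]
        for i in range(n):
            for j in range(i + 1, n):
                v = fun(_counts_from_codes(Xb[i], Xb[j]))
                reps[b, i, j] = reps[b, j, i] = v
        reps[b, range(n), range(n)] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        se = np.nanstd(reps, axis=0, ddof=1)
    se[range(n), range(n)] = 0.0
    all_nan = np.isnan(reps).all(axis=0)
    se[all_nan] = np.nan
    if np.isnan(se).any():
        warnings.warn("bootstrap SE undefined for some pair(s)", stacklevel=2)
    return se


# ---------------------------------------------------------------------------
# readers / writers

def write_square_csv(dm: DistanceMatrix, path: str | Path, digits: int = 6) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow([""] + dm.labels)
        for i, lab in enumerate(dm.labels):
            w.writerow(
                [lab]
                + [
                    "" if i == j else (
                        "NA" if math.isnan(dm.d[i, j]) else f"{dm.d[i, j]:.{digits}g}"
                    )
                    for j in range(dm.n)
                ]
            )


def read_square_csv(
    path: str | Path,
    model: Model,
    units: Literal["fraction", "percent"] = "fraction",
) -> DistanceMatrix:
    """Read a square labelled CSV (empty or NA cells -> 0 diagonal / NaN)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    labels = rows[0][1:]
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    for i, row in enumerate(rows[1 : n + 1]):
        for j, cell in enumerate(row[1 : n + 1]):
            if i == j:
                continue
            cell = cell.strip()
            d[i, j] = math.nan if cell in ("", "NA") else float(cell)
    return DistanceMatrix(labels=labels, d=d, model=model, units=units)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance format with relaxed (whitespace-free) labels."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, lab in enumerate(dm.labels):
            vals = " ".join(f"{dm.d[i, j]:.6f}" for j in range(dm.n))
            fh.write(f"{lab.replace(' ', '_')}  {vals}\n")


def _combined(upper: DistanceMatrix, lower: DistanceMatrix) -> np.ndarray:
    if upper.labels != lower.labels:
        raise ValueError("triangle matrices must share labels and order")
    n = upper.n
    out = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = upper.d[iu]
    il = np.tril_indices(n, k=-1)
    out[il] = lower.d[il]
    return out


def write_combined_csv(
    k2p: DistanceMatrix,
    p: DistanceMatrix,
    path: str | Path,
    se_path: str | Path | None = None,
    digits: int = 1,
) -> None:
    """Write a combined table: K2P upper triangle, p-distance lower triangle.

    Values are written in percent rounded to ``digits`` decimals, mirroring
    how such matrices are conventionally printed; SEs go to a parallel file
    of the same shape when ``se_path`` is given.
    """
    k2p_pc, p_pc = k2p.to_percent(), p.to_percent()
    d = _combined(k2p_pc, p_pc)

    def _write(matrix: np.ndarray, dest: str | Path) -> None:
        with open(dest, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow([""] + k2p_pc.labels)
            for i, lab in enumerate(k2p_pc.labels):
                w.writerow(
                    [lab]
                    + [
                        "" if i == j else (
                            "NA" if math.isnan(matrix[i, j])
                            else f"{matrix[i, j]:.{digits}f}"
                        )
                        for j in range(len(k2p_pc.labels))
                    ]
                )

    _write(d, path)
    if se_path is not None:
        if k2p_pc.se is None or p_pc.se is None:
            raise ValueError("both matrices need SEs to write the SE file")
        _write(_combined(
            DistanceMatrix(k2p_pc.labels, k2p_pc.se, "k2p", "percent"),
            DistanceMatrix(p_pc.labels, p_pc.se, "p", "percent"),
        ), se_path)


def _read_combined(path, labels_check=None):
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    labels = rows[0][1:]
    n = len(labels)
    m = np.full((n, n), np.nan)
    for i, row in enumerate(rows[1 : n + 1]):
        for j, cell in enumerate(row[1 : n + 1]):
            cell = cell.strip()
            if i == j:
                m[i, j] = 0.0
            elif cell not in ("", "NA"):
                m[i, j] = float(cell)
    return labels, m


def load_published_coi_matrices(
    with_se: bool = True,
) -> tuple[DistanceMatrix, DistanceMatrix, dict]:
    """Load the packaged published COI distance matrices (percent units).

    Returns ``(k2p, p, notes)`` where the two 12x12 matrices carry the
    printed one-decimal distances (K2P from the upper triangle, p-distance
    from the lower triangle, each symmetrised) and, when ``with_se``, the
    printed bootstrap SEs.  ``notes`` records provenance details, including
    the one pair whose printed K2P SE has an anomalous format and is stored
    as printed but marked suspect.
    """
    pkg = resources.files("stenobarcode") / "data"
    labels, d = _read_combined(pkg / "coi_distances_percent.csv")
    _, se = _read_combined(pkg / "coi_distance_se_percent.csv")
    notes = json.loads((pkg / "coi_fixture_notes.json").read_text())

    def _sym(m: np.ndarray, upper: bool) -> np.ndarray:
        out = np.zeros_like(m)
        idx = np.triu_indices(len(labels), k=1)
        tri = m[idx] if upper else m.T[idx]
        out[idx] = tri
        return out + out.T

    k2p = DistanceMatrix(
        labels=labels, d=_sym(d, True), model="k2p", units="percent",
        se=_sym(se, True) if with_se else None,
    )
    p = DistanceMatrix(
        labels=labels, d=_sym(d, False), model="p", units="percent",
        se=_sym(se, False) if with_se else None,
    )
    return k2p, p, notes
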