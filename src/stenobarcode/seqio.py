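"""Sequence and metadata I/O plus per-sequence composition diagnostics.

Alignments are plain aligned DNA multi-FASTA files (IUPAC codes, ``-`` for
gaps); specimen metadata is a tab-separated table with ``label``, ``region``
and ``group`` (ingroup/outgroup) columns.  Composition statistics (GC-content
and GC-skew) are the screen the barcoding pipeline uses to check that outgroup
sequences are compositionally ingroup-like before any tree is built.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "AlignmentError",
    "SpecimenInfo",
    "Alignment",
    "CompositionStats",
    "OutgroupVerdict",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_region_set",
    "composition",
    "screen_outgroups",
    "write_composition_table",
]

#: Characters accepted in input sequences: the four bases, IUPAC ambiguity
#: codes, N and the gap symbol.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Characters counted in composition and distance computations.
UNAMBIGUOUS = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file (bad characters, duplicate labels, bad columns)."""


class AlignmentError(ValueError):
    """Sequences violate an alignment requirement (e.g. unequal lengths)."""


@dataclass(frozen=True)
class SpecimenInfo:
    """Per-specimen metadata: sampling region and ingroup/outgroup status."""

    region: str
    group: str  # "ingroup" | "outgroup"

    def __post_init__(self) -> None:
        if self.group not in ("ingroup", "outgroup"):
            raise FormatError(
                f"group must be 'ingroup' or 'outgroup', got {self.group!r}"
            )


@dataclass
class Alignment:
    """An ordered set of (label, sequence) records, optionally aligned.

    Parameters
    ----------
    records:
        ``(label, sequence)`` pairs in file order.  Sequences are uppercase
        strings over the IUPAC DNA alphabet plus ``-``.
    metadata:
        Optional map from label to :class:`SpecimenInfo`; every key must be a
        record label.
    aligned:
        If true, all sequences must have identical length.
    """

    records: list[tuple[str, str]]
    metadata: dict[str, SpecimenInfo] = field(default_factory=dict)
    aligned: bool = True

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.records]
        if any(not lab for lab in labels):
            raise FormatError("empty sequence label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate labels: {dupes}")
        for lab, seq in self.records:
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise FormatError(
                    f"non-IUPAC characters {sorted(bad)} in record {lab!r}"
                )
        if self.aligned:
            lengths = {len(seq) for _, seq in self.records}
            if len(lengths) > 1:
                raise AlignmentError(
                    f"unequal sequence lengths {sorted(lengths)} in aligned input"
                )
        unknown = set(self.metadata) - set(labels)
        if unknown:
            raise FormatError(f"metadata for unknown labels: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.records]

    @property
    def length(self) -> int:
        """Number of alignment columns (0 for an empty alignment)."""
        if not self.records:
            return 0
        if not self.aligned:
            raise AlignmentError("length undefined for unaligned records")
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(label)

    def subset(self, labels: Sequence[str]) -> "Alignment":
        """New alignment restricted to ``labels``, in the given order."""
        seqs = {lab: seq for lab, seq in self.records}
        return Alignment(
            records=[(lab, seqs[lab]) for lab in labels],
            metadata={k: v for k, v in self.metadata.items() if k in set(labels)},
            aligned=self.aligned,
        )


def read_fasta(
    path: str | Path,
    require_aligned: bool = True,
    metadata: Mapping[str, SpecimenInfo] | None = None,
) -> Alignment:
    """Read a (multi-)FASTA file into an :class:`Alignment`.

    Records are kept in file order; sequences are uppercased.  With
    ``require_aligned`` (the default) unequal lengths raise
    :class:`AlignmentError`.  An empty file raises :class:`FormatError`.
    """
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(
        records=records,
        metadata=dict(metadata) if metadata else {},
        aligned=require_aligned,
    )


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    """Write the alignment as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for lab, seq in alignment.records:
            fh.write(f">{lab}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> dict[str, SpecimenInfo]:
    """Read the tab-separated specimen table (label / region / group)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = {"label", "region", "group"} - set(cols)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        out: dict[str, SpecimenInfo] = {}
        for row in reader:
            label = (row["label"] or "").strip()
            if not label:
                raise FormatError("metadata row with empty label")
            if label in out:
                raise FormatError(f"duplicate metadata label {label!r}")
            out[label] = SpecimenInfo(
                region=(row["region"] or "").strip(),
                group=(row["group"] or "").strip().lower(),
            )
    return out


def read_region_set(path: str | Path) -> frozenset[str]:
    """Read a region set (one region name per line, blank lines ignored)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


@dataclass(frozen=True)
class CompositionStats:
    """GC-content and GC-skew of a sequence over its unambiguous bases.

    ``gc_content = (G + C) / (A + C + G + T)`` and
    ``gc_skew = (G - C) / (G + C)``; gaps, N and ambiguity codes are excluded
    from both counts.  When a statistic is undefined (no unambiguous bases,
    or G + C = 0 for the skew) the field is NaN and ``defined`` is False.
    """

    gc_content: float
    gc_skew: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.gc_content)

    @property
    def skew_defined(self) -> bool:
        return not math.isnan(self.gc_skew)


def composition(sequence: str) -> CompositionStats:
    """Compute :class:`CompositionStats` for one sequence.

    Raises ``ValueError`` on an empty sequence; a sequence with no
    unambiguous bases yields NaN statistics (flagged, never a silent zero).
    """
    if not sequence:
        raise ValueError("composition of an empty sequence is undefined")
    seq = sequence.upper()
    a = seq.count("A")
    c = seq.count("C")
    g = seq.count("G")
    t = seq.count("T")
    total = a + c + g + t
    if total == 0:
        return CompositionStats(gc_content=math.nan, gc_skew=math.nan)
    gc = g + c
    skew = (g - c) / gc if gc > 0 else math.nan
    return CompositionStats(gc_content=gc / total, gc_skew=skew)


@dataclass(frozen=True)
class OutgroupVerdict:
    """Comparison of one outgroup's composition to the ingroup range.

    ``gc_content_flag`` / ``gc_skew_flag`` are ``None`` when the value lies
    inside the ingroup min-max range, else ``"above"`` or ``"below"``.
    """

    label: str
    stats: CompositionStats
    gc_content_range: tuple[float, float]
    gc_skew_range: tuple[float, float]
    gc_content_flag: str | None
    gc_skew_flag: str | None

    @property
    def flagged(self) -> bool:
        return self.gc_content_flag is not None or self.gc_skew_flag is not None


def _flag(value: float, lo: float, hi: float) -> str | None:
    if math.isnan(value):
        return "undefined"
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return None


def screen_outgroups(alignment: Alignment) -> list[OutgroupVerdict]:
    """Flag outgroups whose GC-content or GC-skew leaves the ingroup range.

    The ingroup min-max range is computed per statistic over sequences whose
    metadata marks them ``ingroup``; each ``outgroup`` sequence gets a verdict
    with the ranges attached.  No outgroups yields an empty report.  A
    single-member ingroup degenerates to a point range, so any differing
    outgroup is flagged.
    """
    groups = {lab: alignment.metadata[lab].group for lab in alignment.labels
              if lab in alignment.metadata}
    ingroup = [lab for lab, g in groups.items() if g == "ingroup"]
    outgroup = [lab for lab, g in groups.items() if g == "outgroup"]
    if not ingroup:
        raise ValueError("screen_outgroups requires a non-empty ingroup")
    in_stats = [composition(alignment.sequence(lab)) for lab in ingroup]
    contents = [s.gc_content for s in in_stats if s.defined]
    skews = [s.gc_skew for s in in_stats if s.skew_defined]
    if not contents or not skews:
        raise ValueError("ingroup composition undefined for all members")
    c_range = (min(contents), max(contents))
    s_range = (min(skews), max(skews))
    report = []
    for lab in outgroup:
        stats = composition(alignment.sequence(lab))
        report.append(
            OutgroupVerdict(
                label=lab,
                stats=stats,
                gc_content_range=c_range,
                gc_skew_range=s_range,
                gc_content_flag=_flag(stats.gc_content, *c_range),
                gc_skew_flag=_flag(stats.gc_skew, *s_range),
            )
        )
    return report


def write_composition_table(alignment: Alignment, path: str | Path) -> None:
    """Write per-sequence composition as TSV (label, group, skew, content%)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", "group", "gc_skew", "gc_content_percent"])
        for lab, seq in alignment.records:
            stats = composition(seq)
            info = alignment.metadata.get(lab)
            writer.writerow([
                lab,
                info.group if info else "",
                f"{stats.gc_skew:.3f}" if stats.skew_defined else "NA",
                f"{100 * stats.gc_content:.1f}" if stats.defined else "NA",
            ])
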