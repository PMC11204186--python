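"""Genomic-interval arithmetic, probe panel and loop annotation handling, BED I/O.

Coordinates are 1-based and fully closed in memory (``length = end - start + 1``,
the convention under which the published sizes of the five BAC probes on
15q12-q13.1 are exact). BED files on disk use the standard 0-based half-open
convention; :func:`read_bed` / :func:`write_bed` convert explicitly.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "ProbePanel",
    "LoopAnnotation",
    "interval_length",
    "overlap_bp",
    "pair_span",
    "distance_label",
    "assign_loop",
    "read_bed",
    "write_bed",
    "default_probe_panel",
    "default_loop_annotation",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (e.g. ``"chr15"``).
    start, end : int
        First and last base of the interval, both inclusive, ``start >= 1``.
    name : str
        Identifier (BAC clone name, gene symbol, ...).
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class IncomparableIntervalsError(ValueError):
    """Raised when interval arithmetic is requested across chromosomes."""


def _check_same_chrom(a: GenomicInterval, b: GenomicInterval) -> None:
    if a.chrom != b.chrom:
        raise IncomparableIntervalsError(
            f"intervals on different chromosomes: {a.chrom} vs {b.chrom}"
        )


def interval_length(iv: GenomicInterval) -> int:
    """Base-pair length of a closed interval: ``end - start + 1``."""
    return iv.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals on the same chromosome."""
    _check_same_chrom(a, b)
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def pair_span(a: GenomicInterval, b: GenomicInterval) -> int:
    """Outermost span of two intervals: distance between their extreme coordinates.

    This is the convention under which the published inter-probe genomic
    distances (2.6 Mb for probes #1-#4, 1.3 Mb for #2-#3) are reproduced from
    the probe coordinates.
    """
    _check_same_chrom(a, b)
    return max(a.end, b.end) - min(a.start, b.start) + 1


def distance_label(a: GenomicInterval, b: GenomicInterval) -> float:
    """Genomic distance label in Mb, one decimal, half-away-from-zero rounding.

    Overlapping intervals are labelled 0.0 Mb; otherwise the outermost span is
    rounded to one decimal (2.550425 Mb -> 2.6).
    """
    if overlap_bp(a, b) > 0:
        return 0.0
    mb = decimal.Decimal(pair_span(a, b)) / decimal.Decimal(10**6)
    return float(mb.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


# --- probe panel -----------------------------------------------------------

PROBE_ROLES = ("anchor_proximal", "loop_interior")

# The five BAC probes on 15q12-q13.1 (1-based closed, hg19-like).
_DEFAULT_PROBES = (
    GenomicInterval("chr15", 25_540_816, 25_708_423, "RP11-339C21"),
    GenomicInterval("chr15", 26_450_149, 26_643_939, "RP11-299F22"),
    GenomicInterval("chr15", 27_604_108, 27_745_105, "RP11-39L5"),
    GenomicInterval("chr15", 27_894_428, 28_091_240, "RP11-640H21"),
    GenomicInterval("chr15", 28_042_426, 28_192_499, "RP11-142A11"),
)
# Probes #1, #4, #5 sit close to loop borders; #2 and #3 are loop-interior.
_DEFAULT_ROLES = (
    "anchor_proximal",
    "loop_interior",
    "loop_interior",
    "anchor_proximal",
    "anchor_proximal",
)


@dataclass(frozen=True)
class ProbePanel:
    """Ordered FISH probe panel (#1..#n) with a role per probe."""

    probes: tuple[GenomicInterval, ...] = _DEFAULT_PROBES
    roles: tuple[str, ...] = _DEFAULT_ROLES

    def __post_init__(self) -> None:
        if len(self.probes) != len(self.roles):
            raise ValueError("one role per probe required")
        for r in self.roles:
            if r not in PROBE_ROLES:
                raise ValueError(f"unknown probe role {r!r}")

    def probe(self, number: int) -> GenomicInterval:
        """Probe by 1-based panel number (#1..#n)."""
        if not 1 <= number <= len(self.probes):
            raise KeyError(f"panel has probes #1..#{len(self.probes)}, got #{number}")
        return self.probes[number - 1]

    def __len__(self) -> int:
        return len(self.probes)


def default_probe_panel() -> ProbePanel:
    """The five-BAC panel covering the 3 Mb HERC2/OCA2 region."""
    return ProbePanel()


def load_probe_panel(path: str | Path) -> ProbePanel:
    """Load a probe panel from TSV (columns: number, name, chrom, start, end, role).

    Coordinates in the TSV are 1-based fully closed, matching the in-memory
    convention. Rows are ordered by the ``number`` column.
    """
    import csv

    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(row)
    rows.sort(key=lambda r: int(r["number"]))
    probes = tuple(
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["name"])
        for r in rows
    )
    roles = tuple(r["role"] for r in rows)
    return ProbePanel(probes=probes, roles=roles)


def packaged_probe_panel_path() -> Path:
    """Path of the probe-panel TSV shipped as package data."""
    from importlib import resources

    return Path(str(resources.files("loopdist").joinpath("data/probe_panel.tsv")))


# --- loop annotation -------------------------------------------------------


@dataclass(frozen=True)
class LoopAnnotation:
    """Three contiguous chromatin loops tiling [B0, B3] on one chromosome.

    Boundaries are strictly increasing; loop *i* occupies the half-open span
    ``[B_i, B_{i+1})``, except the last loop which is closed at its right
    boundary, so every position inside the region belongs to exactly one loop.
    """

    chrom: str
    boundaries: tuple[int, ...]
    labels: tuple[str, ...]
    genes: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.labels) + 1:
            raise ValueError("need len(labels)+1 boundaries")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if self.genes and len(self.genes) != len(self.labels):
            raise ValueError("one gene tuple per loop when genes are given")

    @property
    def n_loops(self) -> int:
        return len(self.labels)

    @property
    def span(self) -> tuple[int, int]:
        return self.boundaries[0], self.boundaries[-1]

    def loop_sizes(self) -> tuple[int, ...]:
        return tuple(
            b2 - b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])
        )


def default_loop_annotation() -> LoopAnnotation:
    """Default three-loop annotation of 15q12-q13.1 (hg19-like).

    The loop borders are a reconstruction from the region's domain structure
    (no exact border coordinates are published): loop a holds ATP10A and
    GABRB3, loop b holds GABRA5, GABRG3 and OCA2, and loop c — the smallest —
    holds only HERC2. All boundaries are overridable.
    """
    return LoopAnnotation(
        chrom="chr15",
        boundaries=(25_580_000, 26_700_000, 28_360_000, 28_600_000),
        labels=("a", "b", "c"),
        genes=(
            ("ATP10A", "GABRB3"),
            ("GABRA5", "GABRG3", "OCA2"),
            ("HERC2",),
        ),
    )


def assign_loop(position: int | float, loops: LoopAnnotation) -> str | None:
    """Label of the loop containing ``position``, or ``None`` outside the region.

    Ownership is half-open ``[B_i, B_{i+1})`` with the final loop closed at B3.
    """
    bs = loops.boundaries
    if position < bs[0] or position > bs[-1]:
        return None
    for label, b1, b2 in zip(loops.labels, bs, bs[1:]):
        if b1 <= position < b2:
            return label
    return loops.labels[-1]  # position == B3


# --- BED I/O ---------------------------------------------------------------


class BedFormatError(ValueError):
    """Malformed BED line, with the 1-based line number in the message."""


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into 1-based closed intervals.

    On-disk 0-based half-open ``(chromStart, chromEnd)`` becomes
    ``(chromStart + 1, chromEnd)`` in memory. Comment (``#``), ``track`` and
    ``browser`` lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: expected >= 3 fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start0 = int(fields[1])
                end0 = int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if end0 <= start0:
                raise BedFormatError(f"line {lineno}: chromEnd must exceed chromStart")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise BedFormatError(f"line {lineno}: bad strand {strand!r}")
            out.append(GenomicInterval(chrom, start0 + 1, end0, name, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )
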