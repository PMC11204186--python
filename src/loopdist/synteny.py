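"""Synteny conservation checks for the six-gene HERC2/OCA2 region.

Given per-species gene tables (the six panel genes ATP10A, GABRB3, GABRA5,
GABRG3, OCA2, HERC2 with coordinates and strand), checks conservation of
gene order, transcriptional orientation, and the HERC2/OCA2 head-to-tail
arrangement (the 3' end of HERC2 facing the OCA2 gene) across vertebrates.
A whole-region inversion (every strand flipped, order reversed) counts as
concordant and is flagged, since it preserves all relative arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .coords import GenomicInterval, read_bed

__all__ = [
    "PANEL_GENES",
    "GeneTable",
    "SyntenyReport",
    "load_gene_table",
    "packaged_species",
    "load_packaged_tables",
    "order_vector",
    "orientation_concordant",
    "head_to_tail",
    "conservation_summary",
    "ascii_diagram",
]

PANEL_GENES = ("ATP10A", "GABRB3", "GABRA5", "GABRG3", "OCA2", "HERC2")


@dataclass(frozen=True)
class GeneTable:
    """One species' panel genes, symbols unique, strands oriented."""

    species: str
    genes: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        symbols = [g.name for g in self.genes]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbol(s) in {self.species}: {dupes}")
        unknown = sorted(set(symbols) - set(PANEL_GENES))
        if unknown:
            raise ValueError(f"unknown gene symbol(s) in {self.species}: {unknown}")
        for g in self.genes:
            if g.strand not in ("+", "-"):
                raise ValueError(f"{self.species}/{g.name}: strand must be + or -")

    def gene(self, symbol: str) -> GenomicInterval:
        for g in self.genes:
            if g.name == symbol:
                return g
        raise KeyError(f"{symbol} not present in {self.species} table")

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(g.name for g in self.genes)

    def mirrored(self) -> "GeneTable":
        """Whole-region inversion: coordinates reflected, strands flipped."""
        pivot = max(g.end for g in self.genes) + min(g.start for g in self.genes)
        flipped = tuple(
            GenomicInterval(
                g.chrom,
                pivot - g.end,
                pivot - g.start,
                g.name,
                "+" if g.strand == "-" else "-",
            )
            for g in self.genes
        )
        return GeneTable(self.species, flipped)


def load_gene_table(path: str | Path, species: str | None = None) -> GeneTable:
    """Read a species gene table from BED6."""
    path = Path(path)
    name = species if species is not None else path.stem.removeprefix("genes_")
    return GeneTable(species=name, genes=tuple(read_bed(path)))


def packaged_species() -> list[str]:
    """Species with a packaged gene-table fixture, human first."""
    files = resources.files("loopdist").joinpath("data")
    names = sorted(
        p.name.removeprefix("genes_").removesuffix(".bed")
        for p in files.iterdir()
        if p.name.startswith("genes_") and p.name.endswith(".bed")
    )
    names.remove("human")
    return ["human"] + names


def load_packaged_tables() -> dict[str, GeneTable]:
    """All packaged species fixtures keyed by species name."""
    files = resources.files("loopdist").joinpath("data")
    out = {}
    for sp in packaged_species():
        with resources.as_file(files.joinpath(f"genes_{sp}.bed")) as p:
            out[sp] = load_gene_table(p, species=sp)
    return out


def order_vector(table: GeneTable) -> tuple[str, ...]:
    """Gene symbols sorted by interval midpoint (robust to nesting/overlap)."""
    if len(table.genes) < 1:
        raise ValueError("empty gene table")
    return tuple(g.name for g in sorted(table.genes, key=lambda g: g.midpoint))


def orientation_concordant(a: GeneTable, b: GeneTable) -> tuple[bool, bool]:
    """Do two species share gene order and relative orientation?

    Returns ``(concordant, inverted)``: concordant directly (same order,
    same strand per gene) or after a whole-region inversion of ``b``
    (order reversed and every strand flipped), in which case ``inverted``
    is True. A single-gene strand flip breaks both matchings.
    """
    if a.symbols != b.symbols:
        missing_in_b = sorted(a.symbols - b.symbols)
        missing_in_a = sorted(b.symbols - a.symbols)
        raise ValueError(
            f"gene sets differ: missing in {b.species}: {missing_in_b}; "
            f"missing in {a.species}: {missing_in_a}"
        )
    order_a = order_vector(a)
    strands_a = tuple(a.gene(s).strand for s in order_a)

    order_b = order_vector(b)
    strands_b = tuple(b.gene(s).strand for s in order_b)
    if order_a == order_b and strands_a == strands_b:
        return True, False

    flipped = {"+": "-", "-": "+"}
    order_b_inv = tuple(reversed(order_b))
    strands_b_inv = tuple(flipped[s] for s in reversed(strands_b))
    if order_a == order_b_inv and strands_a == strands_b_inv:
        return True, True
    return False, False


def head_to_tail(
    table: GeneTable, upstream_gene: str = "HERC2", downstream_gene: str = "OCA2"
) -> bool:
    """Is the upstream gene's 3' end facing the downstream gene, co-oriented?

    True iff both genes share a strand, no other panel gene lies between
    them, the strand-aware 3' terminus of the upstream gene is its endpoint
    nearest the downstream gene, and transcription of both runs from that
    3' end across the downstream gene. Invariant under whole-region
    inversion and coordinate translation.
    """
    up = table.gene(upstream_gene)
    down = table.gene(downstream_gene)
    if up.strand != down.strand:
        return False
    lo, hi = sorted((up.midpoint, down.midpoint))
    for g in table.genes:
        if g.name in (upstream_gene, downstream_gene):
            continue
        if lo < g.midpoint < hi:
            return False
    three_prime = up.end if up.strand == "+" else up.start
    five_prime = up.start if up.strand == "+" else up.end
    # 3' terminus must be the endpoint nearest the downstream gene ...
    if abs(three_prime - down.midpoint) >= abs(five_prime - down.midpoint):
        return False
    # ... with transcription continuing from it across the downstream gene
    if up.strand == "+":
        return down.midpoint > three_prime
    return down.midpoint < three_prime


@dataclass(frozen=True)
class SyntenyReport:
    """Per-species conservation flags and the overall conserved fraction."""

    table: pd.DataFrame  # species, order, concordant, inverted, head_to_tail, conserved
    conserved_fraction: float


def conservation_summary(
    tables: dict[str, GeneTable], reference: str = "human"
) -> SyntenyReport:
    """Compare every species against the reference species.

    A species is *conserved* when its gene order and orientation are
    concordant with the reference (whole-region inversion tolerated and
    flagged) and its HERC2/OCA2 pair is head-to-tail. The fraction counts
    conserved species over all species including the reference.
    """
    if reference not in tables:
        raise KeyError(f"reference species {reference!r} not among tables")
    ref = tables[reference]
    rows = []
    for sp in sorted(tables, key=lambda s: (s != reference, s)):
        t = tables[sp]
        try:
            concordant, inverted = orientation_concordant(ref, t)
        except ValueError:
            concordant, inverted = False, False
        h2t = (
            head_to_tail(t)
            if {"HERC2", "OCA2"} <= set(t.symbols)
            else False
        )
        rows.append(
            {
                "species": sp,
                "order": ">".join(order_vector(t)),
                "concordant_with_reference": concordant,
                "whole_region_inversion": inverted,
                "head_to_tail": h2t,
                "conserved": concordant and h2t,
            }
        )
    df = pd.DataFrame(rows)
    return SyntenyReport(table=df, conserved_fraction=float(df["conserved"].mean()))


def ascii_diagram(tables: dict[str, GeneTable], reference: str = "human") -> str:
    """Per-species gene order/strand sketch (arrows show transcription)."""
    lines = []
    width = max(len(s) for s in tables) + 2
    for sp in sorted(tables, key=lambda s: (s != reference, s)):
        t = tables[sp]
        parts = []
        for sym in order_vector(t):
            arrow = f"{sym}>" if t.gene(sym).strand == "+" else f"<{sym}"
            parts.append(arrow)
        lines.append(f"{sp:<{width}}" + " ".join(parts))
    return "\n".join(lines)
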