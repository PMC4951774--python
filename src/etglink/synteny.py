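"""Conserved synteny score (CSS) from pairwise alignment block maps.

For a pair (e, g) and each non-reference species s, the enhancer region and
the gene's promoter are lifted through the species' alignment blocks.  When
both land on the same target chromosome, d_s(e, g) is the gap in bp between
the two lifted spans (0 if they overlap).  The score aggregates over species
weighted by phylogenetic distance phi(r, s) from the reference r:

    CSS(e, g) = sum_s phi(r, s) * c_s  /  sum_s phi(r, s)

with per-species conservation c_s = max(0, 1 - d_s / theta) under the
default linear decay kernel (theta = 2 Mb), or c_s = [d_s <= theta] under
the indicator kernel.  A species where either region fails to lift, or the
two regions lift to different chromosomes, contributes c_s = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from intervaltree import IntervalTree

from .genomic import Enhancer, Gene, GenomicInterval, ParameterSet, ParseError, promoter_of

DecayKernel = Literal["linear", "indicator"]


@dataclass(frozen=True)
class AlignmentBlock:
    ref: GenomicInterval
    target_chrom: str
    target_start: int
    target_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if not self.target_start < self.target_end:
            raise ValueError("target_start must be < target_end")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass
class AlignmentBlockMap:
    """One species' pairwise alignment, as colinear liftover blocks.

    Reference blocks must not overlap one another within a map.
    """

    species: str
    blocks: Sequence[AlignmentBlock]
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        trees: dict[str, IntervalTree] = {}
        for b in self.blocks:
            tree = trees.setdefault(b.ref.chrom, IntervalTree())
            if tree.overlap(b.ref.start, b.ref.end):
                raise ValueError(
                    f"{self.species}: overlapping reference blocks at "
                    f"{b.ref.chrom}:{b.ref.start}-{b.ref.end}"
                )
            tree.addi(b.ref.start, b.ref.end, b)
        self._trees = trees

    def overlapping(self, iv: GenomicInterval) -> list[AlignmentBlock]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda b: b.ref.start)
        return hits


@dataclass(frozen=True)
class MappedRegion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class SyntenyResult:
    """Per-species lifted distances and the aggregated score."""

    distances: Mapping[str, float | None]
    css: float


def _lift_block_overlap(block: AlignmentBlock, iv: GenomicInterval) -> tuple[int, int]:
    """Target coordinates of the part of ``iv`` covered by ``block``.

    Coordinates interpolate linearly across the block, reversed for '-'
    orientation blocks.
    """
    a = max(block.ref.start, iv.start)
    b = min(block.ref.end, iv.end)
    ref_len = len(block.ref)
    tgt_len = block.target_end - block.target_start
    scale = tgt_len / ref_len
    lo_off = (a - block.ref.start) * scale
    hi_off = (b - block.ref.start) * scale
    if block.orientation == "+":
        lo = block.target_start + lo_off
        hi = block.target_start + hi_off
    else:
        lo = block.target_end - hi_off
        hi = block.target_end - lo_off
    start, end = int(math.floor(lo)), int(math.ceil(hi))
    return start, max(end, start + 1)


def map_region(block_map: AlignmentBlockMap, iv: GenomicInterval) -> MappedRegion | None:
    """Lift ``iv`` through the species' blocks.

    When overlapping blocks point at several target chromosomes, the
    chromosome with the largest total reference overlap wins; the result is
    the span of that chromosome's lifted pieces.  ``None`` when no block
    overlaps.
    """
    hits = block_map.overlapping(iv)
    if not hits:
        return None
    per_chrom: dict[str, tuple[int, int, int]] = {}  # chrom -> (overlap, lo, hi)
    for b in hits:
        ov = min(b.ref.end, iv.end) - max(b.ref.start, iv.start)
        lo, hi = _lift_block_overlap(b, iv)
        if b.target_chrom in per_chrom:
            tot, clo, chi = per_chrom[b.target_chrom]
            per_chrom[b.target_chrom] = (tot + ov, min(clo, lo), max(chi, hi))
        else:
            per_chrom[b.target_chrom] = (ov, lo, hi)
    chrom = max(per_chrom, key=lambda c: (per_chrom[c][0], c))
    _, lo, hi = per_chrom[chrom]
    return MappedRegion(chrom, lo, hi)


def species_distance(
    block_map: AlignmentBlockMap,
    enhancer: Enhancer,
    gene: Gene,
    params: ParameterSet = ParameterSet(),
) -> float | None:
    """d_s(e, g): gap between the lifted enhancer and promoter spans.

    ``None`` (absent) when either region fails to lift or the two regions
    lift to different target chromosomes; 0 when the spans overlap.
    """
    m_e = map_region(block_map, enhancer.region)
    m_g = map_region(block_map, promoter_of(gene, params))
    if m_e is None or m_g is None or m_e.chrom != m_g.chrom:
        return None
    gap = max(m_e.start, m_g.start) - min(m_e.end, m_g.end)
    return float(max(0, gap))


@dataclass(frozen=True)
class PhyloDistanceTable:
    """Branch-length distances phi(r, s) from the reference species."""

    distances: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.distances:
            raise ValueError("at least one species required")
        for s, phi in self.distances.items():
            if phi <= 0:
                raise ValueError(f"phi({s}) must be > 0")

    def __getitem__(self, species: str) -> float:
        return self.distances[species]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhyloDistanceTable":
        """2-column TSV: species <tab> phi."""
        out: dict[str, float] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns")
                if fields[0] in out:
                    raise ParseError(f"{path}:{lineno}: duplicate species {fields[0]!r}")
                out[fields[0]] = float(fields[1])
        return cls(out)

    @classmethod
    def from_newick(cls, path: str | Path, reference: str) -> "PhyloDistanceTable":
        """Patristic distances from ``reference`` to every other leaf."""
        from Bio import Phylo

        tree = Phylo.read(str(path), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        if reference not in leaves:
            raise ValueError(f"reference {reference!r} not a leaf of the tree")
        return cls(
            {name: tree.distance(reference, name) for name in leaves if name != reference}
        )


def read_block_maps(path: str | Path) -> list[AlignmentBlockMap]:
    """Read per-species alignment blocks from TSV.

    Columns: species, ref_chrom, ref_start, ref_end, tgt_chrom, tgt_start,
    tgt_end, orientation.
    """
    per_species: dict[str, list[AlignmentBlock]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns")
            try:
                block = AlignmentBlock(
                    GenomicInterval(fields[1], int(fields[2]), int(fields[3])),
                    fields[4],
                    int(fields[5]),
                    int(fields[6]),
                    fields[7],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            per_species.setdefault(fields[0], []).append(block)
    return [AlignmentBlockMap(sp, blocks) for sp, blocks in per_species.items()]


def css_score(
    enhancer: Enhancer,
    gene: Gene,
    maps: Sequence[AlignmentBlockMap],
    phylo: PhyloDistanceTable,
    params: ParameterSet = ParameterSet(),
    kernel: DecayKernel = "linear",
) -> SyntenyResult:
    """Phylogenetically weighted conserved-synteny score in [0, 1]."""
    if not maps:
        raise ValueError("at least one species map required")
    distances: dict[str, float | None] = {}
    num = 0.0
    den = 0.0
    for m in maps:
        phi = phylo[m.species]
        d = species_distance(m, enhancer, gene, params)
        distances[m.species] = d
        if d is None:
            c = 0.0
        elif kernel == "linear":
            c = max(0.0, 1.0 - d / params.theta)
        else:
            c = 1.0 if d <= params.theta else 0.0
        num += phi * c
        den += phi
    return SyntenyResult(distances, num / den)
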