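"""Genomic coordinate primitives, annotation I/O and the candidate-gene window.

All internal coordinates are 0-based half-open (BED convention).  GTF/GFF3
inputs, which are 1-based inclusive, are converted on read.  An enhancer's
"endpoints" are its first and last covered base (``start`` and ``end - 1``).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Enhancer:
    enhancer_id: str
    region: GenomicInterval


@dataclass(frozen=True)
class ParameterSet:
    """Tunable constants of the prediction pipeline.

    Defaults: candidate genes are sought within 2 Mb of the enhancer, the
    synteny decay cutoff theta is 2 Mb, the promoter spans 1 kb upstream to
    100 bp downstream of the TSS, Hi-C matrices are 5-kb binned, the forest
    has 500 trees and calls a target at probability >= 0.95, and contact
    support requires at least 5 kb enhancer-promoter separation.
    """

    candidate_window: int = 2_000_000
    theta: int = 2_000_000
    promoter_upstream: int = 1_000
    promoter_downstream: int = 100
    hic_resolution: int = 5_000
    score_cutoff: float = 0.95
    n_trees: int = 500
    min_separation: int = 5_000

    def __post_init__(self) -> None:
        for name in (
            "candidate_window",
            "theta",
            "promoter_upstream",
            "promoter_downstream",
            "hic_resolution",
            "n_trees",
            "min_separation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.score_cutoff < 1.0:
            raise ValueError("score_cutoff must be in (0, 1)")


# ---------------------------------------------------------------------------
# I/O


def read_enhancers(path: str | Path) -> list[Enhancer]:
    """Read enhancers from a BED file (>= 3 columns).

    Ids come from column 4 when present, otherwise ``chrom:start-end``.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    enhancers: list[Enhancer] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            eid = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"{chrom}:{start}-{end}"
            if eid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate enhancer id {eid!r}")
            seen.add(eid)
            try:
                enhancers.append(Enhancer(eid, GenomicInterval(chrom, start, end)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return enhancers


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item and '"' not in item:  # GFF3 style key=value
            key, _, value = item.partition("=")
            out[key.strip()] = value.strip()
        else:  # GTF style key "value"
            key, _, value = item.partition(" ")
            out[key.strip()] = value.strip().strip('"')
    return out


def read_genes(path: str | Path) -> list[Gene]:
    """Read genes from GTF/GFF3 (``gene`` features) or 4-column TSV.

    The tabular dialect is ``gene_id <tab> chrom <tab> tss <tab> strand``
    with 0-based TSS.  GTF/GFF coordinates are 1-based inclusive; the TSS is
    the feature start for + genes and the feature end for - genes, converted
    to 0-based.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for first in fh:
            if first.strip() and not first.startswith("#"):
                break
    is_gtf = path.suffix.lower() in {".gtf", ".gff", ".gff3"} or (
        first.count("\t") >= 7
    )
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gtf:
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF/GFF columns")
                if fields[2] != "gene":
                    continue
                chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                try:
                    start1i, end1i = int(start1), int(end1)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
                attrs = _parse_gtf_attributes(fields[8])
                gid = attrs.get("gene_id") or attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
                tss = start1i - 1 if strand == "+" else end1i - 1
                genes.append(Gene(gid, chrom, tss, strand, attrs.get("gene_name")))
            else:
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 tabular columns")
                gid, chrom, tss_s, strand = fields[:4]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                try:
                    tss = int(tss_s)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric TSS") from exc
                genes.append(Gene(gid, chrom, tss, strand))
    return genes


# ---------------------------------------------------------------------------
# Windows and distances


def promoter_of(gene: Gene, params: ParameterSet = ParameterSet()) -> GenomicInterval:
    """Strand-aware promoter window, by default [TSS-1000, TSS+100) on +.

    Clamped at position 0 near a chromosome start.
    """
    up, down = params.promoter_upstream, params.promoter_downstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down + 1, gene.tss + up + 1
    return GenomicInterval(gene.chrom, max(0, start), end)


def distance_of(enhancer: Enhancer, gene: Gene) -> float:
    """Minimum distance from either enhancer endpoint to the gene's TSS.

    Zero when the TSS falls inside the enhancer; ``math.inf`` when enhancer
    and gene sit on different chromosomes (never a candidate).
    """
    region = enhancer.region
    if region.chrom != gene.chrom:
        return math.inf
    if region.start <= gene.tss < region.end:
        return 0
    return min(abs(region.start - gene.tss), abs(region.end - 1 - gene.tss))


@dataclass
class GeneIndex:
    """Genes bucketed per chromosome and sorted by TSS for window queries."""

    genes: Sequence[Gene]
    _by_chrom: dict[str, list[Gene]] = field(init=False, repr=False)
    _tss: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: (g.tss, g.gene_id))
        self._by_chrom = by_chrom
        self._tss = {c: [g.tss for g in gl] for c, gl in by_chrom.items()}

    def in_window(self, chrom: str, lo: int, hi: int) -> list[Gene]:
        """Genes with lo <= tss <= hi on chrom, in TSS order."""
        glist = self._by_chrom.get(chrom, [])
        tss = self._tss.get(chrom, [])
        return glist[bisect_left(tss, lo) : bisect_right(tss, hi)]


def candidate_genes(
    enhancer: Enhancer,
    genes: Sequence[Gene] | GeneIndex,
    params: ParameterSet = ParameterSet(),
) -> list[Gene]:
    """All genes whose TSS lies within ``candidate_window`` of the enhancer.

    "Within" is inclusive: a gene at exactly the window distance is kept.
    Returned in TSS order.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    region = enhancer.region
    lo = region.start - params.candidate_window
    hi = region.end - 1 + params.candidate_window
    return [
        g
        for g in index.in_window(region.chrom, lo, hi)
        if distance_of(enhancer, g) <= params.candidate_window
    ]


def iter_candidate_pairs(
    enhancers: Iterable[Enhancer],
    genes: Sequence[Gene] | GeneIndex,
    params: ParameterSet = ParameterSet(),
):
    """Yield every (enhancer, candidate gene) pair."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    for e in enhancers:
        for g in candidate_genes(e, index, params):
            yield e, g
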