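"""DNase-hypersensitivity activity tracks and the correlation feature.

The activity of a region in a cell type is its mean per-bp bedGraph signal
(uncovered bases count as 0).  The correlation feature of a pair is the
Spearman rank correlation between the enhancer's and the promoter's activity
vectors across the cell-type panel; a constant vector gives 0 so the feature
is always populated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .genomic import Enhancer, Gene, GenomicInterval, ParameterSet, ParseError, promoter_of


@dataclass
class CoverageTrack:
    """Piecewise-constant per-bp coverage from a bedGraph file."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 3) rows start,end,value

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
                if start >= end or value < 0:
                    raise ParseError(f"{path}:{lineno}: invalid interval or value")
                per_chrom.setdefault(fields[0], []).append((start, end, value))
        track = cls()
        for chrom, rows in per_chrom.items():
            rows.sort()
            track.intervals[chrom] = np.array(rows, dtype=float)
        return track

    def region_signal(self, iv: GenomicInterval) -> float:
        """Mean per-bp signal over ``iv``; uncovered bases contribute 0."""
        rows = self.intervals.get(iv.chrom)
        if rows is None or len(rows) == 0:
            return 0.0
        starts, ends, values = rows[:, 0], rows[:, 1], rows[:, 2]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        total = float((np.clip(ov, 0, None) * values[lo:hi]).sum())
        return total / len(iv)


@dataclass
class SignalTrackSet:
    """Ordered panel of per-cell-type coverage tracks."""

    tracks: Mapping[str, CoverageTrack]

    def __post_init__(self) -> None:
        self.cell_types = list(self.tracks)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "SignalTrackSet":
        """Panel manifest TSV: cell_type <tab> bedGraph path (relative to the
        manifest's directory unless absolute)."""
        base = Path(path).parent
        tracks: dict[str, CoverageTrack] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cell, _, p = line.partition("\t")
                track_path = Path(p)
                if not track_path.is_absolute():
                    track_path = base / track_path
                tracks[cell] = CoverageTrack.from_bedgraph(track_path)
        return cls(tracks)

    def activity_vector(self, iv: GenomicInterval) -> np.ndarray:
        return np.array(
            [self.tracks[c].region_signal(iv) for c in self.cell_types], dtype=float
        )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho with average ranks for ties; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    rho = spearmanr(x, y).statistic
    return float(rho)


def correlation_feature(
    enhancer: Enhancer,
    gene: Gene,
    tracks: SignalTrackSet,
    params: ParameterSet = ParameterSet(),
) -> float:
    """Spearman correlation of enhancer vs promoter DHS activity."""
    if len(tracks.cell_types) < 3:
        raise ValueError("correlation needs >= 3 cell types")
    v_e = tracks.activity_vector(enhancer.region)
    v_p = tracks.activity_vector(promoter_of(gene, params))
    return spearman_rho(v_e, v_p)
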