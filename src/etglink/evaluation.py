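"""Evaluation harness: confusion counts, metrics, ROC AUC, Hi-C support,
random-pair nulls and target-gene inconsecutiveness.

Predicted and known pairs are matched by dual region overlap: a prediction
is a true positive when its enhancer region shares at least 1 bp with one
region of a known pair and its promoter region shares at least 1 bp with
the other.  One prediction matching several known pairs counts once, and a
known pair recovered by several predictions is recovered once, so recall
never exceeds 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .genomic import (
    Enhancer,
    Gene,
    GeneIndex,
    GenomicInterval,
    ParameterSet,
    ParseError,
    candidate_genes,
    distance_of,
    promoter_of,
)


@dataclass(frozen=True)
class RegionPair:
    """A pair of genomic regions: enhancer and promoter."""

    enhancer: GenomicInterval
    promoter: GenomicInterval

    def matches(self, other: "RegionPair") -> bool:
        """Dual-region overlap, in either orientation of the known pair."""
        return (
            self.enhancer.overlaps(other.enhancer)
            and self.promoter.overlaps(other.promoter)
        ) or (
            self.enhancer.overlaps(other.promoter)
            and self.promoter.overlaps(other.enhancer)
        )


def region_pair(enhancer: Enhancer, gene: Gene, params: ParameterSet = ParameterSet()) -> RegionPair:
    return RegionPair(enhancer.region, promoter_of(gene, params))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    """Recall / precision / F1 with the raw pair tallies.

    Undefined ratios (zero denominators) are ``None``, never silently 0.
    """

    n_known: int
    n_predicted: int
    n_known_predicted: int
    recall: float | None
    precision: float | None
    f1: float | None
    roc_auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_known": self.n_known,
            "n_predicted": self.n_predicted,
            "n_known_predicted": self.n_known_predicted,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
        }


def confusion(
    predicted: Sequence[RegionPair],
    known_positive: Sequence[RegionPair],
    known_negative: Sequence[RegionPair] = (),
) -> ConfusionCounts:
    """Confusion counts under dual-region overlap matching."""
    pred_is_tp = [any(p.matches(k) for k in known_positive) for p in predicted]
    tp = sum(pred_is_tp)
    fp = len(predicted) - tp
    fn = sum(1 for k in known_positive if not any(p.matches(k) for p in predicted))
    tn = sum(1 for k in known_negative if not any(p.matches(k) for p in predicted))
    return ConfusionCounts(tp, fp, fn, tn)


def metrics_from_counts(
    n_known: int, n_predicted: int, n_known_predicted: int
) -> MetricReport:
    """Recall = recovered/known, precision = recovered/predicted, F1 their
    harmonic mean — the tally arithmetic used for benchmark tables."""
    recall = n_known_predicted / n_known if n_known else None
    precision = n_known_predicted / n_predicted if n_predicted else None
    f1 = None
    if recall is not None and precision is not None and (recall + precision) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(n_known, n_predicted, n_known_predicted, recall, precision, f1)


def metrics(c: ConfusionCounts) -> MetricReport:
    return metrics_from_counts(c.tp + c.fn, c.tp + c.fp, c.tp)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties handled so the value equals the
    Mann-Whitney rank statistic."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc needs both labels present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Hi-C contact support


@dataclass
class ContactMatrix:
    """Sparse normalized contact counts on fixed-width genomic bins.

    Bins are ``floor(position / resolution)``; triplets are symmetric
    (queries check both bin orders).
    """

    resolution: int
    counts: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, resolution: int = 5_000) -> "ContactMatrix":
        """Triplet TSV: chrom, bin_i_start, bin_j_start, count (bp starts,
        multiples of the resolution)."""
        cm = cls(resolution)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns")
                chrom, i_s, j_s, c_s = fields[:4]
                try:
                    i, j, count = int(i_s), int(j_s), float(c_s)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed triplet") from exc
                if i % resolution or j % resolution:
                    raise ParseError(
                        f"{path}:{lineno}: bin start not a multiple of {resolution}"
                    )
                cm.add(chrom, i // resolution, j // resolution, count)
        return cm

    def add(self, chrom: str, bin_i: int, bin_j: int, count: float) -> None:
        per = self.counts.setdefault(chrom, {})
        key = (min(bin_i, bin_j), max(bin_i, bin_j))
        per[key] = per.get(key, 0.0) + count

    def count(self, chrom: str, bin_i: int, bin_j: int) -> float:
        key = (min(bin_i, bin_j), max(bin_i, bin_j))
        return self.counts.get(chrom, {}).get(key, 0.0)


def region_bins(iv: GenomicInterval, resolution: int) -> range:
    return range(iv.start // resolution, (iv.end - 1) // resolution + 1)


def hic_support(
    pairs: Sequence[tuple[Enhancer, Gene]],
    cm: ContactMatrix,
    read_cutoff: float,
    params: ParameterSet = ParameterSet(),
) -> list[bool]:
    """Flag pairs supported by the contact matrix at ``read_cutoff``.

    A pair is supported when the enhancer and promoter are at least
    ``min_separation`` apart and some bin pair (one bin overlapping the
    enhancer, one the promoter) carries at least ``read_cutoff`` reads.
    """
    if cm.resolution != params.hic_resolution:
        raise ValueError(
            f"contact matrix resolution {cm.resolution} != expected {params.hic_resolution}"
        )
    out = []
    for e, g in pairs:
        if distance_of(e, g) < params.min_separation:
            out.append(False)
            continue
        prom = promoter_of(g, params)
        supported = False
        for bi in region_bins(e.region, cm.resolution):
            for bj in region_bins(prom, cm.resolution):
                if cm.count(e.region.chrom, bi, bj) >= read_cutoff:
                    supported = True
                    break
            if supported:
                break
        out.append(supported)
    return out


# ---------------------------------------------------------------------------
# Null models and pair-layout statistics


def random_pairs(
    enhancers: Sequence[Enhancer],
    genes: Sequence[Gene] | GeneIndex,
    window: int,
    n: int,
    seed: int = 0,
    params: ParameterSet = ParameterSet(),
) -> list[tuple[Enhancer, Gene]]:
    """Null pairs: for each draw, a random enhancer and a random gene within
    ``window`` of it.  Reproducible per seed."""
    import dataclasses

    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    win_params = dataclasses.replace(params, candidate_window=window)
    neighbourhoods = [
        (e, cands)
        for e in enhancers
        if (cands := candidate_genes(e, index, win_params))
    ]
    if not neighbourhoods:
        raise ValueError("no enhancer has a gene within the window")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        e, cands = neighbourhoods[rng.integers(len(neighbourhoods))]
        out.append((e, cands[rng.integers(len(cands))]))
    return out


def binomial_enrichment(k_supported: int, n: int, p0_null: float) -> float:
    """One-sided upper-tail exact binomial p-value of >= k successes."""
    if not 0 <= k_supported <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 < p0_null < 1.0:
        raise ValueError("require 0 < p0 < 1")
    if k_supported == 0:
        return 1.0
    return float(binom.sf(k_supported - 1, n, p0_null))


def inconsecutiveness(
    targets_by_enhancer: Mapping[str, Iterable[str]],
    candidates_by_enhancer: Mapping[str, Sequence[str]],
) -> tuple[dict[str, bool], float]:
    """Fraction of multi-target enhancers whose targets are interrupted.

    ``candidates_by_enhancer`` lists each enhancer's candidate genes in TSS
    order.  An enhancer with >= 2 predicted targets is inconsecutive when a
    non-target candidate lies strictly between two of its targets.  Returns
    per-enhancer flags (for those enhancers only) and their mean; the
    fraction is NaN when no enhancer has two or more targets.
    """
    flags: dict[str, bool] = {}
    for eid, cand in candidates_by_enhancer.items():
        targets = set(targets_by_enhancer.get(eid, ()))
        pos = [i for i, g in enumerate(cand) if g in targets]
        if len(pos) < 2:
            continue
        flags[eid] = any(
            cand[i] not in targets for i in range(pos[0] + 1, pos[-1])
        )
    frac = sum(flags.values()) / len(flags) if flags else math.nan
    return flags, frac
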