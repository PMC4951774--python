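"""End-to-end orchestration over an on-disk input bundle.

This is the library layer the CLI, the self-tests and downstream scripts
share: load every input through its module reader, run motif scanning and
module discovery, assign enhancer GO terms, assemble the feature table,
train/evaluate with an enhancer-level split, and collect the benchmark
statistics (held-out AUC, recall/precision/F1 at the score cutoff, Hi-C
support of predictions vs random pairs, inconsecutiveness of targets).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import activity, evaluation, motif, ontology, synteny
from .features import compute_feature_table
from .genomic import (
    Enhancer,
    Gene,
    GeneIndex,
    ParameterSet,
    candidate_genes,
    read_enhancers,
    read_genes,
)
from .model import EnhancerTargetModel, EnhancerTargetResults, sample_negatives


@dataclass
class InputBundle:
    """All parsed inputs of one prediction run."""

    enhancers: list[Enhancer]
    genes: list[Gene]
    maps: list[synteny.AlignmentBlockMap]
    phylo: synteny.PhyloDistanceTable
    pwms: list[motif.PWM]
    sequences: dict[str, str]
    dag: ontology.GODag
    annotations: ontology.GOAnnotationTable
    tracks: activity.SignalTrackSet | None
    contacts: evaluation.ContactMatrix | None
    truth: pd.DataFrame | None
    params: ParameterSet = ParameterSet()


def load_bundle(
    directory: str | Path, params: ParameterSet = ParameterSet()
) -> InputBundle:
    """Load a fixture-layout directory (see :mod:`etglink.simulate`)."""
    d = Path(directory)
    truth = None
    truth_path = d / "truth_pairs.tsv"
    if truth_path.exists():
        truth = pd.read_csv(
            truth_path, sep="\t", names=["enhancer_id", "gene_id", "label"], comment="#"
        )
    contacts = None
    if (d / "contacts.tsv").exists():
        contacts = evaluation.ContactMatrix.from_tsv(
            d / "contacts.tsv", params.hic_resolution
        )
    tracks = None
    if (d / "panel.tsv").exists():
        tracks = activity.SignalTrackSet.from_manifest(d / "panel.tsv")
    dag = ontology.GODag.from_obo(d / "go.obo")
    annotations = ontology.GOAnnotationTable.from_gaf(d / "annotations.gaf")
    ontology.compute_ic(dag, annotations)
    return InputBundle(
        enhancers=read_enhancers(d / "enhancers.bed"),
        genes=read_genes(d / "genes.gtf"),
        maps=synteny.read_block_maps(d / "blocks.tsv"),
        phylo=synteny.PhyloDistanceTable.from_tsv(d / "phylo.tsv"),
        pwms=motif.read_pwms(d / "pwms.txt"),
        sequences=motif.read_fasta(d / "enhancer_seqs.fa"),
        dag=dag,
        annotations=annotations,
        tracks=tracks,
        contacts=contacts,
        truth=truth,
        params=params,
    )


def discover_and_assign_go(
    bundle: InputBundle,
    threshold_frac: float = 0.8,
    min_support_frac: float = 0.05,
    alpha: float = 0.01,
    fdr: float = 0.05,
) -> tuple[list[motif.MotifModule], dict[str, frozenset[str]]]:
    """Scan sequences, mine motif modules, and derive enhancer GO terms.

    ``min_support_frac`` scales the miner's absolute support threshold with
    the number of enhancers (at least 3).
    """
    occ = motif.scan_motifs(bundle.sequences, bundle.pwms, threshold_frac)
    min_support = max(3, round(min_support_frac * len(bundle.enhancers)))
    modules = motif.discover_modules(occ, min_support=min_support, alpha=alpha)
    terms = motif.assign_enhancer_go(
        bundle.enhancers,
        modules,
        occ,
        bundle.genes,
        bundle.annotations,
        bundle.dag,
        bundle.params,
        fdr,
    )
    return modules, terms


def bundle_feature_table(bundle: InputBundle) -> pd.DataFrame:
    """Labelled feature table for every candidate pair in the bundle."""
    _, enhancer_terms = discover_and_assign_go(bundle)
    labels = None
    if bundle.truth is not None:
        labels = {
            (r.enhancer_id, r.gene_id): int(r.label)
            for r in bundle.truth.itertuples()
        }
    return compute_feature_table(
        bundle.enhancers,
        bundle.genes,
        bundle.maps,
        bundle.phylo,
        enhancer_terms,
        bundle.annotations,
        bundle.dag,
        bundle.tracks,
        bundle.params,
        labels,
    )


def split_by_enhancer(
    table: pd.DataFrame, test_fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split pairs into train/test by enhancer so no enhancer leaks across."""
    rng = np.random.default_rng(seed)
    eids = sorted(table["enhancer_id"].unique())
    n_test = max(1, int(round(test_fraction * len(eids))))
    test_ids = set(rng.permutation(eids)[:n_test].tolist())
    mask = table["enhancer_id"].isin(test_ids)
    return table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def balanced_training_table(
    table: pd.DataFrame, seed: int = 0, n_per_class: int | None = None
) -> pd.DataFrame:
    """Equal numbers of positive and negative pairs, sampled without
    replacement — the balanced-training recipe."""
    pos = table[table["label"] == 1]
    neg = table[table["label"] == 0]
    n = n_per_class or min(len(pos), len(neg))
    if n > min(len(pos), len(neg)):
        raise ValueError("not enough pairs for the requested class size")
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(pos), size=n, replace=False)
    neg_idx = rng.choice(len(neg), size=n, replace=False)
    return pd.concat(
        [pos.iloc[np.sort(pos_idx)], neg.iloc[np.sort(neg_idx)]], ignore_index=True
    )


@dataclass
class BenchmarkResult:
    """Held-out benchmark of one train/test run."""

    results: EnhancerTargetResults
    test_table: pd.DataFrame  # with 'score'
    auc: float
    report: evaluation.MetricReport

    def summary(self) -> str:
        r = self.report
        lines = [
            self.results.summary(),
            "",
            "held-out evaluation",
            "-" * 44,
            f"test pairs:          {len(self.test_table)} "
            f"({r.n_known} positive)",
            f"ROC AUC:             {self.auc:.3f}",
            f"predicted targets:   {r.n_predicted}",
            f"recall:              {_fmt(r.recall)}",
            f"precision:           {_fmt(r.precision)}",
            f"F1 score:            {_fmt(r.f1)}",
        ]
        return "\n".join(lines)


def _fmt(x: float | None) -> str:
    return "undefined" if x is None else f"{x:.3f}"


def train_and_evaluate(
    table: pd.DataFrame,
    params: ParameterSet = ParameterSet(),
    feature_subset: Sequence[str] | None = None,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> BenchmarkResult:
    """Enhancer-level split, balanced training, held-out scoring.

    The returned report counts a known pair as recovered when its own row
    scores at or above the cutoff (identity matching; region-overlap
    matching is for external prediction lists).
    """
    train, test = split_by_enhancer(table, test_fraction, seed)
    balanced = balanced_training_table(train, seed)
    results = EnhancerTargetModel(balanced, params, feature_subset).fit(seed)
    scores = results.score_pairs(test)
    auc = evaluation.roc_auc(scores, test["label"].to_numpy())
    scored = test.copy()
    scored["score"] = scores
    called = scored["score"] >= params.score_cutoff
    n_known = int((scored["label"] == 1).sum())
    n_pred = int(called.sum())
    n_recovered = int((called & (scored["label"] == 1)).sum())
    report = dataclasses.replace(
        evaluation.metrics_from_counts(n_known, n_pred, n_recovered), roc_auc=auc
    )
    return BenchmarkResult(results, scored, auc, report)


def predictions_by_enhancer(scored: pd.DataFrame, cutoff: float) -> dict[str, list[str]]:
    called = scored[scored["score"] >= cutoff]
    return {
        eid: grp["gene_id"].tolist() for eid, grp in called.groupby("enhancer_id")
    }


def candidate_order(bundle: InputBundle) -> dict[str, list[str]]:
    """Each enhancer's candidate genes in TSS order (for inconsecutiveness)."""
    index = GeneIndex(bundle.genes)
    return {
        e.enhancer_id: [g.gene_id for g in candidate_genes(e, index, bundle.params)]
        for e in bundle.enhancers
    }
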