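"""Assembly of the per-pair feature table.

Every (enhancer, candidate gene) pair gets four features: raw bp distance,
conserved synteny score, GO function similarity score and DHS activity
correlation.  The table is a pandas DataFrame with columns ``enhancer_id``,
``gene_id``, ``distance``, ``css``, ``fss``, ``correlation`` and optionally
``label`` — the on-disk form is a tab-separated file with a '#'-prefixed
header line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import activity, motif, ontology, synteny
from .genomic import Enhancer, Gene, GeneIndex, ParameterSet, iter_candidate_pairs

FEATURE_NAMES = ("distance", "css", "fss", "correlation")


def compute_feature_table(
    enhancers: Sequence[Enhancer],
    genes: Sequence[Gene] | GeneIndex,
    maps: Sequence[synteny.AlignmentBlockMap],
    phylo: synteny.PhyloDistanceTable,
    enhancer_terms: Mapping[str, frozenset[str]],
    annotations: ontology.GOAnnotationTable,
    dag: ontology.GODag,
    tracks: activity.SignalTrackSet | None,
    params: ParameterSet = ParameterSet(),
    labels: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Feature rows for every candidate pair within the window.

    ``tracks=None`` leaves the correlation column out (the cross-species
    use case, where no matched DHS panel exists).  ``labels`` maps
    (enhancer_id, gene_id) to 0/1 and adds a ``label`` column restricted to
    the labelled pairs only when given.
    """
    from .genomic import distance_of

    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rows = []
    for e, g in iter_candidate_pairs(enhancers, index, params):
        row: dict[str, object] = {
            "enhancer_id": e.enhancer_id,
            "gene_id": g.gene_id,
            "distance": float(distance_of(e, g)),
            "css": synteny.css_score(e, g, maps, phylo, params).css,
            "fss": ontology.fss_score(
                enhancer_terms.get(e.enhancer_id, frozenset()),
                annotations.terms_of(g.gene_id),
                dag,
            ),
        }
        if tracks is not None:
            row["correlation"] = activity.correlation_feature(e, g, tracks, params)
        if labels is not None:
            key = (e.enhancer_id, g.gene_id)
            if key not in labels:
                continue
            row["label"] = int(labels[key])
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    return df
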