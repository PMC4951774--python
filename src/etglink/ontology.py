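"""Gene Ontology handling: DAG, information content, MICA similarity, FSS.

The information content of a term is IC(t) = -ln(n_t / n_root) where n_t is
the number of genes annotated to t or any of its descendants (annotations
propagated up every is_a path) and n_root the count at the term's namespace
root.  Two terms are compared through their most informative common ancestor
(MICA); the default similarity is the Lin normalisation

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2))

which lies in [0, 1], with raw Resnik IC(MICA) selectable.  Terms from
different namespaces share no ancestor and score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx

SimilarityKind = Literal["lin", "resnik"]


@dataclass
class GODag:
    """GO terms with is_a parents, per-namespace roots and (after
    :func:`compute_ic`) annotation counts and information content."""

    parents: Mapping[str, frozenset[str]]
    namespace: Mapping[str, str]
    term_names: Mapping[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO is_a graph contains a cycle")
        self._graph = g

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestors of ``term`` including the term itself."""
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    @classmethod
    def from_obo(cls, path: str | Path) -> "GODag":
        import obonet

        graph = obonet.read_obo(str(path))
        parents: dict[str, frozenset[str]] = {}
        namespace: dict[str, str] = {}
        names: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            ps = set()
            for _, parent, key in graph.out_edges(term, keys=True):
                if key == "is_a":
                    ps.add(parent)
            parents[term] = frozenset(ps)
            namespace[term] = data.get("namespace", "unknown")
            if "name" in data:
                names[term] = data["name"]
        return cls(parents, namespace, names)


@dataclass
class GOAnnotationTable:
    """Direct gene-to-term annotations; propagation happens in the DAG."""

    direct: Mapping[str, frozenset[str]]

    def genes(self) -> set[str]:
        return set(self.direct)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.direct.get(gene, frozenset())

    def propagated(self, gene: str, dag: GODag) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms_of(gene):
            if t in dag.parents:
                out |= dag.ancestors(t)
        return frozenset(out)

    @classmethod
    def from_gaf(cls, path: str | Path) -> "GOAnnotationTable":
        """Read GAF 2.x; the DB object symbol (column 3) keys each gene."""
        from Bio.UniProt.GOA import gafiterator

        direct: dict[str, set[str]] = {}
        with open(path) as fh:
            for rec in gafiterator(fh):
                if "NOT" in (rec.get("Qualifier") or []):
                    continue
                direct.setdefault(rec["DB_Object_Symbol"], set()).add(rec["GO_ID"])
        return cls({g: frozenset(ts) for g, ts in direct.items()})


def compute_ic(dag: GODag, annotations: GOAnnotationTable) -> GODag:
    """Propagate annotation counts to ancestors and set per-term IC.

    Counts are numbers of distinct genes annotated at or below each term, so
    n_child <= n_parent holds exactly.  Terms with zero count get no IC and
    are excluded from similarity.  Returns ``dag`` mutated in place.
    """
    gene_sets: dict[str, set[str]] = {t: set() for t in dag.parents}
    for gene in annotations.genes():
        for anc in annotations.propagated(gene, dag):
            gene_sets[anc].add(gene)
    dag.counts = {t: len(gs) for t, gs in gene_sets.items()}
    root_count: dict[str, int] = {}
    for root in dag.roots():
        root_count[dag.namespace[root]] = dag.counts[root]
    dag.ic = {}
    for t, n in dag.counts.items():
        n_root = root_count.get(dag.namespace[t], 0)
        if n > 0 and n_root > 0:
            dag.ic[t] = -math.log(n / n_root)
    return dag


def term_similarity(t1: str, t2: str, dag: GODag, kind: SimilarityKind = "lin") -> float:
    """MICA-based semantic similarity of two GO terms.

    Lin similarity is 0 when terms share no informative ancestor (e.g.
    different namespaces, or the only common ancestor is the root).
    """
    if t1 not in dag.ic or t2 not in dag.ic:
        raise ValueError("both terms must have defined information content")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    mica_ic = max((dag.ic[t] for t in common if t in dag.ic), default=0.0)
    if kind == "resnik":
        return mica_ic
    denom = dag.ic[t1] + dag.ic[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * mica_ic / denom


def fss_score(
    enhancer_terms: Iterable[str],
    gene_terms: Iterable[str],
    dag: GODag,
    kind: SimilarityKind = "lin",
) -> float:
    """Function similarity score: best-match average over the two term sets.

    Each term is matched with its best counterpart in the other set; the two
    directional means are averaged.  Either set empty (or holding only
    IC-less terms) gives 0.
    """
    s1 = [t for t in set(enhancer_terms) if t in dag.ic]
    s2 = [t for t in set(gene_terms) if t in dag.ic]
    if not s1 or not s2:
        return 0.0
    sims = [[term_similarity(a, b, dag, kind) for b in s2] for a in s1]
    fwd = sum(max(row) for row in sims) / len(s1)
    rev = sum(max(sims[i][j] for i in range(len(s1))) for j in range(len(s2))) / len(s2)
    return 0.5 * (fwd + rev)


def hypergeom_enrichment(
    study_genes: set[str],
    universe_genes: set[str],
    annotations: GOAnnotationTable,
    dag: GODag,
    fdr: float = 0.05,
) -> dict[str, float]:
    """Terms over-represented in ``study_genes`` vs the gene universe.

    One-sided hypergeometric upper-tail test per propagated term, controlled
    with Benjamini-Hochberg at ``fdr``.  Returns {term: adjusted p} for the
    significant terms.
    """
    from scipy.stats import hypergeom
    from statsmodels.stats.multitest import multipletests

    study = study_genes & universe_genes
    universe_hits: dict[str, int] = {}
    study_hits: dict[str, int] = {}
    for gene in universe_genes:
        for t in annotations.propagated(gene, dag):
            universe_hits[t] = universe_hits.get(t, 0) + 1
            if gene in study:
                study_hits[t] = study_hits.get(t, 0) + 1
    roots = dag.roots()
    terms = [t for t in study_hits if t not in roots]
    if not terms:
        return {}
    m, n = len(universe_genes), len(study)
    pvals = [hypergeom.sf(study_hits[t] - 1, m, universe_hits[t], n) for t in terms]
    reject, padj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return {t: p for t, p, r in zip(terms, padj, reject) if r}
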