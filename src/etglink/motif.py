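"""Motif scanning, motif-module discovery and enhancer GO-term assignment.

A motif module is a set of >= 2 motifs that co-occur in significantly many
enhancers.  Discovery here is a level-wise (Apriori) enumeration with an
exact one-sided binomial test against the independence null and Bonferroni
correction; it is deliberately simple, and externally discovered modules can
be supplied through :func:`read_modules` / :func:`read_module_instances`
instead.

An enhancer inherits GO terms from the modules it carries: all enhancers
containing a module are pooled, every gene within the candidate window of
any of them is collected, and terms over-represented in that gene list
against the full gene universe (hypergeometric, Benjamini-Hochberg) become
the enhancer's terms — the union over its modules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .genomic import Enhancer, Gene, GeneIndex, ParameterSet, ParseError, candidate_genes
from .ontology import GOAnnotationTable, GODag, hypergeom_enrichment

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of per-position base probabilities."""

    motif_id: str
    matrix: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.matrix) < 4:
            raise ValueError("motif length must be >= 4")
        for i, col in enumerate(self.matrix):
            if abs(sum(col) - 1.0) > 1e-6:
                raise ValueError(f"{self.motif_id}: position {i} does not sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[int(np.argmax(col))] for col in self.matrix)

    def log_odds(self, pseudocount: float = 1e-3, background: float = 0.25) -> np.ndarray:
        """(L, 5) log-odds; row 4 is the zero-scoring non-ACGT channel."""
        probs = np.asarray(self.matrix, dtype=float) + pseudocount
        lo = np.log(probs / background)
        return np.hstack([lo, np.zeros((len(self.matrix), 1))])


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse a minimal MEME-style motif text file.

    Recognises ``MOTIF <id>`` headers followed by a ``letter-probability
    matrix:`` line and one whitespace-separated A C G T probability row per
    position.  Header metadata (alphabet, background, strands) is ignored.
    """
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[tuple[float, float, float, float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal motif_id, rows, in_matrix
        if motif_id is not None:
            if not rows:
                raise ParseError(f"{path}: motif {motif_id} has no matrix")
            pwms.append(PWM(motif_id, tuple(rows)))
        motif_id, rows, in_matrix = None, [], False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: MOTIF line without an id")
                motif_id = parts[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 probabilities")
                rows.append((vals[0], vals[1], vals[2], vals[3]))
            elif in_matrix and not line:
                in_matrix = False
    flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0\n")
            for col in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


@dataclass
class OccurrenceMatrix:
    """Binary enhancer x motif occurrence table."""

    enhancer_ids: list[str]
    motif_ids: list[str]
    data: np.ndarray  # bool, shape (n_enhancers, n_motifs)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != (len(self.enhancer_ids), len(self.motif_ids)):
            raise ValueError("occurrence matrix shape mismatch")
        self._erow = {e: i for i, e in enumerate(self.enhancer_ids)}
        self._mcol = {m: j for j, m in enumerate(self.motif_ids)}

    def has(self, enhancer_id: str, motif_id: str) -> bool:
        return bool(self.data[self._erow[enhancer_id], self._mcol[motif_id]])

    def enhancers_with_all(self, motif_ids: Sequence[str]) -> list[str]:
        cols = [self._mcol[m] for m in motif_ids]
        mask = self.data[:, cols].all(axis=1)
        return [e for e, keep in zip(self.enhancer_ids, mask) if keep]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.intp)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def best_score(seq: str, pwm: PWM, pseudocount: float = 1e-3) -> float:
    """Best log-odds over all windows of both strands; -inf if too short.

    Non-ACGT characters contribute zero log-odds (background behaviour).
    """
    L = len(pwm)
    lo = pwm.log_odds(pseudocount)
    best = -math.inf
    for s in (seq, reverse_complement(seq)):
        if len(s) < L:
            continue
        idx = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = lo[np.arange(L), windows].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def scan_motifs(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold_frac: float = 0.8,
    pseudocount: float = 1e-3,
) -> OccurrenceMatrix:
    """Binary occurrence: 1 iff the best hit reaches ``threshold_frac`` of
    the motif's maximal achievable log-odds."""
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must be in (0, 1]")
    enhancer_ids = list(sequences)
    motif_ids = [p.motif_id for p in pwms]
    data = np.zeros((len(enhancer_ids), len(pwms)), dtype=bool)
    for j, pwm in enumerate(pwms):
        lo = pwm.log_odds(pseudocount)
        max_score = float(lo[:, :4].max(axis=1).sum())
        cutoff = threshold_frac * max_score
        for i, eid in enumerate(enhancer_ids):
            data[i, j] = best_score(sequences[eid], pwm, pseudocount) >= cutoff
    return OccurrenceMatrix(enhancer_ids, motif_ids, data)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class MotifModule:
    motif_ids: frozenset[str]
    support: int
    p_value: float  # Bonferroni-corrected

    def __post_init__(self) -> None:
        if len(self.motif_ids) < 2:
            raise ValueError("a motif module needs >= 2 motifs")


def discover_modules(
    occ: OccurrenceMatrix,
    min_size: int = 2,
    max_size: int = 5,
    min_support: int = 3,
    alpha: float = 0.01,
) -> list[MotifModule]:
    """Apriori enumeration of co-occurring motif sets.

    A set of k motifs present together in ``support`` of n enhancers is
    tested against the independence null p0 = product of the members' marginal
    frequencies with an exact one-sided binomial upper tail; p-values are
    Bonferroni-corrected over every set that reached ``min_support``.  Only
    maximal significant sets are returned (no reported set is a subset of
    another), ordered by corrected p then lexicographically.
    """
    n, n_motifs = occ.data.shape
    if n == 0 or n_motifs < 2:
        raise ValueError("need >= 1 enhancer and >= 2 motifs")
    freq = occ.data.mean(axis=0)
    cols = {j: occ.data[:, j] for j in range(n_motifs)}

    # level-wise growth of frequent itemsets (by column index)
    frequent: dict[int, dict[tuple[int, ...], np.ndarray]] = {}
    level1 = {
        (j,): cols[j] for j in range(n_motifs) if int(cols[j].sum()) >= min_support
    }
    frequent[1] = level1
    for size in range(2, max_size + 1):
        prev = frequent.get(size - 1, {})
        cand: dict[tuple[int, ...], np.ndarray] = {}
        items = sorted({j for key in prev for j in key})
        for key, mask in prev.items():
            for j in items:
                if j <= key[-1]:
                    continue
                new_mask = mask & cols[j]
                if int(new_mask.sum()) >= min_support:
                    cand[key + (j,)] = new_mask
        if not cand:
            break
        frequent[size] = cand

    tested: list[tuple[tuple[int, ...], int, float]] = []
    for size in range(max(2, min_size), max_size + 1):
        for key, mask in frequent.get(size, {}).items():
            support = int(mask.sum())
            p0 = float(np.prod([freq[j] for j in key]))
            if p0 >= 1.0:
                pval = 1.0
            else:
                pval = float(binom.sf(support - 1, n, p0))
            tested.append((key, support, pval))
    if not tested:
        return []
    n_tests = len(tested)
    significant = [
        (key, support, min(1.0, p * n_tests))
        for key, support, p in tested
        if min(1.0, p * n_tests) <= alpha
    ]
    # maximality filter
    keys = [set(k) for k, _, _ in significant]
    maximal = []
    for i, (key, support, p) in enumerate(significant):
        if any(i != j and keys[i] < keys[j] for j in range(len(keys))):
            continue
        maximal.append(
            MotifModule(
                frozenset(occ.motif_ids[j] for j in key), support, p
            )
        )
    maximal.sort(key=lambda m: (m.p_value, sorted(m.motif_ids)))
    return maximal


def read_modules(path: str | Path) -> list[frozenset[str]]:
    """Module list TSV: module_id <tab> comma-separated motif ids."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            _, _, motifs = line.partition("\t")
            out.append(frozenset(m for m in motifs.split(",") if m))
    return out


def read_module_instances(path: str | Path) -> dict[str, set[str]]:
    """Instance TSV: enhancer_id <tab> module_id -> {enhancer: module ids}."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            eid, _, mid = line.partition("\t")
            out.setdefault(eid, set()).add(mid)
    return out


def assign_enhancer_go(
    enhancers: Sequence[Enhancer],
    modules: Sequence[MotifModule],
    occ: OccurrenceMatrix,
    genes: Sequence[Gene] | GeneIndex,
    annotations: GOAnnotationTable,
    dag: GODag,
    params: ParameterSet = ParameterSet(),
    fdr: float = 0.05,
) -> dict[str, frozenset[str]]:
    """GO terms of every enhancer, inferred through its motif modules.

    For each module: pool the enhancers carrying it, collect the de-duplicated
    genes within the candidate window of any of them, and test each
    propagated GO term for over-representation against the annotated gene
    universe.  An enhancer's terms are the union over its modules; enhancers
    with no module instance get an empty set.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    by_id = {e.enhancer_id: e for e in enhancers}
    universe = {g.gene_id for g in index.genes} & annotations.genes()

    module_terms: list[frozenset[str]] = []
    module_carriers: list[set[str]] = []
    for module in modules:
        carriers = set(occ.enhancers_with_all(sorted(module.motif_ids)))
        carriers &= set(by_id)
        pooled: set[str] = set()
        for eid in carriers:
            pooled.update(
                g.gene_id for g in candidate_genes(by_id[eid], index, params)
            )
        enriched = hypergeom_enrichment(pooled, universe, annotations, dag, fdr)
        module_terms.append(frozenset(enriched))
        module_carriers.append(carriers)

    out: dict[str, frozenset[str]] = {e.enhancer_id: frozenset() for e in enhancers}
    for terms, carriers in zip(module_terms, module_carriers):
        for eid in carriers:
            out[eid] = out[eid] | terms
    return out
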