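"""Seeded synthetic-fixture generator.

Emits a complete, internally consistent toy dataset — enhancers, gene
annotation, enhancer sequences with planted motif-module instances, a GO
DAG with gene annotations, per-species alignment blocks, per-cell-type DHS
coverage tracks, a sparse 5-kb contact matrix and a truth table — in the
exact file dialects the package's readers consume.

The genome is laid out as isolated neighbourhoods: one enhancer every 5 Mb
with its candidate genes placed around it, so each gene is a candidate of
exactly one enhancer and the planted labels are unambiguous.  True pairs
are drawn nearer (exponential distance decay), retained in more species,
share GO terms through the enhancer's motif module, co-vary in DHS signal
across cell types, and carry more Hi-C reads; each effect's strength is a
config field and can be zeroed independently.  Regeneration under the same
seed is byte-identical: every output artifact draws from its own child
stream of the master seed, so e.g. adding a cell type cannot perturb the
gene layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import Enhancer, Gene, GenomicInterval, ParameterSet, promoter_of
from .motif import PWM, write_pwms

_SPECIES_PHYLO = {
    "chimpanzee": 0.03,
    "mouse": 0.45,
    "chicken": 0.95,
    "frog": 1.60,
    "zebrafish": 2.10,
}

_NEIGHBOURHOOD_SPACING = 5_000_000
_ENHANCER_WIDTH = 500
_MIN_TSS_OFFSET = 6_000  # keeps every pair past the 5-kb Hi-C separation rule
_MIN_TSS_GAP = 3_200  # promoters (1.1 kb) never overlap each other
_MAX_TSS_OFFSET = 1_950_000

_MODULE_MOTIFS = {"MOD1": ("M1", "M2"), "MOD2": ("M3", "M4")}
_BACKGROUND_MOTIFS = ("M5", "M6")
_BACKGROUND_PLANT_PROB = 0.05
_ENHANCER_ALIGN_PROB = 0.95
_DECOY_TERM_PROB = 0.6

GO_ROOT = "GO:0000001"
GO_BRANCHES = {"MOD1": "GO:0000010", "MOD2": "GO:0000020"}
GO_DECOY_BRANCH = "GO:0000030"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give ~1900 candidate pairs with all four feature signals
    planted at strengths that decrease from distance to correlation.
    """

    n_chromosomes: int = 2
    n_enhancers: int = 120
    genes_per_window: int = 16
    true_pairs_per_enhancer: int = 2
    distance_decay_scale: float = 80_000.0  # bp; 0 disables the distance effect
    synteny_true_prob: float = 0.50
    synteny_false_prob: float = 0.12
    go_share_prob_true: float = 0.65
    go_share_prob_false: float = 0.10
    signal_correlation_true: float = 0.20
    signal_correlation_false: float = 0.0
    n_cell_types: int = 13
    hic_reads_true: float = 30.0
    hic_reads_false: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.synteny_true_prob,
            self.synteny_false_prob,
            self.go_share_prob_true,
            self.go_share_prob_false,
            self.signal_correlation_true,
            self.signal_correlation_false,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        pairs = (
            (self.synteny_true_prob, self.synteny_false_prob),
            (self.go_share_prob_true, self.go_share_prob_false),
            (self.signal_correlation_true, self.signal_correlation_false),
            (self.hic_reads_true, self.hic_reads_false),
        )
        if any(t < f for t, f in pairs):
            raise ValueError("every planted true signal must be >= its false signal")
        if self.distance_decay_scale < 0:
            raise ValueError("distance_decay_scale must be >= 0")
        if min(self.n_chromosomes, self.n_enhancers, self.n_cell_types) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.true_pairs_per_enhancer < self.genes_per_window:
            raise ValueError("need 0 < true_pairs_per_enhancer < genes_per_window")

    def zero_effects(self) -> "FixtureConfig":
        """All planted effects removed: labels become exchangeable."""
        return replace(
            self,
            distance_decay_scale=0.0,
            synteny_true_prob=0.2,
            synteny_false_prob=0.2,
            go_share_prob_true=0.2,
            go_share_prob_false=0.2,
            signal_correlation_true=0.0,
            signal_correlation_false=0.0,
            hic_reads_true=2.0,
            hic_reads_false=2.0,
        )


@dataclass
class FixtureBundle:
    """Paths of the emitted files plus the in-memory truth table."""

    outdir: Path
    config: FixtureConfig
    truth: pd.DataFrame  # enhancer_id, gene_id, label
    paths: dict[str, Path] = field(default_factory=dict)


def _default_pwms(rng: np.random.Generator) -> list[PWM]:
    pwms = []
    for mid in ("M1", "M2", "M3", "M4", "M5", "M6"):
        length = 8
        consensus = rng.integers(0, 4, size=length)
        matrix = []
        for b in consensus:
            col = [0.01, 0.01, 0.01, 0.01]
            col[int(b)] = 0.97
            matrix.append(tuple(col))
        pwms.append(PWM(mid, tuple(matrix)))
    return pwms


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("layout", "motif", "sequence", "synteny", "go", "signal", "hic")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _place_genes(
    cfg: FixtureConfig, rng: np.random.Generator, center: int
) -> list[tuple[int, bool]]:
    """(tss, is_true) placements around one enhancer center."""
    placed: list[tuple[int, bool]] = []

    def free(tss: int) -> bool:
        return all(abs(tss - t) >= _MIN_TSS_GAP for t, _ in placed)

    def draw(is_true: bool) -> None:
        for _ in range(500):
            if is_true and cfg.distance_decay_scale > 0:
                d = _MIN_TSS_OFFSET + rng.exponential(cfg.distance_decay_scale)
                if d > _MAX_TSS_OFFSET:
                    continue
            else:
                d = rng.uniform(_MIN_TSS_OFFSET, _MAX_TSS_OFFSET)
            sign = 1 if rng.random() < 0.5 else -1
            tss = center + sign * int(d + _ENHANCER_WIDTH // 2)
            if tss > _MIN_TSS_OFFSET and free(tss):
                placed.append((tss, is_true))
                return
        raise RuntimeError("could not place gene without promoter collision")

    for _ in range(cfg.true_pairs_per_enhancer):
        draw(True)
    for _ in range(cfg.genes_per_window - cfg.true_pairs_per_enhancer):
        draw(False)
    return placed


def generate(cfg: FixtureConfig, outdir: str | Path) -> FixtureBundle:
    """Write the full fixture bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    rngs = _streams(cfg.seed)
    params = ParameterSet()

    # ---- layout: enhancers, genes, labels, modules -----------------------
    rng = rngs["layout"]
    per_chrom = math.ceil(cfg.n_enhancers / cfg.n_chromosomes)
    enhancers: list[Enhancer] = []
    genes: list[Gene] = []
    rows = []
    module_of: dict[str, str] = {}
    gene_counter = 0
    for i in range(cfg.n_enhancers):
        chrom = f"chr{i // per_chrom + 1}"
        center = 2_500_000 + (i % per_chrom) * _NEIGHBOURHOOD_SPACING
        eid = f"E{i + 1:04d}"
        e = Enhancer(
            eid,
            GenomicInterval(
                chrom, center - _ENHANCER_WIDTH // 2, center + _ENHANCER_WIDTH // 2
            ),
        )
        enhancers.append(e)
        module_of[eid] = "MOD1" if i % 2 == 0 else "MOD2"
        for tss, is_true in _place_genes(cfg, rng, center):
            gene_counter += 1
            gid = f"G{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, chrom, tss, strand))
            rows.append({"enhancer_id": eid, "gene_id": gid, "label": int(is_true)})
    truth = pd.DataFrame(rows)
    gene_by_id = {g.gene_id: g for g in genes}

    paths: dict[str, Path] = {}

    paths["enhancers"] = outdir / "enhancers.bed"
    with open(paths["enhancers"], "w") as fh:
        for e in enhancers:
            r = e.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{e.enhancer_id}\n")

    paths["genes"] = outdir / "genes.gtf"
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 2\n")
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss + 1, g.tss + 1500
            else:
                start1, end1 = max(1, g.tss + 1 - 1499), g.tss + 1
            fh.write(
                f"{g.chrom}\tsim\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";\n'
            )

    paths["truth"] = outdir / "truth_pairs.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("#enhancer_id\tgene_id\tlabel\n")
        for row in rows:
            fh.write(f"{row['enhancer_id']}\t{row['gene_id']}\t{row['label']}\n")

    # ---- motifs and enhancer sequences -----------------------------------
    pwms = _default_pwms(rngs["motif"])
    pwm_by_id = {p.motif_id: p for p in pwms}
    paths["pwms"] = outdir / "pwms.txt"
    write_pwms(pwms, paths["pwms"])

    rng = rngs["sequence"]
    bases = np.array(list("ACGT"))
    paths["sequences"] = outdir / "enhancer_seqs.fa"
    with open(paths["sequences"], "w") as fh:
        for e in enhancers:
            seq = rng.choice(bases, size=_ENHANCER_WIDTH)
            plant = list(_MODULE_MOTIFS[module_of[e.enhancer_id]])
            for m in _BACKGROUND_MOTIFS:
                if rng.random() < _BACKGROUND_PLANT_PROB:
                    plant.append(m)
            slot = 10
            for mid in plant:
                cons = pwm_by_id[mid].consensus
                if rng.random() < 0.5:
                    from .motif import reverse_complement

                    cons = reverse_complement(cons)
                seq[slot : slot + len(cons)] = list(cons)
                slot += len(cons) + 12
            fh.write(f">{e.enhancer_id}\n{''.join(seq)}\n")

    paths["modules"] = outdir / "modules.tsv"
    with open(paths["modules"], "w") as fh:
        fh.write("#module_id\tmotif_ids\n")
        for mid, motifs_ in _MODULE_MOTIFS.items():
            fh.write(f"{mid}\t{','.join(motifs_)}\n")
    paths["instances"] = outdir / "instances.tsv"
    with open(paths["instances"], "w") as fh:
        fh.write("#enhancer_id\tmodule_id\n")
        for e in enhancers:
            fh.write(f"{e.enhancer_id}\t{module_of[e.enhancer_id]}\n")

    # ---- synteny: per-species alignment blocks + phylogeny ---------------
    rng = rngs["synteny"]
    paths["phylo"] = outdir / "phylo.tsv"
    with open(paths["phylo"], "w") as fh:
        fh.write("#species\tphi\n")
        for sp, phi in _SPECIES_PHYLO.items():
            fh.write(f"{sp}\t{phi}\n")

    truth_of = {(r["enhancer_id"], r["gene_id"]): r["label"] for r in rows}
    enhancer_of_gene = {r["gene_id"]: r["enhancer_id"] for r in rows}
    paths["blocks"] = outdir / "blocks.tsv"
    with open(paths["blocks"], "w") as fh:
        fh.write(
            "#species\tref_chrom\tref_start\tref_end\ttgt_chrom\ttgt_start\ttgt_end\torientation\n"
        )
        for sp in _SPECIES_PHYLO:
            for e in enhancers:
                if rng.random() < _ENHANCER_ALIGN_PROB:
                    r = e.region
                    fh.write(
                        f"{sp}\t{r.chrom}\t{r.start}\t{r.end}\t"
                        f"{sp}_{r.chrom}\t{r.start}\t{r.end}\t+\n"
                    )
            for g in genes:
                eid = enhancer_of_gene[g.gene_id]
                p_keep = (
                    cfg.synteny_true_prob
                    if truth_of[(eid, g.gene_id)]
                    else cfg.synteny_false_prob
                )
                prom = promoter_of(g, params)
                u = rng.random()
                lost = rng.random() < 0.5  # unmapped vs mapped-elsewhere
                if u < p_keep:
                    fh.write(
                        f"{sp}\t{prom.chrom}\t{prom.start}\t{prom.end}\t"
                        f"{sp}_{prom.chrom}\t{prom.start}\t{prom.end}\t+\n"
                    )
                elif not lost:
                    fh.write(
                        f"{sp}\t{prom.chrom}\t{prom.start}\t{prom.end}\t"
                        f"{sp}_chrU\t{prom.start}\t{prom.end}\t+\n"
                    )

    # ---- gene ontology ----------------------------------------------------
    rng = rngs["go"]
    paths["obo"] = outdir / "go.obo"
    leaves: dict[str, list[str]] = {}
    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: sim\n\n")

        def term(tid: str, name: str, parent: str | None) -> None:
            fh.write(f"[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
            if parent:
                fh.write(f"is_a: {parent} ! parent\n")
            fh.write("\n")

        term(GO_ROOT, "simulated biological process root", None)
        for branch_key, tid in {**GO_BRANCHES, "decoy": GO_DECOY_BRANCH}.items():
            term(tid, f"{branch_key} process", GO_ROOT)
            leaves[tid] = []
            for k in range(1, 4):
                leaf = f"{tid[:-1]}{k}"
                leaves[tid].append(leaf)
                term(leaf, f"{branch_key} subprocess {k}", tid)

    paths["gaf"] = outdir / "annotations.gaf"
    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.1\n")

        def annotate(gene_id: str, term_id: str) -> None:
            fh.write(
                f"SIM\t{gene_id}\t{gene_id}\t\t{term_id}\tSIM:0001\tIEA\t\tP\t"
                f"{gene_id}\t\tgene\ttaxon:9606\t20160101\tSIM\t\t\n"
            )

        for g in genes:
            eid = enhancer_of_gene[g.gene_id]
            branch = GO_BRANCHES[module_of[eid]]
            p_share = (
                cfg.go_share_prob_true
                if truth_of[(eid, g.gene_id)]
                else cfg.go_share_prob_false
            )
            if rng.random() < p_share:
                annotate(g.gene_id, leaves[branch][rng.integers(3)])
            if rng.random() < _DECOY_TERM_PROB:
                annotate(g.gene_id, leaves[GO_DECOY_BRANCH][rng.integers(3)])

    # ---- DHS activity tracks ----------------------------------------------
    rng = rngs["signal"]
    cells = [f"cell{c + 1:02d}" for c in range(cfg.n_cell_types)]
    z_enh = {e.enhancer_id: rng.standard_normal(cfg.n_cell_types) for e in enhancers}
    z_gene = {}
    for g in genes:
        eid = enhancer_of_gene[g.gene_id]
        rho = (
            cfg.signal_correlation_true
            if truth_of[(eid, g.gene_id)]
            else cfg.signal_correlation_false
        )
        eps = rng.standard_normal(cfg.n_cell_types)
        z_gene[g.gene_id] = rho * z_enh[eid] + math.sqrt(1.0 - rho * rho) * eps
    manifest_rows = []
    for c, cell in enumerate(cells):
        track_path = outdir / "tracks" / f"{cell}.bedgraph"
        manifest_rows.append((cell, f"tracks/{cell}.bedgraph"))
        segments = []
        for e in enhancers:
            r = e.region
            segments.append((r.chrom, r.start, r.end, math.exp(z_enh[e.enhancer_id][c])))
        for g in genes:
            prom = promoter_of(g, params)
            segments.append(
                (prom.chrom, prom.start, prom.end, math.exp(z_gene[g.gene_id][c]))
            )
        segments.sort(key=lambda s: (s[0], s[1]))
        with open(track_path, "w") as fh:
            for chrom, start, end, value in segments:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")
    paths["panel"] = outdir / "panel.tsv"
    with open(paths["panel"], "w") as fh:
        fh.write("#cell_type\tpath\n")
        for cell, rel in manifest_rows:
            fh.write(f"{cell}\t{rel}\n")

    # ---- Hi-C contact triplets --------------------------------------------
    rng = rngs["hic"]
    res = params.hic_resolution
    enh_by_id = {e.enhancer_id: e for e in enhancers}
    triplets: dict[tuple[str, int, int], int] = {}
    for r in rows:
        e = enh_by_id[r["enhancer_id"]]
        g = gene_by_id[r["gene_id"]]
        mean = cfg.hic_reads_true if r["label"] else cfg.hic_reads_false
        count = int(rng.poisson(mean))
        if count > 0:
            bi = (e.region.start + _ENHANCER_WIDTH // 2) // res
            bj = g.tss // res
            key = (e.region.chrom, min(bi, bj) * res, max(bi, bj) * res)
            triplets[key] = triplets.get(key, 0) + count
    for e in enhancers:  # sparse background contacts
        bi = (e.region.start + _ENHANCER_WIDTH // 2) // res
        for _ in range(3):
            bj = bi + int(rng.integers(-400, 401))
            count = int(rng.poisson(1.0))
            if count > 0 and bj > 0:
                key = (e.region.chrom, min(bi, bj) * res, max(bi, bj) * res)
                triplets[key] = triplets.get(key, 0) + count
    paths["contacts"] = outdir / "contacts.tsv"
    with open(paths["contacts"], "w") as fh:
        fh.write("#chrom\tbin_i_start\tbin_j_start\tcount\n")
        for (chrom, i, j), count in sorted(triplets.items()):
            fh.write(f"{chrom}\t{i}\t{j}\t{count}\n")

    return FixtureBundle(outdir, cfg, truth, paths)


def truth_metrics(bundle: FixtureBundle) -> pd.DataFrame:
    """Planted-signal self-test: per-feature separation of true vs false.

    Runs the real feature pipeline on the bundle and reports, per feature,
    the true-pair mean, false-pair mean and their gap (true - false, with
    distance negated so a positive gap always means 'signal in the planted
    direction').
    """
    from .pipeline import bundle_feature_table, load_bundle

    loaded = load_bundle(bundle.outdir)
    table = bundle_feature_table(loaded)
    out = []
    for feat in ("distance", "css", "fss", "correlation"):
        t = table.loc[table["label"] == 1, feat].mean()
        f = table.loc[table["label"] == 0, feat].mean()
        gap = (f - t) if feat == "distance" else (t - f)
        out.append({"feature": feat, "mean_true": t, "mean_false": f, "gap": gap})
    return pd.DataFrame(out)
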