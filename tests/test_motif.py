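import itertools
import math

import numpy as np
import pytest

from etglink.genomic import Enhancer, GenomicInterval
from etglink.motif import (
    PWM,
    OccurrenceMatrix,
    assign_enhancer_go,
    best_score,
    discover_modules,
    read_module_instances,
    read_modules,
    read_pwms,
    reverse_complement,
    scan_motifs,
    write_pwms,
)
from etglink.ontology import GOAnnotationTable, GODag, compute_ic


def strong_pwm(motif_id, consensus):
    cols = []
    for b in consensus:
        col = [0.01, 0.01, 0.01, 0.01]
        col["ACGT".index(b)] = 0.97
        cols.append(tuple(col))
    return PWM(motif_id, tuple(cols))


class TestPwm:
    def test_column_sum_validation(self):
        with pytest.raises(ValueError, match="sum"):
            PWM("bad", tuple([(0.5, 0.5, 0.5, 0.5)] * 4))

    def test_min_length(self):
        with pytest.raises(ValueError, match="length"):
            PWM("short", tuple([(0.25, 0.25, 0.25, 0.25)] * 3))

    def test_round_trip(self, tmp_path):
        pwms = [strong_pwm("M1", "ACGTAC"), strong_pwm("M2", "GGGTTT")]
        p = tmp_path / "pwms.txt"
        write_pwms(pwms, p)
        back = read_pwms(p)
        assert [b.motif_id for b in back] == ["M1", "M2"]
        assert back[0].consensus == "ACGTAC"
        np.testing.assert_allclose(back[0].matrix, pwms[0].matrix, atol=1e-6)


class TestScan:
    pwm = strong_pwm("M1", "ACGTACGT")

    def test_consensus_hits(self):
        occ = scan_motifs({"e1": "TT" + self.pwm.consensus + "GG"}, [self.pwm], 0.8)
        assert occ.has("e1", "M1")

    def test_all_n_sequence_misses(self):
        occ = scan_motifs({"e1": "N" * 50}, [self.pwm], 0.8)
        assert not occ.has("e1", "M1")

    def test_too_short_sequence_misses(self):
        occ = scan_motifs({"e1": "ACG"}, [self.pwm], 0.8)
        assert not occ.has("e1", "M1")

    def test_reverse_strand_found(self):
        """Oracle: scanning the explicit reverse complement forward-only."""
        planted = reverse_complement(self.pwm.consensus)
        seq = "TTTT" + planted + "CCCC"
        occ = scan_motifs({"e1": seq}, [self.pwm], 0.8)
        assert occ.has("e1", "M1")
        # forward-only score of the revcomp sequence reaches the maximum
        lo = self.pwm.log_odds()
        fwd = sum(
            lo[i, "ACGT".index(b)] for i, b in enumerate(self.pwm.consensus)
        )
        assert best_score(seq, self.pwm) == pytest.approx(fwd)


def exhaustive_modules(data, min_size, max_size, min_support, alpha):
    """Independent itemset oracle: full subset enumeration + exact binomial
    tail computed from math.comb, Bonferroni over tested sets, maximality."""
    n, m = data.shape
    freq = data.mean(axis=0)
    tested = []
    for size in range(max(2, min_size), max_size + 1):
        for combo in itertools.combinations(range(m), size):
            support = int(data[:, combo].all(axis=1).sum())
            if support < min_support:
                continue
            p0 = float(np.prod(freq[list(combo)]))
            pval = sum(
                math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
                for k in range(support, n + 1)
            )
            tested.append((frozenset(combo), support, pval))
    n_tests = len(tested)
    sig = [
        (s, sup, min(1.0, p * n_tests))
        for s, sup, p in tested
        if min(1.0, p * n_tests) <= alpha
    ]
    keep = [
        (s, sup, p)
        for s, sup, p in sig
        if not any(s < s2 for s2, _, _ in sig)
    ]
    return {s: (sup, p) for s, sup, p in keep}


class TestDiscoverModules:
    def make_occ(self, data, motif_ids=None):
        n, m = data.shape
        return OccurrenceMatrix(
            [f"e{i}" for i in range(n)],
            motif_ids or [f"M{j}" for j in range(m)],
            data,
        )

    def test_planted_pair_found_noise_motif_excluded(self):
        # A and B co-occur in 15/60 enhancers while each occurs alone in 3
        # more, so their joint frequency far exceeds the product of the
        # marginals; C is independent noise.
        rng = np.random.default_rng(0)
        n = 60
        data = np.zeros((n, 3), dtype=bool)
        data[:15, 0] = data[:15, 1] = True
        data[15:18, 0] = True
        data[18:21, 1] = True
        data[:, 2] = rng.random(n) < 0.3
        mods = discover_modules(self.make_occ(data), min_support=3, alpha=0.01)
        assert any(m.motif_ids == frozenset({"M0", "M1"}) for m in mods)
        assert all("M2" not in m.motif_ids for m in mods)

    def test_all_zero_matrix_empty(self):
        data = np.zeros((5, 3), dtype=bool)
        assert discover_modules(self.make_occ(data), min_support=2) == []

    def test_support_gate(self):
        data = np.zeros((50, 2), dtype=bool)
        data[:2, :] = True  # perfectly co-occurring but support 2 < 3
        assert discover_modules(self.make_occ(data), min_support=3) == []

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            discover_modules(self.make_occ(np.zeros((0, 3), dtype=bool)))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 40, 8
        data = rng.random((n, m)) < 0.35
        data[: n // 2, 0] = data[: n // 2, 1] = True
        data[: n // 3, 4] = data[: n // 3, 5] = data[: n // 3, 6] = True
        got = discover_modules(self.make_occ(data), 2, 5, 4, 0.01)
        expected = exhaustive_modules(data, 2, 5, 4, 0.01)
        got_sets = {
            frozenset(int(mid[1:]) for mid in mod.motif_ids): (mod.support, mod.p_value)
            for mod in got
        }
        assert set(got_sets) == set(expected)
        for s, (sup, p) in expected.items():
            assert got_sets[s][0] == sup
            assert got_sets[s][1] == pytest.approx(p, rel=1e-9)


class TestAssignEnhancerGo:
    def build(self):
        """Two enhancers share a module; their window genes share leaf1."""
        from etglink.genomic import Gene, ParameterSet

        params = ParameterSet(candidate_window=100_000)
        enhancers = [
            Enhancer("e1", GenomicInterval("chr1", 1_000_000, 1_000_500)),
            Enhancer("e2", GenomicInterval("chr1", 9_000_000, 9_000_500)),
            Enhancer("e3", GenomicInterval("chr1", 20_000_000, 20_000_500)),
        ]
        # genes near e1/e2 carry leaf1; a distant background population doesn't
        genes, direct = [], {}
        for i, center in enumerate([1_000_000, 1_020_000, 9_020_000, 9_040_000]):
            g = f"near{i}"
            genes.append(Gene(g, "chr1", center + 5_000, "+"))
            direct[g] = frozenset({"leaf1"})
        for i in range(12):
            g = f"far{i}"
            genes.append(Gene(g, "chr1", 30_000_000 + i * 10_000, "+"))
            direct[g] = frozenset({"mid"})  # uniform background term
        parents = {
            "root": frozenset(),
            "mid": frozenset({"root"}),
            "leaf1": frozenset({"mid"}),
            "leaf2": frozenset({"mid"}),
        }
        dag = GODag(parents, {t: "bp" for t in parents})
        # annotate background so 'mid' is carried by everything
        direct = {g: ts | {"mid"} for g, ts in direct.items()}
        ann = GOAnnotationTable(direct)
        compute_ic(dag, ann)
        occ = OccurrenceMatrix(
            ["e1", "e2", "e3"],
            ["A", "B"],
            np.array([[1, 1], [1, 1], [0, 0]], dtype=bool),
        )
        from etglink.motif import MotifModule

        modules = [MotifModule(frozenset({"A", "B"}), 2, 1e-4)]
        return enhancers, modules, occ, genes, ann, dag, params

    def test_shared_term_significant(self):
        enhancers, modules, occ, genes, ann, dag, params = self.build()
        assigned = assign_enhancer_go(enhancers, modules, occ, genes, ann, dag, params)
        assert "leaf1" in assigned["e1"]
        assert assigned["e1"] == assigned["e2"]

    def test_uniform_term_not_significant(self):
        enhancers, modules, occ, genes, ann, dag, params = self.build()
        assigned = assign_enhancer_go(enhancers, modules, occ, genes, ann, dag, params)
        assert "mid" not in assigned["e1"]

    def test_enhancer_without_module_empty(self):
        enhancers, modules, occ, genes, ann, dag, params = self.build()
        assigned = assign_enhancer_go(enhancers, modules, occ, genes, ann, dag, params)
        assert assigned["e3"] == frozenset()


def test_module_tsv_readers(tmp_path):
    m = tmp_path / "modules.tsv"
    m.write_text("#module_id\tmotif_ids\nMOD1\tM1,M2\nMOD2\tM3,M4,M5\n")
    assert read_modules(m) == [frozenset({"M1", "M2"}), frozenset({"M3", "M4", "M5"})]
    i = tmp_path / "instances.tsv"
    i.write_text("e1\tMOD1\ne1\tMOD2\ne2\tMOD1\n")
    assert read_module_instances(i) == {"e1": {"MOD1", "MOD2"}, "e2": {"MOD1"}}
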