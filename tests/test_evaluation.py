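import math
from fractions import Fraction

import numpy as np
import pytest

from etglink.evaluation import (
    ConfusionCounts,
    ContactMatrix,
    RegionPair,
    binomial_enrichment,
    confusion,
    hic_support,
    inconsecutiveness,
    metrics,
    metrics_from_counts,
    random_pairs,
    roc_auc,
)
from etglink.genomic import Enhancer, Gene, GenomicInterval, ParameterSet


def rp(e_start, e_end, p_start, p_end, chrom="chr1"):
    return RegionPair(
        GenomicInterval(chrom, e_start, e_end), GenomicInterval(chrom, p_start, p_end)
    )


class TestConfusion:
    def test_exact_match(self):
        known = [rp(100, 200, 5000, 6000), rp(9000, 9500, 20000, 21000)]
        c = confusion(known, known, known_negative=[rp(50000, 50100, 70000, 70500)])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 1)

    def test_empty_predictions(self):
        known = [rp(100, 200, 5000, 6000)]
        c = confusion([], known)
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_partial_overlap_counts(self):
        pred = rp(150, 250, 5500, 6500)  # shifted but still overlapping
        c = confusion([pred], [rp(100, 200, 5000, 6000)])
        assert (c.tp, c.fn) == (1, 0)

    def test_swapped_orientation_matches(self):
        pred = rp(100, 200, 5000, 6000)
        known = rp(5000, 6000, 100, 200)  # regions listed the other way round
        assert confusion([pred], [known]).tp == 1

    def test_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(8)

        def rand_pairs(k):
            out = []
            for _ in range(k):
                a = int(rng.integers(0, 5000))
                b = int(rng.integers(6000, 11000))
                out.append(rp(a, a + 300, b, b + 300))
            return out

        pred, known = rand_pairs(20), rand_pairs(15)
        c = confusion(pred, known)

        def overlap(x, y):
            return x.start < y.end and y.start < x.end

        def match(p, k):
            return (overlap(p.enhancer, k.enhancer) and overlap(p.promoter, k.promoter)) or (
                overlap(p.enhancer, k.promoter) and overlap(p.promoter, k.enhancer)
            )

        tp = sum(any(match(p, k) for k in known) for p in pred)
        fn = sum(not any(match(p, k) for p in pred) for k in known)
        assert (c.tp, c.fp, c.fn) == (tp, len(pred) - tp, fn)

    def test_one_prediction_matching_two_known_counts_once(self):
        pred = rp(0, 10_000, 20_000, 30_000)  # broad, hits both known pairs
        known = [rp(100, 200, 21_000, 21_500), rp(5_000, 5_200, 25_000, 25_500)]
        c = confusion([pred], known)
        assert c.tp == 1
        assert c.fn == 0


class TestMetrics:
    @pytest.mark.parametrize(
        "known,predicted,recovered,recall,precision,f1",
        [
            (4110, 9244, 1917, 0.466, 0.207, 0.287),
            (370, 560, 187, 0.505, 0.334, 0.402),
            (24146, 36271, 9915, 0.411, 0.273, 0.328),
            (64075, 23454, 17354, 0.271, 0.740, 0.397),
        ],
    )
    def test_benchmark_row_arithmetic(self, known, predicted, recovered, recall, precision, f1):
        r = metrics_from_counts(known, predicted, recovered)
        assert r.recall == pytest.approx(recall, abs=5e-4)
        assert r.precision == pytest.approx(precision, abs=5e-4)
        assert r.f1 == pytest.approx(f1, abs=5e-4)

    def test_undefined_precision(self):
        r = metrics(ConfusionCounts(0, 0, 5, 3))
        assert r.precision is None
        assert r.recall == 0.0
        assert r.f1 is None

    def test_harmonic_mean_identity_rational_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp = int(rng.integers(0, 50))
            fp = int(rng.integers(0, 50))
            fn = int(rng.integers(0, 50))
            if tp + fp == 0 or tp + fn == 0 or tp == 0:
                continue
            r = metrics(ConfusionCounts(tp, fp, fn, 0))
            p_frac = Fraction(tp, tp + fp)
            r_frac = Fraction(tp, tp + fn)
            f1_frac = 2 * p_frac * r_frac / (p_frac + r_frac)
            assert r.f1 == pytest.approx(float(f1_frac), abs=1e-12)
            assert r.f1 <= (r.precision + r.recall) / 2 + 1e-12


class TestRocAuc:
    def test_perfect_and_null(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 20_000)
        s = rng.random(20_000)
        assert abs(roc_auc(s, y) - 0.5) < 0.02

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_six_point_tie_hand_value(self):
        scores = [0.9, 0.7, 0.7, 0.5, 0.3, 0.1]
        labels = [1, 1, 0, 0, 1, 0]
        # rank oracle: concordant + 0.5*tied over 3x3 pairs
        # pos scores {0.9, 0.7, 0.3}, neg {0.7, 0.5, 0.1}
        # 0.9: beats all 3; 0.7: ties 0.7, beats 0.5, 0.1 -> 2.5; 0.3: beats 0.1
        assert roc_auc(scores, labels) == pytest.approx((3 + 2.5 + 1) / 9)

    def test_rank_pair_oracle_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            num = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert roc_auc(scores, labels) == pytest.approx(num / (len(pos) * len(neg)))


class TestHicSupport:
    enhancer = Enhancer("e", GenomicInterval("chr1", 100_000, 100_500))
    gene = Gene("g", "chr1", 150_000, "+")  # promoter [149000, 150100)

    def make_cm(self, count):
        cm = ContactMatrix(5000)
        cm.add("chr1", 100_000 // 5000, 149_500 // 5000, count)
        return cm

    def test_supported_at_cutoff(self):
        assert hic_support([(self.enhancer, self.gene)], self.make_cm(6), 5) == [True]

    def test_unsupported_above_cutoff(self):
        assert hic_support([(self.enhancer, self.gene)], self.make_cm(6), 10) == [False]

    def test_minimum_separation_rule(self):
        near = Gene("g2", "chr1", 103_000, "+")  # 3 kb away -> excluded
        cm = ContactMatrix(5000)
        cm.add("chr1", 100_000 // 5000, 102_500 // 5000, 100)
        assert hic_support([(self.enhancer, near)], cm, 5) == [False]

    def test_monotone_in_read_cutoff(self):
        cm = self.make_cm(7)
        pairs = [(self.enhancer, self.gene)]
        flags = [hic_support(pairs, cm, c)[0] for c in (1, 5, 7, 8, 20)]
        assert flags == sorted(flags, reverse=True)

    def test_resolution_mismatch(self):
        cm = ContactMatrix(10_000)
        with pytest.raises(ValueError, match="resolution"):
            hic_support([(self.enhancer, self.gene)], cm, 5)

    def test_triplet_reader(self, tmp_path):
        p = tmp_path / "contacts.tsv"
        p.write_text("#h\nchr1\t100000\t145000\t12\nchr1\t100000\t145000\t3\n")
        cm = ContactMatrix.from_tsv(p, 5000)
        assert cm.count("chr1", 20, 29) == 15.0
        assert cm.count("chr1", 29, 20) == 15.0  # symmetric lookup
        bad = tmp_path / "bad.tsv"
        bad.write_text("chr1\t100001\t145000\t3\n")
        with pytest.raises(Exception, match="multiple"):
            ContactMatrix.from_tsv(bad, 5000)


class TestRandomPairs:
    enhancers = [Enhancer("e1", GenomicInterval("chr1", 1_000_000, 1_000_500))]

    def test_forced_single_gene(self):
        genes = [Gene("g1", "chr1", 1_200_000, "+")]
        pairs = random_pairs(self.enhancers, genes, 2_000_000, 5, seed=0)
        assert all(p[0].enhancer_id == "e1" and p[1].gene_id == "g1" for p in pairs)

    def test_seed_determinism(self):
        genes = [Gene(f"g{i}", "chr1", 1_050_000 + 40_000 * i, "+") for i in range(20)]
        a = random_pairs(self.enhancers, genes, 2_000_000, 10, seed=3)
        b = random_pairs(self.enhancers, genes, 2_000_000, 10, seed=3)
        assert [(e.enhancer_id, g.gene_id) for e, g in a] == [
            (e.enhancer_id, g.gene_id) for e, g in b
        ]

    def test_no_eligible_gene_error(self):
        genes = [Gene("g1", "chr2", 100, "+")]
        with pytest.raises(ValueError):
            random_pairs(self.enhancers, genes, 2_000_000, 1, seed=0)

    def test_window_respected(self):
        genes = [Gene("near", "chr1", 1_500_000, "+"), Gene("far", "chr1", 4_000_000, "+")]
        pairs = random_pairs(self.enhancers, genes, 1_000_000, 20, seed=1)
        assert {g.gene_id for _, g in pairs} == {"near"}


class TestBinomialEnrichment:
    def test_closed_form_all_successes(self):
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(2**-10)

    def test_zero_successes(self):
        assert binomial_enrichment(0, 10, 0.5) == 1.0

    def test_direct_summation_oracle(self):
        k, n, p0 = 7, 10, 0.102
        expected = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert binomial_enrichment(k, n, p0) == pytest.approx(expected, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_enrichment(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_enrichment(5, 10, 0.0)


class TestInconsecutiveness:
    candidates = {"e1": ["g1", "g2", "g3", "g4"]}

    def test_interrupted_targets(self):
        flags, frac = inconsecutiveness({"e1": ["g1", "g3"]}, self.candidates)
        assert flags == {"e1": True}
        assert frac == 1.0

    def test_consecutive_targets(self):
        flags, frac = inconsecutiveness({"e1": ["g1", "g2"]}, self.candidates)
        assert flags == {"e1": False}
        assert frac == 0.0

    def test_single_target_excluded(self):
        flags, frac = inconsecutiveness({"e1": ["g2"]}, self.candidates)
        assert flags == {}
        assert math.isnan(frac)

    def test_mixed_fraction(self):
        cands = {"e1": ["a", "b", "c"], "e2": ["d", "e", "f"], "e3": ["x", "y"]}
        targets = {"e1": ["a", "c"], "e2": ["d", "e"], "e3": ["x"]}
        flags, frac = inconsecutiveness(targets, cands)
        assert flags == {"e1": True, "e2": False}
        assert frac == 0.5
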