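"""Per-gene codon-usage indices against hand arithmetic, oracles and invariants."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonbias import (
    CodingSequence,
    CodonCountTable,
    aromo,
    cai,
    cai_weights,
    count_codons,
    enc_expected,
    enc_observed,
    family_homozygosity,
    gc_metrics,
    gravy,
    rscu,
    translate,
)

from oracles import oracle_cai, oracle_enc, oracle_gc_positions, oracle_rscu


def random_count_table(rng, code, max_count=30) -> CodonCountTable:
    counts = {
        c: rng.randint(0, max_count) for c in code.sense_codons if rng.random() < 0.8
    }
    return CodonCountTable({c: n for c, n in counts.items() if n > 0})


class TestCountCodons:
    def test_terminal_stop_excluded(self):
        t = count_codons(CodingSequence("x", "ATGTGGTAA"))
        assert t.counts == {"ATG": 1, "TGG": 1} and t.total_codons == 2

    def test_n_codon_skipped(self):
        t = count_codons(CodingSequence("x", "ATGANNTGG"))
        assert t.counts == {"ATG": 1, "TGG": 1} and t.total_codons == 2

    def test_matches_sliding_window_oracle(self, code):
        rng = random.Random(11)
        cds = "".join(rng.choice(code.sense_codons) for _ in range(100))
        t = count_codons(CodingSequence("x", cds))
        # independent splitter: sliding window with step 3
        from collections import Counter

        expected = Counter(cds[i : i + 3] for i in range(0, len(cds), 3))
        assert t.counts == dict(expected)

    def test_non_triplet_raises(self):
        with pytest.raises(ValueError):
            count_codons(CodingSequence("x", "ATGA"))


class TestRscu:
    def test_phe_printed_counts(self):
        r = rscu(CodonCountTable({"TTT": 99671, "TTC": 106107}))
        assert round(r["TTT"], 2) == 0.97
        assert round(r["TTC"], 2) == 1.03

    def test_uniform_counts_give_ones(self, code):
        r = rscu(CodonCountTable({c: 7 for c in code.sense_codons}))
        assert all(abs(v - 1.0) < 1e-12 for v in r.values())

    def test_leu_high_pool_counts(self):
        counts = {"TTA": 540, "TTG": 2598, "CTT": 2570, "CTC": 5332, "CTA": 1099, "CTG": 4118}
        r = rscu(CodonCountTable(counts))
        assert round(r["TTA"], 2) == 0.20

    def test_unobserved_family_is_nan(self, code):
        r = rscu(CodonCountTable({"TTT": 5}))
        assert math.isnan(r["GGG"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_family_sums_equal_degeneracy(self, seed):
        from codonbias import standard_code

        code = standard_code()
        rng = random.Random(seed)
        t = random_count_table(rng, code)
        r = rscu(t, code)
        for aa, family in code.families.items():
            total = sum(t.get(c) for c in family)
            if total > 0:
                assert sum(r[c] for c in family) == pytest.approx(len(family))

    def test_scale_invariance(self, code):
        rng = random.Random(5)
        t = random_count_table(rng, code)
        scaled = CodonCountTable({c: 13 * n for c, n in t.counts.items()})
        r1, r2 = rscu(t, code), rscu(scaled, code)
        for c in r1:
            if not math.isnan(r1[c]):
                assert r1[c] == pytest.approx(r2[c])


class TestEnc:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 1), 0.5),  # (4*0.625-1)/3
            ((5, 0), 1.0),
            ((2, 2), 1.0 / 3.0),
        ],
    )
    def test_family_homozygosity_hand_values(self, counts, expected):
        assert family_homozygosity(counts) == pytest.approx(expected)

    def test_family_homozygosity_undefined_below_two(self):
        assert math.isnan(family_homozygosity((1, 0)))
        assert math.isnan(family_homozygosity((0, 0)))

    def test_single_codon_per_amino_acid_gives_twenty(self, code):
        counts = {fam[0]: 4 for fam in code.families.values()}
        assert enc_observed(CodonCountTable(counts)) == 20.0

    def test_equal_usage_approaches_sixty_one(self, code):
        t = CodonCountTable({c: 1000 for c in code.sense_codons})
        assert abs(enc_observed(t) - 61.0) <= 0.5

    def test_toy_table_matches_hand_formula(self):
        # Phe (3,1): F=0.5; Tyr (2,2): F=1/3; Val (4,0,0,0): F=1; Gly (1,1,1,1): F=(4*0.25-1)/3=0
        # Gly class mean = (1+0)/2 = 0.5 ... F3 imputed as mean(F2bar, F4bar)
        counts = {
            "TTT": 3, "TTC": 1,
            "TAT": 2, "TAC": 2,
            "GTT": 4,
            "GGT": 1, "GGC": 1, "GGA": 1, "GGG": 1,
            "TTA": 2, "TTG": 2,  # Leu 6-fold, n=4, sum p2 = 0.5 -> F=(2-1)/3
        }
        f2 = (0.5 + 1 / 3) / 2
        f4 = (1.0 + 0.0) / 2
        f6 = (4 * 0.5 - 1) / 3
        f3 = (f2 + f4) / 2
        expected = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
        assert enc_observed(CodonCountTable(counts)) == pytest.approx(min(expected, 61.0))

    def test_missing_two_fold_class_is_nan(self):
        assert math.isnan(enc_observed(CodonCountTable({"GTT": 5, "GTC": 5})))

    def test_brute_force_equivalence_on_random_tables(self, code):
        rng = random.Random(42)
        checked = 0
        for _ in range(200):
            t = random_count_table(rng, code, max_count=12)
            ours = enc_observed(t, code)
            theirs = oracle_enc(t.counts, code.families)
            if math.isnan(ours):
                assert math.isnan(theirs)
            else:
                assert ours == pytest.approx(theirs)
                checked += 1
        assert checked > 100


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (1.0, 32.0), (0.0, 31.0)])
    def test_closed_form_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_maximum_near_half(self):
        grid = np.linspace(0, 1, 201)
        vals = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)
        assert max(vals) > 60

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestGcMetrics:
    def test_all_gc_sequence_saturates(self):
        m = gc_metrics(CodingSequence("x", "GCCGGCGCG"))
        assert (m.gc1, m.gc2, m.gc3, m.gc3s, m.gc12, m.gc_all) == (1, 1, 1, 1, 1, 1)

    def test_met_excluded_from_gc3s_only(self):
        m = gc_metrics(CodingSequence("x", "ATGTAT"))
        assert m.gc3 == pytest.approx(0.5)  # ATG ends in G, TAT in T
        assert m.gc3s == pytest.approx(0.0)  # only Tyr is synonymously variable

    def test_gc12_is_mean_of_gc1_gc2(self, code):
        rng = random.Random(8)
        cds = "".join(rng.choice(code.sense_codons) for _ in range(50))
        m = gc_metrics(CodingSequence("x", cds))
        assert m.gc12 == pytest.approx((m.gc1 + m.gc2) / 2)

    def test_matches_position_scan_oracle(self, code):
        rng = random.Random(9)
        cds = "".join(rng.choice(code.sense_codons) for _ in range(50)) + "TAA"
        m = gc_metrics(CodingSequence("x", cds))
        g1, g2, g3 = oracle_gc_positions(cds, set(code.stop_codons))
        assert (m.gc1, m.gc2, m.gc3) == pytest.approx((g1, g2, g3))


class TestCai:
    def test_weights_from_phe_reference(self):
        w = cai_weights(CodonCountTable({"TTT": 99671, "TTC": 106107}))
        assert w.w["TTC"] == pytest.approx(1.0)
        assert w.w["TTT"] == pytest.approx(99671 / 106107, abs=1e-4)

    def test_pseudocount_keeps_w_positive(self):
        w = cai_weights(CodonCountTable({"TTT": 100}))
        assert 0 < w.w["TTC"] < 1

    def test_uniform_reference_gives_unit_weights(self, code):
        w = cai_weights(CodonCountTable({c: 50 for c in code.sense_codons}))
        assert all(v == pytest.approx(1.0) for v in w.w.values())

    def test_max_w_is_one_in_every_family(self, code):
        rng = random.Random(12)
        w = cai_weights(random_count_table(rng, code), code)
        for aa, family in code.families.items():
            if len(family) > 1:
                assert max(w.w[c] for c in family) == pytest.approx(1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cai_weights(CodonCountTable({}))

    def test_gene_of_preferred_codons_scores_one(self, code):
        rng = random.Random(13)
        w = cai_weights(random_count_table(rng, code), code)
        best = {max(fam, key=lambda c: w.w[c]): 3 for fam in code.families.values() if len(fam) > 1}
        assert cai(CodonCountTable(best), w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self, code):
        w = cai_weights(CodonCountTable({"TTT": 25, "TTC": 100, "TAT": 10, "TAC": 10}), code)
        # TTT carries w=0.25, TTC w=1; equal use -> sqrt(0.25)
        gene = CodonCountTable({"TTT": 10, "TTC": 10})
        assert cai(gene, w) == pytest.approx(0.5)

    def test_matches_log_mean_oracle(self, code):
        rng = random.Random(14)
        w = cai_weights(random_count_table(rng, code), code)
        gene = random_count_table(rng, code, max_count=5)
        ours = cai(gene, w)
        theirs = oracle_cai(gene.counts, w.w)
        if math.isnan(ours):
            assert math.isnan(theirs)
        else:
            assert ours == pytest.approx(theirs)

    def test_reference_beats_uniform_gene(self, code):
        """A reference set scored against its own weights >= a uniform-usage gene."""
        rng = random.Random(15)
        ref = random_count_table(rng, code, max_count=50)
        w = cai_weights(ref, code)
        uniform = CodonCountTable({c: 10 for c in code.analysis_codons})
        assert cai(ref, w) >= cai(uniform, w)


class TestProteinIndices:
    def test_gravy_single_residue(self):
        assert gravy("AAAA") == pytest.approx(1.8)

    def test_gravy_two_entry_mean(self):
        assert gravy("MW") == pytest.approx((1.9 - 0.9) / 2)

    def test_gravy_matches_biopython_analysis(self, code):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = random.Random(16)
        prot = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(20))
        assert gravy(prot) == pytest.approx(ProteinAnalysis(prot).gravy())

    def test_gravy_all_x_is_nan(self):
        assert math.isnan(gravy("XXX"))

    @pytest.mark.parametrize("prot,expected", [("FYWA", 0.75), ("AAAA", 0.0)])
    def test_aromo_examples(self, prot, expected):
        assert aromo(prot) == expected

    def test_aromo_matches_membership_counter(self):
        rng = random.Random(17)
        prot = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
        assert aromo(prot) == pytest.approx(sum(map(prot.count, "FYW")) / len(prot))
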