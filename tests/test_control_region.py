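"""Tandem repeats, SSRs, inverted repeats, motif blocks, tRNA folds."""

import re

import numpy as np
import pytest

from anomito.control_region import (annotate_motifs, classify_trna_structure,
                                    find_inverted_repeats, find_ssrs,
                                    find_tandem_repeats)
from anomito.synthetic import (CRSpec, generate_control_region,
                               structured_trna)

RC = str.maketrans("ACGT", "TGCA")


def rand_dna(rng, n, p=(0.33, 0.12, 0.16, 0.39)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])


class TestTandemRepeats:
    def test_dinucleotide_repeat_in_flanks(self):
        seq = "CCGGAAGGCC" + "AT" * 6 + "GGCCTTACGG"
        reps = find_tandem_repeats(seq)
        assert any(r.period == 2 and r.copy_number == pytest.approx(6.0, abs=0.1)
                   for r in reps)

    def test_perfect_repeat_period_and_copies(self):
        rng = np.random.default_rng(0)
        motif = rand_dna(rng, 12)
        seq = rand_dna(rng, 60) + motif * 5 + rand_dna(rng, 60)
        reps = find_tandem_repeats(seq)
        hit = [r for r in reps
               if 12 % r.period == 0 and abs(r.end - r.start + 1 - 60) <= 12]
        assert hit, reps
        main = min(hit, key=lambda r: abs(r.period - 12))
        if main.period == 12:
            assert main.copy_number == pytest.approx(5.0, abs=0.1)
            assert main.percent_matches == 100.0
            assert main.consensus in motif * 2

    def test_planted_47bp_repeat_recovered_with_mutations(self):
        cr, truth = generate_control_region(CRSpec(seed=123))
        reps = find_tandem_repeats(cr)
        hit = [r for r in reps
               if abs(r.period - 47) <= 1 and abs(r.copy_number - 3.6) <= 0.3]
        assert hit
        r = hit[0]
        assert abs(r.start - truth.repeat["start"]) <= 47
        assert abs(r.end - truth.repeat["end"]) <= 47

    def test_nothing_reported_on_short_random_sequence(self):
        rng = np.random.default_rng(5)
        seq = "ACGTGACTTGCACGATCGATTACGGATCGCAT"
        assert find_tandem_repeats(seq) == []

    def test_copy_number_threshold(self):
        rng = np.random.default_rng(1)
        motif = rand_dna(rng, 30)
        seq = rand_dna(rng, 50) + motif + motif[:10] + rand_dna(rng, 50)
        reps = find_tandem_repeats(seq)   # only ~1.3 copies planted
        assert not any(r.period == 30 for r in reps)


class TestSSRs:
    def test_at_microsatellite(self):
        found = find_ssrs("GGC" + "AT" * 8 + "CCA")
        assert any(s.unit == "AT" and s.copies == 8 for s in found)

    def test_mononucleotide_run(self):
        found = find_ssrs("C" * 3 + "A" * 15 + "G" * 3)
        assert any(s.unit == "A" and s.copies == 15 for s in found)

    def test_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(17)
        seq = rand_dna(rng, 1000, p=(0.25, 0.25, 0.25, 0.25))
        seq = seq[:300] + "TA" * 7 + seq[300:600] + "AAG" * 5 + seq[600:]
        found = {(s.unit, s.copies, s.start) for s in find_ssrs(seq)}
        expected = set()
        thresholds = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}
        for u, min_c in thresholds.items():
            for m in re.finditer(r"(.{%d})\1{%d,}" % (u, min_c - 1), seq):
                unit = m.group(1)
                if any(unit == unit[:d] * (u // d)
                       for d in range(1, u) if u % d == 0):
                    continue
                copies = len(m.group(0)) // u
                expected.add((unit, copies, m.start() + 1))
        # regex matching is also left-greedy/maximal; sets must agree
        assert found == expected


class TestInvertedRepeats:
    def test_planted_arm15_loop4(self):
        rng = np.random.default_rng(3)
        core = rand_dna(rng, 15, p=(0.25,) * 4)
        seq = rand_dna(rng, 30, p=(0.25,) * 4) + core + "AAAA" + \
            core.translate(RC)[::-1] + rand_dna(rng, 30, p=(0.25,) * 4)
        hits = find_inverted_repeats(seq, min_arm=10)
        assert any(h.arm_length >= 15 and h.loop_length == 4 for h in hits)

    def test_no_arm_means_empty(self):
        assert find_inverted_repeats("ACGAATCGTAGCCGAGGTCCTTGAATCCAC") == []

    def test_two_planted_hairpins_recovered(self):
        cr, truth = generate_control_region(
            CRSpec(hairpin_stems=((12, 5), (14, 6)), seed=7))
        hits = find_inverted_repeats(cr)
        for planted in truth.hairpins:
            assert any(abs(h.arm1_start - planted["start"]) <= 3
                       and abs(h.arm2_end - planted["end"]) <= 3
                       for h in hits), (planted, hits)

    def test_arm2_reverse_complements_arm1(self):
        rng = np.random.default_rng(8)
        core = rand_dna(rng, 20, p=(0.25,) * 4)
        seq = core + "AAAAA" + core.translate(RC)[::-1]
        h = find_inverted_repeats(seq)[0]
        arm1 = seq[h.arm1_start - 1:h.arm1_end]
        arm2 = seq[h.arm2_start - 1:h.arm2_end]
        mism = sum(a != b for a, b in
                   zip(arm1, arm2.translate(RC)[::-1]))
        assert 100.0 * (len(arm1) - mism) / len(arm1) >= h.matches - 1e-9


class TestMotifBlocks:
    def test_poly_t(self):
        blocks = annotate_motifs("ACGAC" + "T" * 7 + "GCAGC",
                                 include_hairpins=False)
        assert [(b.kind, b.start, b.end) for b in blocks] == \
            [("polyT", 6, 12)]

    def test_taa_block(self):
        blocks = annotate_motifs("GCGC" + "TATAATAA" + "GCGC",
                                 include_hairpins=False)
        assert any(b.kind == "TAA_block" and b.start == 5 and b.end == 12
                   for b in blocks)

    def test_ga_block_needs_two_g(self):
        blocks = annotate_motifs("CCGAGAGGACC", include_hairpins=False)
        assert any(b.kind == "GA_block" for b in blocks)
        assert not any(b.kind == "GA_block"
                       for b in annotate_motifs("CCAAAAAGCC",
                                                include_hairpins=False))

    def test_subtypes_relative_to_main_repeat(self):
        cr, truth = generate_control_region(CRSpec(seed=2))
        blocks = annotate_motifs(cr)
        ga = [b for b in blocks if b.kind == "GA_block"]
        rep = truth.repeat
        for b in ga:
            if b.end < rep["start"] - 50:
                assert b.subtype == "5prime"
            elif b.start > rep["end"] + 50:
                assert b.subtype == "3prime"

    def test_planted_motifs_found(self):
        cr, truth = generate_control_region(CRSpec(seed=31))
        blocks = annotate_motifs(cr, include_hairpins=False)
        for planted in truth.motifs:
            assert any(b.kind == planted["kind"]
                       and b.start <= planted["start"]
                       and b.end >= planted["end"] - 1
                       for b in blocks), planted


class TestTrnaClassification:
    def test_designed_cloverleaf(self):
        assert classify_trna_structure(structured_trna()) == "cloverleaf"

    def test_d_arm_deletion_becomes_atypical(self):
        assert classify_trna_structure(
            structured_trna(drop_d_arm=True)) == "atypical"

    def test_unstructured_poly_a_atypical(self):
        assert classify_trna_structure("A" * 40) == "atypical"

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            classify_trna_structure("ACGU" * 5)
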