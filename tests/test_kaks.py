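"""NG86 Ka/Ks estimation: counting oracles, alignment, windows, Fisher."""

import itertools
import math

import numpy as np
import pytest

from anomito.kaks import (CodonAlignment, SaturationError, classify_selection,
                          codon_align, depth_pair_report, fisher_exact,
                          kaks_ng86, ng86_counts, sliding_window)
from anomito.mitoio import MITO_TABLE
from anomito.synthetic import CodonPairSpec, evolve_codon_pair

STOPS = set(MITO_TABLE.stop_codons)
AA = MITO_TABLE.forward_table


def pairwise_aln(codons1, codons2, gene="g"):
    return CodonAlignment(tuple(codons1), tuple(codons2),
                          tuple([True] * len(codons1)), gene)


def oracle_pathway_counts(c1, c2):
    """Exhaustive substitution-order enumeration, written independently:
    returns pathway-averaged (syn, nonsyn) differences with stop-passing
    orders excluded (all orders when every one is blocked)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    all_paths, open_paths = [], []
    for perm in itertools.permutations(diff_pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for p in perm:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                blocked = True
            if cur in STOPS or nxt in STOPS:
                nd += 1        # steps touching a stop count as nonsynonymous
            elif AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            open_paths.append((sd, nd))
    chosen = open_paths or all_paths
    return (sum(s for s, _ in chosen) / len(chosen),
            sum(n for _, n in chosen) / len(chosen))


def oracle_syn_sites(codon):
    syn = 0
    for p in range(3):
        for b in "ACGT":
            if b != codon[p]:
                mut = codon[:p] + b + codon[p + 1:]
                if mut not in STOPS and AA[mut] == AA[codon]:
                    syn += 1
    return syn / 3.0


CODON_PANEL = ["TTT", "TTC", "CTG", "ATG", "AAA", "AGA", "GGG", "TCA",
               "TGG", "CGA"]


class TestCountingOracles:
    def test_pathway_counts_match_exhaustive_enumeration(self):
        """All <=3-codon alignments over a fixed panel: S_A and S_S equal
        the exhaustive substitution-order oracle to 1e-9."""
        sense = [c for c in CODON_PANEL if c not in STOPS]
        for cs1 in itertools.product(sense, repeat=2):
            for cs2 in itertools.product(sense, repeat=2):
                nd, sd, la, ls, _ = ng86_counts(
                    pairwise_aln(list(cs1), list(cs2)), min_codons=1)
                exp_sd = sum(oracle_pathway_counts(a, b)[0]
                             for a, b in zip(cs1, cs2))
                exp_nd = sum(oracle_pathway_counts(a, b)[1]
                             for a, b in zip(cs1, cs2))
                assert sd == pytest.approx(exp_sd, abs=1e-9), (cs1, cs2)
                assert nd == pytest.approx(exp_nd, abs=1e-9), (cs1, cs2)
                exp_ls = sum((oracle_syn_sites(a) + oracle_syn_sites(b)) / 2
                             for a, b in zip(cs1, cs2))
                assert ls == pytest.approx(exp_ls, abs=1e-9)

    def test_site_count_conservation(self):
        rng = np.random.default_rng(0)
        codons = sorted(AA)
        for _ in range(30):
            k = int(rng.integers(10, 40))
            c1 = list(rng.choice(codons, k))
            c2 = list(rng.choice(codons, k))
            nd, sd, la, ls, used = ng86_counts(pairwise_aln(c1, c2))
            assert la + ls == pytest.approx(3 * k, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        codons = sorted(AA)
        c1 = list(rng.choice(codons, 30))
        c2 = list(rng.choice(codons, 30))
        assert ng86_counts(pairwise_aln(c1, c2)) == \
            ng86_counts(pairwise_aln(c2, c1))


class TestEstimates:
    def test_identical_sequences(self):
        est = kaks_ng86(pairwise_aln(["ATG"] * 12, ["ATG"] * 12),
                        with_fisher=False)
        assert est.Ka == 0 and est.Ks == 0 and not est.omega_defined

    def test_synonymous_only_divergence_gives_omega_zero(self):
        # third-position synonymous differences only (NAD4L-row pattern)
        c1 = ["ATT"] * 16 + ["GGA", "CTA", "TCA", "GTA"]
        c2 = ["ATT"] * 16 + ["GGG", "CTG", "TCG", "GTG"]
        est = kaks_ng86(pairwise_aln(c1, c2), with_fisher=False)
        assert est.Ka == 0 and est.Ks > 0
        assert est.omega == 0.0 and est.omega_defined

    def test_saturation_raises(self):
        c1 = ["TTT"] * 12
        c2 = ["AAG"] * 12
        with pytest.raises(SaturationError):
            kaks_ng86(pairwise_aln(c1, c2), with_fisher=False)

    def test_too_few_codons_rejected(self):
        with pytest.raises(ValueError, match="unmasked"):
            kaks_ng86(pairwise_aln(["ATG"] * 5, ["ATG"] * 5))

    def test_ks_increases_with_divergence_time(self):
        ks = []
        for t in (0.05, 0.2, 0.5):
            vals = []
            for seed in range(3):
                s1, s2, _ = evolve_codon_pair(
                    CodonPairSpec(n_codons=300, omega=0.2, t=t, seed=seed))
                vals.append(kaks_ng86(codon_align(s1, s2),
                                      with_fisher=False).Ks)
            ks.append(np.mean(vals))
        assert ks[0] < ks[1] < ks[2]


class TestCodonAlign:
    def test_identical_no_masked_columns(self):
        cds = "ATGAAACCCGGGTTTTAT" * 3
        aln = codon_align(cds, cds)
        assert aln.n_unmasked == aln.n_codons == len(cds) // 3

    def test_codon_insertion_masks_one_gap_column(self):
        cds1 = "ATGAAATTCGGATAT"
        cds2 = "ATGAAACTGTTCGGATAT"   # one extra codon
        aln = codon_align(cds1, cds2)
        assert aln.n_codons - aln.n_unmasked == 1
        assert "---" in aln.codons1

    def test_masked_count_matches_column_scan(self):
        rng = np.random.default_rng(6)
        s1, s2, _ = evolve_codon_pair(CodonPairSpec(n_codons=100, omega=0.3,
                                                    t=0.4, seed=5))
        aln = codon_align(s1, s2)
        recount = sum(
            "-" in c1 or "-" in c2 or c1 in STOPS or c2 in STOPS
            for c1, c2 in zip(aln.codons1, aln.codons2))
        assert aln.n_codons - aln.n_unmasked == recount

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_align("ATGA", "ATG")


class TestFisher:
    def test_no_substitutions_p_one(self):
        est = kaks_ng86(pairwise_aln(["ATG"] * 12, ["ATG"] * 12),
                        with_fisher=True)
        assert est.p_fisher == 1.0

    def test_matches_hypergeometric_enumeration(self):
        from anomito.kaks import KaKsEstimate
        est = KaKsEstimate("g", S_A=1, S_S=50, L_A=100, L_S=100,
                           Ka=0, Ks=0, omega=0, omega_defined=True)
        p = fisher_exact(est)
        assert p == pytest.approx(_brute_fisher(1, 99, 50, 50), rel=1e-9)

    def test_underflow_reported_as_min_positive_float(self):
        from anomito.kaks import KaKsEstimate
        est = KaKsEstimate("g", S_A=0, S_S=900, L_A=2000, L_S=1000,
                           Ka=0, Ks=0, omega=0, omega_defined=True)
        p = fisher_exact(est)
        assert p > 0.0


def _brute_fisher(a, b, c, d):
    """Two-sided Fisher by full enumeration over tables with fixed margins."""
    def log_fact(n):
        return math.lgamma(n + 1)

    def log_p(a_, b_, c_, d_):
        n = a_ + b_ + c_ + d_
        return (log_fact(a_ + b_) + log_fact(c_ + d_) + log_fact(a_ + c_)
                + log_fact(b_ + d_) - log_fact(n) - log_fact(a_)
                - log_fact(b_) - log_fact(c_) - log_fact(d_))

    row1, row2, col1 = a + b, c + d, a + c
    p_obs = log_p(a, b, c, d)
    total = 0.0
    for a_ in range(max(0, col1 - row2), min(row1, col1) + 1):
        lp = log_p(a_, row1 - a_, col1 - a_, row2 - col1 + a_)
        if lp <= p_obs + 1e-12:
            total += math.exp(lp)
    return total


class TestWindowsAndClassification:
    def test_window_tiling_156_codons(self):
        c = ["ATG"] * 156
        aln = pairwise_aln(c, c)
        scan = sliding_window(aln, window=52, step=12)
        assert scan.starts == tuple(range(0, 97, 12))
        assert len(scan.estimates) == 9

    def test_whole_gene_window_equals_full_estimate(self):
        s1, s2, _ = evolve_codon_pair(CodonPairSpec(n_codons=60, omega=0.3,
                                                    t=0.3, seed=2))
        aln = codon_align(s1, s2)
        scan = sliding_window(aln, window=aln.n_codons, step=12)
        whole = kaks_ng86(aln, with_fisher=False)
        assert len(scan.estimates) == 1
        assert scan.estimates[0].Ka == pytest.approx(whole.Ka)
        assert scan.estimates[0].Ks == pytest.approx(whole.Ks)

    def test_divergent_block_found_by_max_omega_window(self):
        rng = np.random.default_rng(12)
        quiet1, quiet2, _ = evolve_codon_pair(
            CodonPairSpec(n_codons=160, omega=0.02, t=0.3, seed=31))
        hot1, hot2, _ = evolve_codon_pair(
            CodonPairSpec(n_codons=52, omega=2.0, t=0.3, seed=32))
        c1 = quiet1[:240] + hot1 + quiet1[240:]
        c2 = quiet2[:240] + hot2 + quiet2[240:]
        aln = codon_align(c1, c2)
        scan = sliding_window(aln)
        omegas = [(s, e.omega) for s, e in zip(scan.starts, scan.estimates)
                  if e.omega_defined and not math.isnan(e.omega)]
        best_start = max(omegas, key=lambda x: x[1])[0]
        # the divergent block occupies codons 80..132
        assert 36 <= best_start <= 120

    @pytest.mark.parametrize("omega,expected", [
        (0.00287, "purifying"),       # COX1-scale pairwise omega
        (1.0, "neutral"),
        (1.04, "neutral"),
        (1.5, "positive"),
        (0.7, "purifying"),
    ])
    def test_classification_bands(self, omega, expected):
        assert classify_selection(omega) == expected

    def test_undefined_omega_rejected(self):
        with pytest.raises(ValueError):
            classify_selection(float("nan"))


class TestDepthPairReport:
    def test_identical_genomes_all_zero(self, genome_pair_omega01):
        g1, _ = genome_pair_omega01
        table = depth_pair_report([(g1, g1, "same")])
        ok = table[table.status == "ok"]
        assert len(ok) == 13
        assert (ok["Ka"] == 0).all() and (ok["Ks"] == 0).all()

    def test_omega_below_one_for_purifying_pair(self, genome_pair_omega01):
        g1, g2 = genome_pair_omega01
        table = depth_pair_report([(g1, g2, "shallow|shallow")])
        ok = table[table.status == "ok"]
        assert len(ok) == 13
        assert (ok["Ka/Ks"] < 1).all()

    def test_missing_gene_reported_and_skipped(self, genome_pair_omega01):
        from anomito.mitoio import MitoGenome
        g1, g2 = genome_pair_omega01
        partial = MitoGenome(g2.accession, g2.taxon, g2.sequence,
                             features=[f for f in g2.features
                                       if f.name != "atp8"])
        table = depth_pair_report([(g1, partial, "x")])
        assert (table[table.PCG == "atp8"]["status"] == "missing").all()
        assert len(table[table.status == "ok"]) == 12
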