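"""Diversity, Tajima's D, Weir-Cockerham Fst and ABBA-BABA statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from yeastcohort.popgen import (
    abba_baba,
    nucleotide_diversity,
    tajimas_d,
    wc_fst,
    wc_site_components,
)
from yeastcohort.variant_io import GenotypeMatrix


def _matrix(code_rows, chroms=None, positions=None):
    codes = np.array(code_rows, dtype=np.int8)
    n_sites, n_strains = codes.shape
    sites = pd.DataFrame(
        {
            "chrom": chroms or ["chr01"] * n_sites,
            "pos": positions or list(range(1, n_sites + 1)),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    return GenotypeMatrix([f"S{i + 1}" for i in range(n_strains)], sites, codes)


def _brute_pi(site_codes, span):
    """Average pairwise haplotype difference summed over sites, by explicit
    enumeration of the per-site allele multisets."""
    total = 0.0
    for row in site_codes:
        alleles = []
        for code in row:
            if code < 0:
                continue
            alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[code]
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if alleles[i] != alleles[j]
        )
        total += diffs / (n * (n - 1) / 2)
    return total / span


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        m = _matrix([[0, 0], [0, 0], [0, 0]])
        assert nucleotide_diversity(m, ["S1", "S2"], span_bp=100).pi == 0.0

    def test_one_het_site_of_hundred(self):
        # 2 haplotypes (one diploid strain) differing at 1 of 100 spanned sites
        m = _matrix([[1]])
        res = nucleotide_diversity(m, ["S1"], span_bp=100)
        assert res.pi == pytest.approx(0.01)

    def test_matches_brute_force_enumeration(self, rng):
        codes = rng.integers(0, 3, size=(5, 2)).astype(np.int8)
        m = _matrix(codes)
        res = nucleotide_diversity(m, ["S1", "S2"], span_bp=5)
        assert res.pi == pytest.approx(_brute_pi(codes, 5), abs=1e-12)

    def test_invariant_to_strain_order_and_allele_relabeling(self, rng):
        codes = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        m = _matrix(codes)
        strains = ["S1", "S2", "S3", "S4"]
        a = nucleotide_diversity(m, strains, 1000).pi
        b = nucleotide_diversity(m, strains[::-1], 1000).pi
        flipped = _matrix((2 - codes).astype(np.int8))
        c = nucleotide_diversity(flipped, strains, 1000).pi
        assert a == pytest.approx(b, abs=1e-15)
        assert a == pytest.approx(c, abs=1e-12)

    def test_empty_group_rejected(self):
        m = _matrix([[0, 0]])
        with pytest.raises(ValueError):
            nucleotide_diversity(m, [], span_bp=10)


class TestTajimasD:
    def test_monomorphic_group_is_na(self):
        m = _matrix([[0, 0], [0, 0]])
        assert tajimas_d(m, ["S1", "S2"]).tajimas_d is None

    def test_singletons_fixture_matches_closed_form(self):
        # n = 4 haplotypes (2 diploids), S = 3 singleton sites: one het call
        # per site, alternating strains
        m = _matrix([[1, 0], [0, 1], [1, 0]])
        res = tajimas_d(m, ["S1", "S2"])
        n, S = 4, 3
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        theta_pi = 3 * (2 * 1 * 3 / (4 * 3))  # three singleton sites
        expected = (theta_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert res.tajimas_d == pytest.approx(expected, abs=1e-12)
        assert res.tajimas_d < 0

    def test_neutral_coalescent_mean_near_zero(self):
        """Mean D over msprime neutral replicates (n = 10 haplotypes) is ~0."""
        msprime = pytest.importorskip("msprime")
        values = []
        reps = msprime.sim_ancestry(
            samples=5, ploidy=2, sequence_length=5e4, recombination_rate=0,
            population_size=1e4, num_replicates=3000, random_seed=7,
        )
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=ts.num_edges + 1)
            if mts.num_sites < 3:
                continue
            geno = mts.genotype_matrix()  # sites x 10 haplotypes
            codes = (geno[:, ::2] + geno[:, 1::2]).astype(np.int8)
            codes[codes > 2] = 2
            d = tajimas_d(_matrix(codes), [f"S{i + 1}" for i in range(5)]).tajimas_d
            if d is not None:
                values.append(d)
        assert len(values) > 1000
        assert np.mean(values) == pytest.approx(0.0, abs=0.1)


def _wc_oracle(codes_a, codes_b):
    """Independent transcription of the two-population Weir-Cockerham (1984)
    component formulas with explicit loops."""
    pops = []
    for codes in (codes_a, codes_b):
        called = [c for c in codes if c >= 0]
        n = len(called)
        p = sum(called) / (2 * n)
        h = sum(1 for c in called if c == 1) / n
        pops.append((n, p, h))
    r = 2
    n_bar = sum(n for n, _, _ in pops) / r
    n_c = (r * n_bar - sum(n * n for n, _, _ in pops) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p, _ in pops) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p, _ in pops) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, _, h in pops) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


class TestWcFst:
    def test_textbook_fixture_to_1e12(self):
        # p1 = 0.2, p2 = 0.8, 10 diploids each, all calls homozygous
        codes_a = np.array([2, 2, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        codes_b = np.array([2, 2, 2, 2, 2, 2, 2, 2, 0, 0], dtype=np.int8)
        ours = wc_site_components([codes_a, codes_b])
        oracle = _wc_oracle(codes_a, codes_b)
        for x, y in zip(ours, oracle):
            assert x == pytest.approx(y, abs=1e-12)

    def test_random_sites_match_oracle(self, rng):
        for _ in range(50):
            codes_a = rng.integers(0, 3, size=8).astype(np.int8)
            codes_b = rng.integers(0, 3, size=6).astype(np.int8)
            ours = wc_site_components([codes_a, codes_b])
            oracle = _wc_oracle(codes_a, codes_b)
            for x, y in zip(ours, oracle):
                assert x == pytest.approx(y, abs=1e-12)

    def test_fixed_difference_near_one(self):
        codes = np.vstack([np.concatenate([np.zeros(10), np.full(10, 2)])
                           for _ in range(5)]).astype(np.int8)
        m = _matrix(codes)
        a = [f"S{i + 1}" for i in range(10)]
        b = [f"S{i + 11}" for i in range(10)]
        win = wc_fst(m, a, b)
        assert len(win) == 1
        assert win["weighted_fst"].iloc[0] >= 0.95

    def test_panmictic_groups_near_zero(self, rng):
        # both groups drawn from the same allele frequencies
        n_sites = 400
        freqs = rng.uniform(0.1, 0.9, n_sites)
        codes = np.column_stack(
            [rng.binomial(2, freqs) for _ in range(20)]
        ).astype(np.int8)
        m = _matrix(codes, positions=list(range(1, 10 * n_sites, 10)))
        a = [f"S{i + 1}" for i in range(10)]
        b = [f"S{i + 11}" for i in range(10)]
        win = wc_fst(m, a, b, window_bp=500)
        assert abs(win["weighted_fst"].median()) < 0.02

    def test_window_sums_conserve_pooled_components(self, rng):
        codes = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
        m = _matrix(codes, positions=list(range(1, 4000, 20)))
        a = [f"S{i + 1}" for i in range(6)]
        b = [f"S{i + 7}" for i in range(6)]
        win = wc_fst(m, a, b, window_bp=1000)
        pooled = np.array(
            [wc_site_components([codes[i, :6], codes[i, 6:]]) for i in range(200)]
        )
        finite = np.isfinite(pooled[:, 0])
        assert win["sum_a"].sum() == pytest.approx(pooled[finite, 0].sum(), abs=1e-9)
        total = pooled[finite].sum()
        assert (win["sum_a"] + win["sum_b"] + win["sum_c"]).sum() == pytest.approx(
            total, abs=1e-9
        )


class TestAbbaBaba:
    @staticmethod
    def _pattern_matrix(n_abba, n_baba, n_bbaa=0):
        rows = []
        # columns: P1, P2, P3, O strains (one diploid each)
        rows += [[0, 2, 2, 0]] * n_abba
        rows += [[2, 0, 2, 0]] * n_baba
        rows += [[2, 2, 0, 0]] * n_bbaa
        return _matrix(rows)

    def test_integer_count_fixture(self):
        m = self._pattern_matrix(30, 10, 5)
        res = abba_baba(m, ["S1"], ["S2"], ["S3"], ["S4"])
        assert res.abba == pytest.approx(30)
        assert res.baba == pytest.approx(10)
        assert res.bbaa == pytest.approx(5)
        assert res.d == pytest.approx(0.5)

    def test_swap_p1_p2_negates_d(self):
        m = self._pattern_matrix(30, 10)
        a = abba_baba(m, ["S1"], ["S2"], ["S3"], ["S4"])
        b = abba_baba(m, ["S2"], ["S1"], ["S3"], ["S4"])
        assert b.d == pytest.approx(-a.d, abs=1e-15)

    def test_no_informative_sites_is_na(self):
        m = _matrix([[2, 2, 2, 0], [0, 0, 0, 0]])
        res = abba_baba(m, ["S1"], ["S2"], ["S3"], ["S4"])
        assert res.d is None

    def test_symmetric_null_within_three_se(self, rng):
        # P1 and P2 drawn iid from the same frequencies: E[D] = 0
        n_sites = 2000
        freqs = rng.uniform(0.05, 0.95, n_sites)
        cols = {}
        for i in range(4):  # P1 strains S1..S4
            cols[i] = rng.binomial(2, freqs)
        for i in range(4, 8):  # P2 strains
            cols[i] = rng.binomial(2, freqs)
        p3_freqs = np.clip(freqs + rng.normal(0, 0.1, n_sites), 0, 1)
        for i in range(8, 12):
            cols[i] = rng.binomial(2, p3_freqs)
        for i in range(12, 14):  # outgroup mostly ancestral
            cols[i] = rng.binomial(2, np.full(n_sites, 0.05))
        codes = np.column_stack([cols[i] for i in range(14)]).astype(np.int8)
        m = _matrix(codes)
        res = abba_baba(
            m,
            [f"S{i}" for i in range(1, 5)],
            [f"S{i}" for i in range(5, 9)],
            [f"S{i}" for i in range(9, 13)],
            ["S13", "S14"],
        )
        assert res.se is not None and res.se > 0
        assert abs(res.d) < 3 * res.se

    def test_z_sign_matches_d_sign(self):
        m = self._pattern_matrix(30, 10)
        res = abba_baba(m, ["S1"], ["S2"], ["S3"], ["S4"], block_count=8)
        if res.z is not None and res.d:
            assert np.sign(res.z) == np.sign(res.d)
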