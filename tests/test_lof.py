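"""CDS reconstruction, LOF classification and gap-statistic clustering."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from yeastcohort import synthetic
from yeastcohort.lof import (
    ConsequenceCall,
    GeneModel,
    build_lof_matrix,
    classify_cohort_lof,
    classify_lof,
    kmeans_cluster,
    select_k_gap,
)
from yeastcohort.variant_io import HET, HOM_ALT, SampleCall, VariantSite

_NONSTOP = [
    c
    for c in ("".join(b) for b in __import__("itertools").product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
]


def _toy_gene(n_codons=300, strand="+", pad=50, seed=0):
    """A single-CDS gene embedded in a padded chromosome."""
    rng = np.random.default_rng(seed)
    body = [c for c in rng.choice(_NONSTOP, n_codons - 2) if c != "ATG"]
    while len(body) < n_codons - 2:
        body.append("CAT")
    cds = "ATG" + "".join(body) + "TAA"
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    flank = "".join(rng.choice(list("ACGT"), pad))
    chrom_seq = flank + genomic + flank
    gene = GeneModel("toy", "chr01", strand, ((pad, pad + len(cds)),))
    return gene, {"chr01": chrom_seq}, cds


class TestClassifyLof:
    def test_reference_itself_is_none(self):
        gene, ref, _ = _toy_gene()
        call = classify_lof("S", gene, ref, [])
        assert call.lof_class == "none"

    def test_single_bp_deletion_is_frameshift(self):
        gene, ref, _ = _toy_gene()
        # delete one base inside codon 10 (CDS offset 29)
        pos0 = 50 + 28
        ref_str = ref["chr01"][pos0 : pos0 + 2]
        call = classify_lof("S", gene, ref, [(pos0 + 1, ref_str, ref_str[0])])
        assert call.lof_class == "frameshift"

    def test_compensated_insertion_pair_is_none(self):
        # +1 bp at codon 10 and +2 bp 9 bases later restore the frame;
        # the planting helper guarantees no stop appears in between
        cohort = synthetic.simulate_cohort(
            synthetic.CohortConfig(
                n_chromosomes=2, chrom_length_bp=100_000, n_genes=8,
                group_specs=(synthetic.GroupSpec("A", 2, 2, 0.0, 0.001),), seed=3,
            )
        )
        gene_id = cohort.genes["gene_id"].iloc[0]
        synthetic.plant_lof_variants(cohort, [("A_01", gene_id, "compensated_pair")])
        models = [GeneModel.from_annotation(r) for _, r in cohort.genes.iterrows()]
        calls = classify_cohort_lof(cohort.variants, models, cohort.reference, ["A_01"])
        assert all(not c.is_lof for c in calls)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_at_99_percent_is_none(self, strand):
        gene, ref, cds = _toy_gene(n_codons=300, strand=strand)
        # plant TAA at codon 297 (1-based), beyond floor(0.98 x 300) = 294
        codon_i = 296
        variants = _codon_to_taa_variants(gene, ref, cds, codon_i)
        call = classify_lof("S", gene, ref, variants)
        assert call.lof_class == "none"
        assert call.stop_fraction == pytest.approx(297 / 300)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_early_stop_is_stop_gained(self, strand):
        gene, ref, cds = _toy_gene(n_codons=300, strand=strand)
        variants = _codon_to_taa_variants(gene, ref, cds, 99)
        call = classify_lof("S", gene, ref, variants)
        assert call.lof_class == "stop_gained"
        assert call.stop_fraction == pytest.approx(100 / 300)

    def test_start_codon_disruption(self):
        gene, ref, _ = _toy_gene()
        pos = 50 + 1  # A of ATG, 1-based genomic position 51
        call = classify_lof("S", gene, ref, [(pos, "A", "C")])
        assert call.lof_class == "start_lost"

    def test_heterozygous_variants_are_not_applied(self):
        gene, ref, _ = _toy_gene()
        pos0 = 50 + 28
        ref_str = ref["chr01"][pos0 : pos0 + 2]
        site = VariantSite(
            "chr01", pos0 + 1, ref_str, ref_str[0], 99,
            {"S": SampleCall(HET, 30, (15, 15), 60.0)},
        )
        calls = classify_cohort_lof([site], [gene], ref, ["S"])
        assert calls[0].lof_class == "none"

    def test_low_depth_calls_are_not_applied(self):
        gene, ref, _ = _toy_gene()
        pos0 = 50 + 28
        ref_str = ref["chr01"][pos0 : pos0 + 2]
        site = VariantSite(
            "chr01", pos0 + 1, ref_str, ref_str[0], 99,
            {"S": SampleCall(HOM_ALT, 5, (0, 5), 60.0)},
        )
        calls = classify_cohort_lof([site], [gene], ref, ["S"], min_depth=10)
        assert calls[0].lof_class == "none"


def _codon_to_taa_variants(gene, ref, cds, codon_i):
    """SNP variants turning CDS codon ``codon_i`` (0-based) into TAA."""
    variants = []
    start, end = gene.cds_intervals[0]
    for k, base in enumerate("TAA"):
        coding_off = 3 * codon_i + k
        if cds[coding_off] == base:
            continue
        if gene.strand == "+":
            g0 = start + coding_off
            alt = base
        else:
            g0 = end - 1 - coding_off
            alt = str(Seq(base).reverse_complement())
        variants.append((g0 + 1, ref[gene.chrom][g0], alt))
    assert variants, "codon already a stop"
    return variants


class TestCompensationProperty:
    def test_indel_pairs_exhaustively_match_translate_oracle(self):
        """For insertion pairs of lengths l1, l2 <= 3 with no stop created
        between them, LOF holds iff (l1 + l2) % 3 != 0 -- checked against a
        direct reconstruct-and-translate oracle (Biopython)."""
        gene, ref, cds = _toy_gene(n_codons=100, seed=4)
        start = gene.cds_intervals[0][0]
        i1, i2 = 30, 60  # insert after these CDS offsets
        for l1 in (1, 2, 3):
            for l2 in (1, 2, 3):
                ins1, ins2 = "C" * l1, "C" * l2
                mutated = (
                    cds[: i1 + 1] + ins1 + cds[i1 + 1 : i2 + 1] + ins2 + cds[i2 + 1 :]
                )
                protein = str(Seq(mutated[: len(mutated) - len(mutated) % 3]).translate())
                first_stop = protein.find("*")
                terminal = len(mutated) // 3 - 1
                if 0 <= first_stop < terminal and first_stop >= (i1 + 1) // 3:
                    has_stop_between = first_stop < (i2 + 1 + l1) // 3
                    if has_stop_between:
                        continue  # premise of the property not met
                expected_lof = (l1 + l2) % 3 != 0
                variants = [
                    (start + i1 + 1, cds[i1], cds[i1] + ins1),
                    (start + i2 + 1, cds[i2], cds[i2] + ins2),
                ]
                call = classify_lof("S", gene, ref, variants)
                oracle_lof = first_stop != terminal if first_stop >= 0 else True
                assert call.is_lof == expected_lof == oracle_lof, (l1, l2)


class TestLofMatrix:
    def test_no_calls_all_zero(self):
        m = build_lof_matrix([], ["g1", "g2"], ["s1", "s2"])
        assert (m.values == 0).all()

    def test_single_call_single_one(self):
        calls = [ConsequenceCall("s1", "g2", "frameshift")]
        m = build_lof_matrix(calls, ["g1", "g2"], ["s1", "s2"])
        assert m.values.sum() == 1
        assert m.loc["g2", "s1"] == 1

    def test_planted_truth_recovered_exactly(self, small_cohort):
        import copy

        cohort = copy.deepcopy(small_cohort)
        genes = cohort.genes["gene_id"].tolist()
        spec = [
            ("A_01", genes[0], "frameshift"),
            ("A_02", genes[1], "stop_gained"),
            ("A_03", genes[2], "start_lost"),
            ("A_04", genes[3], "compensated_pair"),
            ("B_01", genes[4], "late_stop"),
        ]
        synthetic.plant_lof_variants(cohort, spec)
        models = [GeneModel.from_annotation(r) for _, r in cohort.genes.iterrows()]
        calls = classify_cohort_lof(
            cohort.variants, models, cohort.reference, cohort.strains
        )
        matrix = build_lof_matrix(calls, genes, cohort.strains)
        expected = pd.DataFrame(0, index=genes, columns=cohort.strains, dtype=np.int8)
        for _, row in cohort.truth.lof.iterrows():
            if row["expected_lof"]:
                expected.loc[row["gene"], row["strain"]] = 1
        assert matrix.equals(expected)


def _block_matrix(rng, n_clusters=3, genes_per=12, n_strains=60, flip=0.02):
    centers = rng.integers(0, 2, size=(n_clusters, n_strains))
    rows, labels = [], []
    for c in range(n_clusters):
        for g in range(genes_per):
            row = centers[c].copy()
            flips = rng.random(n_strains) < flip
            row[flips] = 1 - row[flips]
            rows.append(row)
            labels.append(c)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(labels)


class TestClustering:
    def test_k_equals_n_genes_zero_inertia(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 8)), index=list("abcdef"))
        res = kmeans_cluster(m, k=6, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert res.assignments.nunique() <= 6

    def test_two_orthogonal_blocks_recovered(self):
        top = [[1, 1, 1, 1, 0, 0, 0, 0]] * 5
        bottom = [[0, 0, 0, 0, 1, 1, 1, 1]] * 5
        m = pd.DataFrame(top + bottom, index=[f"g{i}" for i in range(10)])
        res = kmeans_cluster(m, k=2, seed=0)
        first = set(res.assignments.iloc[:5])
        second = set(res.assignments.iloc[5:])
        assert len(first) == len(second) == 1
        assert first != second

    def test_gene_permutation_preserves_partition(self, rng):
        m, _ = _block_matrix(rng)
        perm = rng.permutation(len(m))
        res_a = kmeans_cluster(m, 3, seed=1)
        res_b = kmeans_cluster(m.iloc[perm], 3, seed=1)
        # compare partitions as frozensets of gene-id groups
        part = lambda r: frozenset(
            frozenset(r.assignments.index[r.assignments == c])
            for c in r.assignments.unique()
        )
        assert part(res_a) == part(res_b)

    def test_inertia_non_increasing_in_k(self, rng):
        m, _ = _block_matrix(rng, flip=0.2)
        inertias = [kmeans_cluster(m, k, seed=0).inertia for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_gap_statistic_identical_rows_choose_one(self):
        m = pd.DataFrame([[1, 0, 1, 0]] * 8, index=[f"g{i}" for i in range(8)])
        res = select_k_gap(m, k_max=4, b_reference=10, seed=0)
        assert res.k == 1

    def test_gap_statistic_recovers_three_planted_clusters(self, rng):
        m, truth = _block_matrix(rng, n_clusters=3, flip=0.02)
        res = select_k_gap(m, k_max=6, b_reference=20, seed=0)
        assert res.k == 3
        # the partition must match the planted blocks
        for c in range(3):
            block = res.assignments.iloc[c * 12 : (c + 1) * 12]
            assert block.nunique() == 1

    def test_fixed_k_override_for_reporting(self, rng):
        m, _ = _block_matrix(rng, n_clusters=4, genes_per=5)
        res = kmeans_cluster(m, k=16, seed=0)
        assert res.k == 16
        assert len(res.assignments) == 20
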