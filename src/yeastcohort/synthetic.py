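"""Synthetic multi-clade yeast cohort with full truth tables.

The generator emulates the statistical structure of a short-read wine-yeast
cohort mapped against a reference: several strain groups radiating from one
ancestor (star phylogeny, group-specific branch lengths), diploid or triploid
strains, per-strain heterozygosity targets, read-depth and allele-depth draws
tied to allelic copy ratio, per-ORF depth proportional to copy number, binned
genome coverage, and accessory (non-reference) ORF content including a
horizontally transferred multi-gene cluster.  Every planted event is recorded
in :class:`TruthTables` so downstream modules can be scored for exact
recovery.

Background mutations are placed outside CDS intervals so that coding-impact
truth is exhaustively known: the only high-impact variants in a cohort are
the ones planted through :func:`plant_lof_variants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from yeastcohort.variant_io import HET, HOM_ALT, HOM_REF, SampleCall, VariantSite

# Depth noise is negative binomial with variance = 2 x mean at base
# resolution; region-level depth aggregates the per-base counts, so ORF and
# bin depth estimates tighten with region length.

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


class ConfigError(ValueError):
    """Raised for impossible cohort configurations."""


class PlantingError(ValueError):
    """Raised when a requested event cannot be planted."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GroupSpec:
    """One strain group of the cohort.

    ``heterozygosity`` is the target fraction of a strain's variant calls
    that are heterozygous; ``divergence`` is the per-site rate of homozygous
    differences from the ancestor (reference).
    """

    label: str
    n_strains: int
    ploidy: int = 2
    heterozygosity: float = 0.0
    divergence: float = 0.005

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")
        if self.ploidy not in (2, 3):
            raise ConfigError("ploidy must be 2 or 3")
        if not 0.0 <= self.heterozygosity < 1.0:
            raise ConfigError("heterozygosity must be in [0, 1)")
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigError("divergence must be in [0, 1]")


# Default groups mirror the study design: four groups of wine and oak strains
# with median heterozygosity 3.8% (BCWE), 0% (PWCW), 13% (RCW) and 0% (RNAO),
# and per-site divergence matched to the reported median SNP densities
# (~52.5-71.8 k SNPs over the 12 Mb genome).  Group sizes are scaled down
# (about 1/4 of 38/34/10/20) to keep a full simulation at desk scale.
_DEFAULT_GROUPS = (
    GroupSpec("BCWE", 10, 2, 0.038, 0.0044),
    GroupSpec("PWCW", 9, 2, 0.0, 0.0052),
    GroupSpec("RCW", 4, 2, 0.13, 0.0044),
    GroupSpec("RNAO", 6, 2, 0.0, 0.0060),
)


@dataclass(frozen=True)
class CohortConfig:
    """Scale and composition of a synthetic cohort.

    Genome defaults (4 chromosomes x 200 kb, 100 single-CDS genes) are large
    enough for 50 kb / 25 kb heterozygosity windows and 10 kb coverage bins
    while keeping simulation at seconds scale.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 200_000
    n_genes: int = 100
    group_specs: tuple[GroupSpec, ...] = _DEFAULT_GROUPS
    depth_mean: float = 100.0
    shared_fraction: float = 0.5  # fraction of divergence fixed group-wide
    indel_fraction: float = 0.1  # fraction of background variants that are indels
    bin_size_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1 or self.n_genes < 1:
            raise ConfigError("all counts must be >= 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigError("shared_fraction must be in [0, 1]")
        if not self.group_specs:
            raise ConfigError("at least one group required")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class TruthTables:
    """Planted ground truth, one DataFrame per event family."""

    ploidy: pd.DataFrame
    heterozygosity: pd.DataFrame
    lof: pd.DataFrame
    cn_events: pd.DataFrame
    aneuploidies: pd.DataFrame
    accessory: pd.DataFrame
    introgression: pd.DataFrame

    @staticmethod
    def empty(strains: pd.DataFrame | None = None) -> "TruthTables":
        return TruthTables(
            ploidy=pd.DataFrame(columns=["strain", "ploidy"]),
            heterozygosity=pd.DataFrame(columns=["strain", "target_het", "n_het", "n_hom"]),
            lof=pd.DataFrame(columns=["strain", "gene", "lof_class", "expected_lof"]),
            cn_events=pd.DataFrame(columns=["strain", "gene", "cn"]),
            aneuploidies=pd.DataFrame(columns=["strain", "chrom", "delta"]),
            accessory=pd.DataFrame(columns=["strain", "cluster", "state"]),
            introgression=pd.DataFrame(columns=["donor", "recipient", "chrom", "pos"]),
        )


@dataclass
class SyntheticCohort:
    config: CohortConfig
    reference: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end (0-based half-open), strand
    strains: list[str]
    groups: dict[str, str]  # strain -> group label
    ploidy: dict[str, int]
    variants: list[VariantSite]
    orf_depth: pd.DataFrame  # strains x genes, length-normalized depth
    coverage_bins: pd.DataFrame  # strain, chrom, start, end, depth
    orf_seqs: dict[str, dict[str, str]]  # strain -> {orf_id: sequence}
    accessory_reps: dict[str, str]
    truth: TruthTables
    rng: np.random.Generator
    group_shared_sites: dict[str, list[int]] = field(default_factory=dict)

    def gene_row(self, gene_id: str) -> pd.Series:
        rows = self.genes[self.genes["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return rows.iloc[0]

    def cds_sequence(self, gene_id: str) -> str:
        g = self.gene_row(gene_id)
        seq = self.reference[g["chrom"]][g["start"] : g["end"]]
        return revcomp(seq) if g["strand"] == "-" else seq

    def sort_variants(self) -> None:
        self.variants.sort(key=lambda s: (s.chrom, s.pos, s.alt))


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return codons


def _make_gene_sequence(rng: np.random.Generator, n_codons: int) -> tuple[str, int, int]:
    """Build a CDS of ``n_codons`` codons.

    Two sentinel TAT codons (one substitution away from a TAA stop) are
    embedded at ~30% and at the second-to-last codon so that both early and
    late premature stops can always be planted.
    """
    codons = ["ATG"] + _random_codons(rng, n_codons - 2) + ["TAA"]
    early = max(2, int(0.3 * n_codons))  # 0-based codon index, within first 98%
    late = n_codons - 2  # beyond 98% for genes of >= 100 codons
    codons[early] = "TAT"
    codons[late] = "TAT"
    return "".join(codons), early, late


def _build_genome(config: CohortConfig, rng: np.random.Generator):
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    slot = config.chrom_length_bp // (per_chrom + 1)
    max_gene_bp = 1500
    if slot < max_gene_bp + 400:
        raise ConfigError(
            f"{config.n_genes} genes do not fit in "
            f"{config.n_chromosomes} x {config.chrom_length_bp} bp"
        )
    reference: dict[str, str] = {}
    gene_rows = []
    gene_idx = 0
    for ci, chrom in enumerate(config.chrom_names):
        seq = rng.choice(_BASES, size=config.chrom_length_bp)
        n_here = min(per_chrom, config.n_genes - gene_idx)
        for gi in range(n_here):
            n_codons = int(rng.integers(100, 501))
            cds, early, late = _make_gene_sequence(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = cds if strand == "+" else revcomp(cds)
            start = (gi + 1) * slot
            end = start + len(cds)
            seq[start:end] = list(genomic)
            gene_rows.append(
                {
                    "gene_id": f"G{gene_idx + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "length": len(cds),
                    "early_stop_codon": early,
                    "late_stop_codon": late,
                }
            )
            gene_idx += 1
        reference[chrom] = "".join(seq)
    genes = pd.DataFrame(gene_rows)
    return reference, genes


def _allowed_positions(config: CohortConfig, genes: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    out = []
    for chrom in config.chrom_names:
        mask = np.ones(config.chrom_length_bp, dtype=bool)
        mask[:10] = False
        mask[-10:] = False
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            mask[max(0, g["start"] - 5) : g["end"] + 5] = False
        out.append((chrom, np.flatnonzero(mask)))
    return out


def _draw_depths(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    """Overdispersed read-depth draws (negative binomial, variance = 2 x mean)."""
    return rng.negative_binomial(mean, 0.5, size=size)


def _mutate_base(rng: np.random.Generator, ref: str) -> str:
    if rng.random() < 2.0 / 3.0:  # transition:transversion 2:1
        return _TRANSITION[ref]
    choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return choices[int(rng.integers(0, 2))]


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the cohort: reference, annotation, variants, depth tables.

    Deterministic for a fixed ``config.seed``.  Per-site allele depths at
    heterozygous sites are binomial with success probability equal to the
    strain's allelic copy ratio (1/2 diploid; 1/3 or 2/3 triploid).
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)
    reference, genes = _build_genome(config, rng)

    strains: list[str] = []
    groups: dict[str, str] = {}
    ploidy: dict[str, int] = {}
    for spec in config.group_specs:
        for i in range(spec.n_strains):
            name = f"{spec.label}_{i + 1:02d}"
            strains.append(name)
            groups[name] = spec.label
            ploidy[name] = spec.ploidy

    # one shuffled global pool of intergenic positions; consumed sequentially
    pools = _allowed_positions(config, genes)
    pool_pairs = [(chrom, int(p)) for chrom, arr in pools for p in arr]
    order = rng.permutation(len(pool_pairs))
    cursor = 0

    def take_positions(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        if cursor + n > len(pool_pairs):
            raise ConfigError("genome too small for requested divergence")
        picked = [pool_pairs[order[i]] for i in range(cursor, cursor + n)]
        cursor += n
        return picked

    # site registry: (chrom, pos0) -> record
    records: dict[tuple[str, int], dict] = {}

    def make_snp_record(chrom: str, pos0: int) -> dict:
        ref = reference[chrom][pos0]
        rec = {"chrom": chrom, "pos0": pos0, "ref": ref, "alt": _mutate_base(rng, ref), "gts": {}}
        records[(chrom, pos0)] = rec
        return rec

    def make_indel_record(chrom: str, pos0: int) -> dict:
        seq = reference[chrom]
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5 and pos0 + length + 1 < len(seq):  # deletion
            ref = seq[pos0 : pos0 + length + 1]
            alt = seq[pos0]
        else:  # insertion
            ref = seq[pos0]
            alt = ref + "".join(rng.choice(_BASES, size=length))
        rec = {"chrom": chrom, "pos0": pos0, "ref": ref, "alt": alt, "gts": {}}
        records[(chrom, pos0)] = rec
        return rec

    def new_record(chrom: str, pos0: int) -> dict:
        if rng.random() < config.indel_fraction:
            return make_indel_record(chrom, pos0)
        return make_snp_record(chrom, pos0)

    genome_len = config.genome_length
    group_shared_sites: dict[str, list[int]] = {}
    het_truth_rows = []
    shared_keys: dict[str, list[tuple[str, int]]] = {}
    for spec in config.group_specs:
        n_shared = int(round(config.shared_fraction * spec.divergence * genome_len))
        keys = []
        for chrom, pos0 in take_positions(n_shared):
            rec = new_record(chrom, pos0)
            for s in strains:
                if groups[s] == spec.label:
                    rec["gts"][s] = (HOM_ALT, ploidy[s])
            keys.append((chrom, pos0))
        shared_keys[spec.label] = keys

        n_private = int(round((1.0 - config.shared_fraction) * spec.divergence * genome_len))
        h = spec.heterozygosity
        n_hom_total = n_shared + n_private
        n_het = int(round(h / (1.0 - h) * n_hom_total)) if h > 0 else 0
        for s in strains:
            if groups[s] != spec.label:
                continue
            for chrom, pos0 in take_positions(n_private):
                rec = new_record(chrom, pos0)
                rec["gts"][s] = (HOM_ALT, ploidy[s])
            for chrom, pos0 in take_positions(n_het):
                rec = make_snp_record(chrom, pos0)  # het sites kept as SNPs
                copies = 1 if ploidy[s] == 2 else int(rng.integers(1, 3))
                rec["gts"][s] = (HET, copies)
            het_truth_rows.append(
                {"strain": s, "target_het": h, "n_het": n_het, "n_hom": n_hom_total}
            )

    # materialize VariantSite list, sorted, with depth/AD/GQ draws
    variants: list[VariantSite] = []
    n_strains = len(strains)
    for (chrom, pos0), rec in sorted(records.items()):
        depths = _draw_depths(rng, config.depth_mean, n_strains)
        calls = {}
        for j, s in enumerate(strains):
            d = int(depths[j])
            code, copies = rec["gts"].get(s, (HOM_REF, 0))
            if code == HOM_REF:
                ad = (d, 0)
            elif code == HOM_ALT:
                ad = (0, d)
            else:
                alt_reads = int(rng.binomial(d, copies / ploidy[s])) if d else 0
                ad = (d - alt_reads, alt_reads)
            calls[s] = SampleCall(genotype=code, depth=d, allele_depths=ad, genotype_quality=60.0)
        variants.append(
            VariantSite(chrom=chrom, pos=pos0 + 1, ref=rec["ref"], alt=rec["alt"], qual=100.0, calls=calls)
        )

    # index shared sites after sorting, for introgression planting
    key_to_idx = {(v.chrom, v.pos): i for i, v in enumerate(variants)}
    for label, keys in shared_keys.items():
        group_shared_sites[label] = [key_to_idx[(c, p + 1)] for c, p in keys]

    # per-ORF length-normalized depth: aggregated per-base counts are
    # negative binomial with mean depth * L, so longer ORFs estimate tighter
    lengths = genes["length"].to_numpy()
    depth_mat = np.empty((n_strains, len(genes)))
    for i in range(n_strains):
        counts = _draw_depths(rng, config.depth_mean * lengths, len(genes))
        depth_mat[i] = counts / lengths
    orf_depth = pd.DataFrame(depth_mat, index=strains, columns=genes["gene_id"])

    bin_rows = []
    for s in strains:
        for chrom in config.chrom_names:
            for start in range(0, config.chrom_length_bp, config.bin_size_bp):
                end = min(start + config.bin_size_bp, config.chrom_length_bp)
                counts = int(_draw_depths(rng, config.depth_mean * (end - start), 1)[0])
                bin_rows.append(
                    {"strain": s, "chrom": chrom, "start": start, "end": end,
                     "depth": counts / (end - start)}
                )
    coverage_bins = pd.DataFrame(bin_rows)

    truth = TruthTables.empty()
    truth.ploidy = pd.DataFrame({"strain": strains, "ploidy": [ploidy[s] for s in strains]})
    truth.heterozygosity = pd.DataFrame(het_truth_rows)

    return SyntheticCohort(
        config=config,
        reference=reference,
        genes=genes,
        strains=strains,
        groups=groups,
        ploidy=ploidy,
        variants=variants,
        orf_depth=orf_depth,
        coverage_bins=coverage_bins,
        orf_seqs={s: {} for s in strains},
        accessory_reps={},
        truth=truth,
        rng=rng,
        group_shared_sites=group_shared_sites,
    )


# ---------------------------------------------------------------------------
# planting operations
# ---------------------------------------------------------------------------

LOF_CLASSES = ("frameshift", "stop_gained", "start_lost", "compensated_pair", "late_stop")
_EXPECTED_LOF = {"frameshift": True, "stop_gained": True, "start_lost": True,
                 "compensated_pair": False, "late_stop": False}


def _coding_to_genomic(gene: pd.Series, i: int) -> int:
    """0-based genomic index of coding offset ``i``."""
    if gene["strand"] == "+":
        return int(gene["start"]) + i
    return int(gene["end"]) - 1 - i


def _append_planted_site(
    cohort: SyntheticCohort, strain: str, chrom: str, pos0: int, ref: str, alt: str
) -> None:
    depths = _draw_depths(cohort.rng, cohort.config.depth_mean, len(cohort.strains))
    calls = {}
    for j, s in enumerate(cohort.strains):
        d = int(depths[j])
        if s == strain:
            calls[s] = SampleCall(HOM_ALT, d, (0, d), 60.0)
        else:
            calls[s] = SampleCall(HOM_REF, d, (d, 0), 60.0)
    cohort.variants.append(VariantSite(chrom, pos0 + 1, ref, alt, 100.0, calls))


def _plant_coding_snp(cohort: SyntheticCohort, strain: str, gene: pd.Series, coding_i: int, new_base: str) -> None:
    g = _coding_to_genomic(gene, coding_i)
    chrom = gene["chrom"]
    ref = cohort.reference[chrom][g]
    alt = new_base if gene["strand"] == "+" else revcomp(new_base)
    if ref == alt:
        raise PlantingError("planted base equals reference")
    _append_planted_site(cohort, strain, chrom, g, ref, alt)


def _plant_coding_insertion(cohort: SyntheticCohort, strain: str, gene: pd.Series, coding_i: int, coding_bases: str) -> None:
    """Insert ``coding_bases`` (coding orientation) after coding offset ``coding_i``."""
    chrom = gene["chrom"]
    if gene["strand"] == "+":
        anchor = _coding_to_genomic(gene, coding_i)
        inserted = coding_bases
    else:
        anchor = _coding_to_genomic(gene, coding_i + 1)
        inserted = revcomp(coding_bases)
    ref = cohort.reference[chrom][anchor]
    _append_planted_site(cohort, strain, chrom, anchor, ref, ref + inserted)


def _plant_genomic_deletion(cohort: SyntheticCohort, strain: str, chrom: str, pos0: int, length: int) -> None:
    seq = cohort.reference[chrom]
    ref = seq[pos0 : pos0 + length + 1]
    _append_planted_site(cohort, strain, chrom, pos0, ref, seq[pos0])


def _translate(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def _first_stop_codon(seq: str) -> int | None:
    for i, codon in enumerate(_translate(seq)):
        if codon in _STOPS:
            return i
    return None


def plant_lof_variants(
    cohort: SyntheticCohort, spec: list[tuple[str, str, str]]
) -> SyntheticCohort:
    """Plant homozygous coding variants of the requested classes.

    Classes: ``frameshift`` (1 bp deletion), ``stop_gained`` (premature stop
    within the first 98% of codons), ``start_lost`` (ATG disrupted),
    ``compensated_pair`` (two insertions whose lengths sum to a multiple of 3
    with no stop codon created between them -- must NOT be called LOF
    downstream) and ``late_stop`` (stop beyond 98% of CDS -- also not LOF).
    """
    lof_rows = []
    for strain, gene_id, lof_class in spec:
        if strain not in cohort.strains:
            raise PlantingError(f"unknown strain {strain!r}")
        if lof_class not in LOF_CLASSES:
            raise PlantingError(f"unknown LOF class {lof_class!r}")
        gene = cohort.gene_row(gene_id)
        n_codons = int(gene["length"]) // 3
        if n_codons < 100:
            raise PlantingError(f"gene {gene_id} too short for planting")
        if lof_class == "start_lost":
            _plant_coding_snp(cohort, strain, gene, 0, "C")  # ATG -> CTG
        elif lof_class == "stop_gained":
            codon = int(gene["early_stop_codon"])  # sentinel TAT codon
            _plant_coding_snp(cohort, strain, gene, 3 * codon + 2, "A")  # TAT -> TAA
        elif lof_class == "late_stop":
            codon = int(gene["late_stop_codon"])
            _plant_coding_snp(cohort, strain, gene, 3 * codon + 2, "A")
        elif lof_class == "frameshift":
            g = _coding_to_genomic(gene, 30) if gene["strand"] == "+" else int(gene["start"]) + 30
            _plant_genomic_deletion(cohort, strain, gene["chrom"], g - 1, 1)
        elif lof_class == "compensated_pair":
            _plant_compensated_pair(cohort, strain, gene)
        lof_rows.append(
            {"strain": strain, "gene": gene_id, "lof_class": lof_class,
             "expected_lof": _EXPECTED_LOF[lof_class]}
        )
    cohort.sort_variants()
    cohort.truth.lof = pd.concat(
        [cohort.truth.lof, pd.DataFrame(lof_rows)], ignore_index=True
    )
    return cohort


def _plant_compensated_pair(cohort: SyntheticCohort, strain: str, gene: pd.Series) -> None:
    """+1 bp and +2 bp insertions a few bases apart restoring frame, with no
    stop codon created between them.  The +1-shifted frame between the
    insertions can expose stops already present in the sequence, so both the
    anchor position and the inserted bases are searched."""
    cds = cohort.cds_sequence(gene["gene_id"])
    for i1 in range(29, 90, 3):  # after coding offset i1, within codons 10-30
        for gap in (9, 12, 15):
            i2 = i1 + gap
            for b1 in "CAGT":
                for b2a in "CAGT":
                    for b2b in "CAGT":
                        mutated = (
                            cds[: i1 + 1] + b1 + cds[i1 + 1 : i2 + 1]
                            + b2a + b2b + cds[i2 + 1 :]
                        )
                        stop = _first_stop_codon(mutated)
                        # frame restored after i2: acceptable iff the first
                        # stop is the (shifted) terminal stop
                        if stop is not None and stop == len(mutated) // 3 - 1:
                            _plant_coding_insertion(cohort, strain, gene, i2, b2a + b2b)
                            _plant_coding_insertion(cohort, strain, gene, i1, b1)
                            return
    raise PlantingError(f"no stop-free compensated pair found in {gene['gene_id']}")


def plant_cn_events(
    cohort: SyntheticCohort, spec: list[tuple[str, str, int]], noise_floor_frac: float = 0.002
) -> SyntheticCohort:
    """Rescale per-ORF depth and overlapping coverage bins to planted CN.

    Per-ORF depth is redrawn with mean ``depth_mean * CN / ploidy``; CN = 0
    leaves only a mapping-noise floor.  Coverage bins overlapping the gene
    span are rescaled in proportion to their overlap.
    """
    rows = []
    for strain, gene_id, cn in spec:
        if strain not in cohort.strains:
            raise PlantingError(f"unknown strain {strain!r}")
        if cn < 0:
            raise PlantingError("CN must be >= 0")
        gene = cohort.gene_row(gene_id)
        p = cohort.ploidy[strain]
        length = int(gene["length"])
        factor = cn / p if cn > 0 else noise_floor_frac
        mean_counts = cohort.config.depth_mean * factor * length
        counts = int(_draw_depths(cohort.rng, mean_counts, 1)[0]) if mean_counts > 0 else 0
        cohort.orf_depth.loc[strain, gene_id] = counts / length

        bins = cohort.coverage_bins
        sel = (
            (bins["strain"] == strain)
            & (bins["chrom"] == gene["chrom"])
            & (bins["start"] < gene["end"])
            & (bins["end"] > gene["start"])
        )
        for idx in bins.index[sel]:
            b = bins.loc[idx]
            overlap = min(b["end"], gene["end"]) - max(b["start"], gene["start"])
            frac = overlap / (b["end"] - b["start"])
            bins.loc[idx, "depth"] = b["depth"] * (1.0 + (cn / p - 1.0) * frac)
        rows.append({"strain": strain, "gene": gene_id, "cn": cn})
    cohort.truth.cn_events = pd.concat(
        [cohort.truth.cn_events, pd.DataFrame(rows)], ignore_index=True
    )
    return cohort


def plant_aneuploidy(
    cohort: SyntheticCohort, spec: list[tuple[str, str, int]]
) -> SyntheticCohort:
    """Scale a whole chromosome's coverage bins by (ploidy + delta) / ploidy."""
    rows = []
    for strain, chrom, delta in spec:
        if delta == 0:
            raise PlantingError("aneuploidy delta must be nonzero")
        if chrom not in cohort.reference:
            raise PlantingError(f"unknown chromosome {chrom!r}")
        p = cohort.ploidy[strain]
        factor = (p + delta) / p
        sel = (cohort.coverage_bins["strain"] == strain) & (
            cohort.coverage_bins["chrom"] == chrom
        )
        cohort.coverage_bins.loc[sel, "depth"] *= factor
        on_chrom = cohort.genes.loc[cohort.genes["chrom"] == chrom, "gene_id"]
        cohort.orf_depth.loc[strain, on_chrom] *= factor
        rows.append({"strain": strain, "chrom": chrom, "delta": delta})
    cohort.truth.aneuploidies = pd.concat(
        [cohort.truth.aneuploidies, pd.DataFrame(rows)], ignore_index=True
    )
    return cohort


def plant_accessory_content(
    cohort: SyntheticCohort,
    n_clusters: int = 10,
    hgt_cluster_size: int = 5,
    carrier_fraction: dict[str, float] | float = 0.5,
    partial_fraction: float = 0.15,
    substitution_rate: float = 0.003,
) -> SyntheticCohort:
    """Plant accessory (non-reference) ORF content with known truth.

    The first ``hgt_cluster_size`` clusters form one linked, horizontally
    transferred multi-gene cluster: its genes co-occur full-length in every
    carrier strain (carrier status drawn per group from ``carrier_fraction``).
    The remaining clusters are scattered independently; a carried copy is
    truncated to 60% of the representative length with probability
    ``partial_fraction``.
    """
    if n_clusters < 1:
        raise ConfigError("n_clusters must be >= 1")
    if hgt_cluster_size > n_clusters:
        raise ConfigError("hgt_cluster_size cannot exceed n_clusters")
    rng = cohort.rng
    if isinstance(carrier_fraction, (int, float)):
        carrier_fraction = {g.label: float(carrier_fraction) for g in cohort.config.group_specs}

    cluster_ids = [f"WC{i + 1}" for i in range(hgt_cluster_size)] + [
        f"ACC{i + 1}" for i in range(n_clusters - hgt_cluster_size)
    ]
    for cid in cluster_ids:
        n_codons = int(rng.integers(100, 401))
        seq = "ATG" + "".join(_random_codons(rng, n_codons - 2)) + "TAA"
        cohort.accessory_reps[cid] = seq

    acc_carrier_prob = {
        cid: float(rng.uniform(0.2, 0.8)) for cid in cluster_ids[hgt_cluster_size:]
    }
    rows = []
    for s in cohort.strains:
        frac = carrier_fraction.get(cohort.groups[s], 0.0)
        wc_carrier = rng.random() < frac
        for cid in cluster_ids:
            rep = cohort.accessory_reps[cid]
            if cid.startswith("WC"):
                carried, partial = wc_carrier, False
            else:
                carried = rng.random() < acc_carrier_prob[cid]
                partial = carried and rng.random() < partial_fraction
            if not carried:
                rows.append({"strain": s, "cluster": cid, "state": "absent"})
                continue
            if partial:
                seq = rep[: int(0.6 * len(rep))]
                state = "partial"
            else:
                seq = _mutate_sequence(rng, rep, substitution_rate)
                state = "full"
            cohort.orf_seqs[s][f"{s}|{cid}"] = seq
            rows.append({"strain": s, "cluster": cid, "state": state})
    cohort.truth.accessory = pd.concat(
        [cohort.truth.accessory, pd.DataFrame(rows)], ignore_index=True
    )
    return cohort


def _mutate_sequence(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    # substitutions avoid the start codon and keep the terminal stop intact
    n = rng.binomial(max(len(seq) - 6, 0), rate)
    positions = rng.choice(np.arange(3, len(seq) - 3), size=n, replace=False)
    for p in positions:
        arr[p] = _mutate_base(rng, arr[p]) if arr[p] in "ACGT" else arr[p]
    return "".join(arr)


def plant_introgression(
    cohort: SyntheticCohort, donor_group: str, recipient_group: str, fraction: float = 0.05
) -> SyntheticCohort:
    """Copy a fraction of the donor group's fixed alleles into every
    recipient strain (homozygous), emulating gene flow."""
    if donor_group not in cohort.group_shared_sites:
        raise PlantingError(f"unknown group {donor_group!r}")
    idx = cohort.group_shared_sites[donor_group]
    n = int(round(fraction * len(idx)))
    chosen = sorted(cohort.rng.choice(idx, size=n, replace=False))
    recipients = [s for s in cohort.strains if cohort.groups[s] == recipient_group]
    rows = []
    for i in chosen:
        site = cohort.variants[i]
        for s in recipients:
            d = site.calls[s].depth or 0
            site.calls[s] = SampleCall(HOM_ALT, d, (0, d), 60.0)
        rows.append({"donor": donor_group, "recipient": recipient_group,
                     "chrom": site.chrom, "pos": site.pos})
    cohort.truth.introgression = pd.concat(
        [cohort.truth.introgression, pd.DataFrame(rows)], ignore_index=True
    )
    return cohort


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort as plain-text standard formats.

    reference.fasta, genes.tsv (1-based inclusive CDS intervals),
    variants.vcf, orf_depth.tsv, coverage_bins.tsv (0-based half-open),
    groups.tsv, orfs/<strain>.fasta and truth/*.tsv.
    """
    from pathlib import Path

    from yeastcohort.variant_io import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reference.fasta", "w") as fh:
        for chrom, seq in cohort.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff = cohort.genes.copy()
    gff["start"] = gff["start"] + 1  # 1-based inclusive on I/O
    gff.to_csv(out / "genes.tsv", sep="\t", index=False)
    contigs = {c: len(s) for c, s in cohort.reference.items()}
    write_vcf(cohort.variants, str(out / "variants.vcf"), cohort.strains, contigs)
    cohort.orf_depth.to_csv(out / "orf_depth.tsv", sep="\t", index_label="strain")
    cohort.coverage_bins.to_csv(out / "coverage_bins.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"strain": cohort.strains, "group": [cohort.groups[s] for s in cohort.strains]}
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    orf_dir = out / "orfs"
    orf_dir.mkdir(exist_ok=True)
    for s in cohort.strains:
        with open(orf_dir / f"{s}.fasta", "w") as fh:
            for oid, seq in cohort.orf_seqs[s].items():
                fh.write(f">{oid}\n{seq}\n")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name in ("ploidy", "heterozygosity", "lof", "cn_events", "aneuploidies",
                 "accessory", "introgression"):
        getattr(cohort.truth, name).to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)
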