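"""Multi-sample variant I/O, site/sample filtering and LD pruning.

Variant records are held as lightweight :class:`VariantSite` objects with
per-strain :class:`SampleCall` entries (genotype code, depth, allele depths,
genotype quality).  Reading goes through :mod:`pysam`; multiallelic records
are split into biallelic records on input.  Filtering implements the
vcftools-style site filters (missingness, indel removal, minor allele count,
site quality) with an optional per-sample depth/quality sub-filter applied
first, and a plink-style greedy LD pruner on genotype-dosage r².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class SampleCall:
    """One strain's call at one site.

    ``genotype`` uses dosage codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    Triploid genotypes are coded by rounding allele dosage into {0, 1, 2}.
    """

    genotype: int = MISSING
    depth: int | None = None
    allele_depths: tuple[int, int] | None = None
    genotype_quality: float | None = None

    @property
    def is_missing(self) -> bool:
        return self.genotype == MISSING

    @property
    def allelic_balance(self) -> float | None:
        """min(ref, alt) read depth over total; None without allele depths."""
        if self.allele_depths is None:
            return None
        ref_d, alt_d = self.allele_depths
        total = ref_d + alt_d
        if total == 0:
            return None
        return min(ref_d, alt_d) / total


@dataclass
class VariantSite:
    """A biallelic variant record with per-strain calls."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def allele_counts(self) -> tuple[int, int]:
        """(ref, alt) allele counts over non-missing diploid-coded genotypes."""
        ref_n = alt_n = 0
        for call in self.calls.values():
            if call.genotype == MISSING:
                continue
            alt_n += call.genotype
            ref_n += 2 - call.genotype
        return ref_n, alt_n

    def missing_fraction(self) -> float:
        if not self.calls:
            return 0.0
        n_missing = sum(1 for c in self.calls.values() if c.is_missing)
        return n_missing / len(self.calls)


@dataclass(frozen=True)
class FilterSpec:
    """Site- and sample-level filter thresholds.

    Defaults reproduce the study's phylogeny-arm filter
    (``--max-missing 1 --remove-indels --mac 3 --minQ 10``); the per-sample
    depth/quality 10 sub-filter belongs to the annotation arm and is off by
    default.  Sample calls failing the sub-filter are set to missing *before*
    site-level evaluation.
    """

    max_missing: float = 1.0
    remove_indels: bool = True
    mac: int = 3
    min_qual: float = 10.0
    min_sample_depth: int | None = None
    min_sample_quality: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.mac < 0 or self.min_qual < 0:
            raise ValueError("thresholds must be >= 0")


def _call_from_record(rec: pysam.VariantRecord, sample: str, alt_index: int) -> SampleCall:
    s = rec.samples[sample]
    gt = s.get("GT")
    if gt is None or any(a is None for a in gt):
        genotype = MISSING
    else:
        # dosage of this ALT allele; triploid dosage rounded into {0,1,2}
        k = alt_index + 1
        dosage = sum(1 for a in gt if a == k)
        if len(gt) != 2:
            dosage = int(round(2 * dosage / len(gt)))
        genotype = min(dosage, 2)
    depth = s.get("DP")
    ad = s.get("AD")
    allele_depths = None
    if ad is not None and ad[0] is not None and len(ad) > alt_index + 1:
        allele_depths = (int(ad[0]), int(ad[alt_index + 1]))
    gq = s.get("GQ")
    return SampleCall(
        genotype=genotype,
        depth=None if depth is None else int(depth),
        allele_depths=allele_depths,
        genotype_quality=None if gq is None else float(gq),
    )


def read_vcf(path: str) -> list[VariantSite]:
    """Read a VCF into biallelic :class:`VariantSite` records.

    Multiallelic records are split into one record per ALT allele (order
    preserved); each sample's genotype is re-coded as the dosage of that ALT.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts):
                if alt is None or alt in (".", "*"):
                    continue
                calls = {s: _call_from_record(rec, s, k) for s in samples}
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=0.0 if rec.qual is None else float(rec.qual),
                        calls=calls,
                    )
                )
    return sites


def write_vcf(
    sites: list[VariantSite],
    path: str,
    strains: list[str] | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write biallelic sites as VCF v4.2 with GT:DP:AD:GQ per sample."""
    if strains is None:
        strains = sorted({s for site in sites for s in site.calls})
    if contigs is None:
        contigs = {}
        for site in sites:
            contigs[site.chrom] = max(contigs.get(site.chrom, 0), site.pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=yeastcohort\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(strains)
            + "\n"
        )
        for site in sites:
            cols = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref,
                site.alt,
                f"{site.qual:g}",
                "PASS",
                ".",
                "GT:DP:AD:GQ",
            ]
            for strain in strains:
                call = site.calls.get(strain, SampleCall())
                gt = _GT_STRINGS[call.genotype]
                dp = "." if call.depth is None else str(call.depth)
                ad = (
                    "."
                    if call.allele_depths is None
                    else f"{call.allele_depths[0]},{call.allele_depths[1]}"
                )
                gq = (
                    "."
                    if call.genotype_quality is None
                    else str(int(round(call.genotype_quality)))
                )
                cols.append(f"{gt}:{dp}:{ad}:{gq}")
            fh.write("\t".join(cols) + "\n")


def _apply_sample_filter(site: VariantSite, spec: FilterSpec) -> VariantSite:
    changed = False
    new_calls = {}
    for strain, call in site.calls.items():
        drop = False
        if not call.is_missing:
            if spec.min_sample_depth is not None and (
                call.depth is None or call.depth < spec.min_sample_depth
            ):
                drop = True
            if spec.min_sample_quality is not None and (
                call.genotype_quality is None
                or call.genotype_quality < spec.min_sample_quality
            ):
                drop = True
        if drop:
            new_calls[strain] = replace(call, genotype=MISSING)
            changed = True
        else:
            new_calls[strain] = call
    if not changed:
        return site
    return VariantSite(site.chrom, site.pos, site.ref, site.alt, site.qual, new_calls)


def filter_sites(sites: list[VariantSite], spec: FilterSpec) -> list[VariantSite]:
    """Apply the vcftools-style site filter.

    A site is kept iff it passes, in order: indel removal (when
    ``remove_indels``), missing-call fraction <= 1 - ``max_missing``
    (``max_missing=1`` allows no missing calls), minor allele count over
    non-missing genotypes >= ``mac``, and site quality >= ``min_qual``.  When
    per-sample thresholds are set, failing calls become missing before the
    site-level rules are evaluated.  Idempotent.
    """
    kept: list[VariantSite] = []
    for site in sites:
        if spec.min_sample_depth is not None or spec.min_sample_quality is not None:
            site = _apply_sample_filter(site, spec)
        if spec.remove_indels and site.is_indel:
            continue
        if site.missing_fraction() > 1.0 - spec.max_missing + 1e-12:
            continue
        ref_n, alt_n = site.allele_counts()
        if min(ref_n, alt_n) < spec.mac:
            continue
        if site.qual < spec.min_qual:
            continue
        kept.append(site)
    return kept


@dataclass
class GenotypeMatrix:
    """Sites x strains genotype dosage codes with site metadata.

    ``codes`` is an int8 array of shape (n_sites, n_strains) holding 0/1/2
    dosages with -1 for missing; ``sites`` is a DataFrame with columns
    chrom, pos, ref, alt ordered by (chrom, pos).
    """

    strains: list[str]
    sites: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sites), len(self.strains)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.strains)} strains"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def subset_strains(self, strains: list[str]) -> "GenotypeMatrix":
        idx = [self.strain_index(s) for s in strains]
        return GenotypeMatrix(list(strains), self.sites.copy(), self.codes[:, idx])

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        sub = self.sites.loc[mask_or_index] if isinstance(mask_or_index, np.ndarray) and mask_or_index.dtype == bool else None
        if sub is None:
            index = np.asarray(mask_or_index)
            return GenotypeMatrix(
                self.strains, self.sites.iloc[index].reset_index(drop=True), self.codes[index]
            )
        mask = np.asarray(mask_or_index, dtype=bool)
        return GenotypeMatrix(
            self.strains, self.sites.loc[mask].reset_index(drop=True), self.codes[mask]
        )

    def to_tsv(self, path: str) -> None:
        df = self.sites.copy()
        for j, strain in enumerate(self.strains):
            df[strain] = self.codes[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "pos", "ref", "alt"]
        strains = [c for c in df.columns if c not in meta_cols]
        codes = df[strains].to_numpy(dtype=np.int8)
        return cls(strains, df[meta_cols].reset_index(drop=True), codes)


def to_genotype_matrix(
    sites: list[VariantSite],
    strains: list[str],
    snps_only: bool = False,
) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` with stable (chrom, pos) site order.

    ``snps_only`` restricts to biallelic SNP sites, the substrate required by
    the popgen statistics.
    """
    known = {s for site in sites for s in site.calls}
    for strain in strains:
        if sites and strain not in known:
            raise KeyError(f"unknown strain {strain!r}")
    use = [s for s in sites if (s.is_snp or not snps_only)]
    use.sort(key=lambda s: (s.chrom, s.pos, s.alt))
    meta = pd.DataFrame(
        {
            "chrom": [s.chrom for s in use],
            "pos": [s.pos for s in use],
            "ref": [s.ref for s in use],
            "alt": [s.alt for s in use],
        }
    )
    codes = np.full((len(use), len(strains)), MISSING, dtype=np.int8)
    for i, site in enumerate(use):
        for j, strain in enumerate(strains):
            call = site.calls.get(strain)
            if call is not None:
                codes[i, j] = call.genotype
    return GenotypeMatrix(list(strains), meta, codes)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing (-1)
    pairwise-deleted.  Returns NaN when either vector is constant."""
    mask = (x >= 0) & (y >= 0)
    if mask.sum() < 2:
        return float("nan")
    xv = x[mask].astype(float)
    yv = y[mask].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_prune(
    matrix: GenotypeMatrix,
    window_sites: int = 50,
    step_sites: int = 5,
    r2_threshold: float = 0.5,
) -> GenotypeMatrix:
    """Greedy plink-style LD pruning on genotype-dosage r².

    Windows of ``window_sites`` consecutive retained sites advance by
    ``step_sites``; within a window, when a retained pair exceeds the r²
    threshold the *later* site is removed.  Passes repeat until no removal
    occurs, so the output is a fixed point (pruning a pruned matrix removes
    nothing).  Sites on different chromosomes are never compared.
    """
    n = matrix.n_sites
    keep = np.ones(n, dtype=bool)
    chroms = matrix.sites["chrom"].to_numpy()
    changed = True
    while changed:
        changed = False
        live = np.flatnonzero(keep)
        for start in range(0, max(len(live) - 1, 0), step_sites):
            window = live[start : start + window_sites]
            for a_i in range(len(window)):
                i = window[a_i]
                if not keep[i]:
                    continue
                for b_i in range(a_i + 1, len(window)):
                    j = window[b_i]
                    if not keep[j] or chroms[i] != chroms[j]:
                        continue
                    r2 = genotype_r2(matrix.codes[i], matrix.codes[j])
                    if np.isfinite(r2) and r2 > r2_threshold:
                        keep[j] = False
                        changed = True
    return matrix.take_sites(keep)
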