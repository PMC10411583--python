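"""Loss-of-function classification and LOF-matrix clustering.

A gene is predicted LOF in a strain when its homozygous variants, applied
jointly to the CDS and translated, cause a frameshift (cumulative indel
offset not a multiple of 3, never restored before a novel stop appears),
loss of the initiator ATG, or a premature stop within the first 98% of CDS
codons.  Applying variants jointly before translation means compensated
frameshift pairs that restore the reading frame -- and create no stop in
between -- are classified as intact, and stops landing beyond 98% of the
coding region are ignored.  The genes x strains binary LOF matrix is then
clustered with k-means, the number of clusters chosen by the Tibshirani gap
statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from yeastcohort.variant_io import HOM_ALT, VariantSite

logger = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GeneModelError(ValueError):
    """Gene model inconsistent with the reference sequence."""


@dataclass(frozen=True)
class GeneModel:
    """CDS gene model with 0-based half-open genomic intervals, ordered by
    coordinate; total length must be divisible by 3."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end or start < prev_end:
                raise GeneModelError(f"bad CDS intervals for {self.gene_id}")
            prev_end = end
        if self.cds_length % 3:
            raise GeneModelError(f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @classmethod
    def from_annotation(cls, row: pd.Series) -> "GeneModel":
        """Build from a genes-table row with 0-based half-open start/end."""
        return cls(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            cds_intervals=((int(row["start"]), int(row["end"])),),
        )


@dataclass(frozen=True)
class ConsequenceCall:
    strain: str
    gene: str
    lof_class: str  # frameshift | stop_gained | start_lost | none
    stop_fraction: float | None = None  # position of a novel stop, as CDS fraction

    @property
    def is_lof(self) -> bool:
        return self.lof_class != "none"


def _to_cds_coords(
    gene: GeneModel, variants: list[tuple[int, str, str]]
) -> list[tuple[int, str, str]]:
    """Map genomic variants into concatenated plus-orientation CDS offsets.

    A variant is kept iff its reference span lies wholly within one CDS
    interval; others are ignored (with a warning for partial overlaps).
    """
    out = []
    offset = 0
    for start, end in gene.cds_intervals:
        for pos, ref, alt in variants:
            g0 = pos - 1
            if g0 >= start and g0 + len(ref) <= end:
                out.append((g0 - start + offset, ref, alt))
            elif g0 < end and g0 + len(ref) > start:
                logger.warning(
                    "variant at %s:%d straddles a CDS boundary of %s; ignored",
                    gene.chrom, pos, gene.gene_id,
                )
        offset += end - start
    return sorted(out)


def _apply_with_map(
    original: str, variants: list[tuple[int, str, str]]
) -> tuple[str, np.ndarray]:
    """Apply (offset, ref, alt) variants; return the mutated sequence and an
    array mapping each mutated index to the original index it derives from
    (inserted bases map to their anchor)."""
    pieces: list[str] = []
    maps: list[np.ndarray] = []
    cursor = 0
    for off, ref, alt in variants:
        if off < cursor:
            logger.warning("skipping overlapping variant at CDS offset %d", off)
            continue
        if original[off : off + len(ref)] != ref:
            raise GeneModelError(
                f"reference mismatch at CDS offset {off}: expected {ref!r}, "
                f"found {original[off:off + len(ref)]!r}"
            )
        pieces.append(original[cursor:off])
        maps.append(np.arange(cursor, off))
        pieces.append(alt)
        alt_map = np.minimum(off + np.arange(len(alt)), off + len(ref) - 1)
        maps.append(alt_map)
        cursor = off + len(ref)
    pieces.append(original[cursor:])
    maps.append(np.arange(cursor, len(original)))
    mutated = "".join(pieces)
    orig_index = np.concatenate(maps) if maps else np.arange(len(original))
    return mutated, orig_index


def classify_lof(
    strain: str,
    gene: GeneModel,
    reference: dict[str, str],
    variants: list[tuple[int, str, str]],
) -> ConsequenceCall:
    """Classify the joint coding impact of a strain's homozygous variants.

    ``variants`` holds (pos 1-based, ref, alt) records already restricted to
    homozygous calls passing the per-sample depth/quality filter; variants
    outside the CDS are ignored.  The mutated CDS is reconstructed in
    coordinate order (strand-aware) and translated as a whole.
    """
    seq = reference.get(gene.chrom)
    if seq is None:
        raise GeneModelError(f"chromosome {gene.chrom} absent from reference")
    genomic_cds = "".join(seq[s:e] for s, e in gene.cds_intervals)
    cds_variants = _to_cds_coords(gene, variants)
    if not cds_variants:
        return ConsequenceCall(strain, gene.gene_id, "none")

    mutated, orig_index = _apply_with_map(genomic_cds, cds_variants)
    L = len(genomic_cds)
    n0 = L // 3
    if gene.strand == "-":
        coding = _revcomp(mutated)
        coding_orig = (L - 1 - orig_index)[::-1]
    else:
        coding = mutated
        coding_orig = orig_index

    if coding[:3] != "ATG":
        return ConsequenceCall(strain, gene.gene_id, "start_lost")

    first_stop = None
    for i in range(0, len(coding) - 2, 3):
        if coding[i : i + 3] in _STOPS:
            first_stop = i // 3
            break

    net_offset = len(mutated) - L
    if first_stop is None:
        if net_offset % 3:
            return ConsequenceCall(strain, gene.gene_id, "frameshift")
        return ConsequenceCall(strain, gene.gene_id, "none")

    m0 = 3 * first_stop
    o0 = int(coding_orig[m0])
    frame_offset = m0 - o0
    c_orig = o0 // 3 + 1  # 1-based codon index in the original CDS
    stop_fraction = c_orig / n0
    if frame_offset % 3:
        return ConsequenceCall(strain, gene.gene_id, "frameshift", stop_fraction)
    if c_orig < n0 and c_orig <= math.floor(0.98 * n0):
        return ConsequenceCall(strain, gene.gene_id, "stop_gained", stop_fraction)
    return ConsequenceCall(strain, gene.gene_id, "none", stop_fraction)


def classify_cohort_lof(
    sites: list[VariantSite],
    genes: list[GeneModel],
    reference: dict[str, str],
    strains: list[str],
    min_depth: int = 10,
    min_quality: float = 10.0,
) -> list[ConsequenceCall]:
    """Run the classifier for every strain x gene pair.

    Only homozygous-alt calls with depth >= ``min_depth`` and genotype
    quality >= ``min_quality`` are applied (the annotation-arm per-sample
    filter).
    """
    by_strain_chrom: dict[tuple[str, str], list[tuple[int, str, str]]] = {}
    for site in sites:
        for strain in strains:
            call = site.calls.get(strain)
            if call is None or call.genotype != HOM_ALT:
                continue
            if call.depth is not None and call.depth < min_depth:
                continue
            if call.genotype_quality is not None and call.genotype_quality < min_quality:
                continue
            by_strain_chrom.setdefault((strain, site.chrom), []).append(
                (site.pos, site.ref, site.alt)
            )
    calls = []
    for strain in strains:
        for gene in genes:
            variants = by_strain_chrom.get((strain, gene.chrom), [])
            calls.append(classify_lof(strain, gene, reference, variants))
    return calls


def build_lof_matrix(
    calls: list[ConsequenceCall], genes: list[str], strains: list[str]
) -> pd.DataFrame:
    """Genes x strains binary matrix: 1 iff any non-none call for the pair."""
    mat = pd.DataFrame(0, index=list(genes), columns=list(strains), dtype=np.int8)
    for call in calls:
        if call.is_lof and call.gene in mat.index and call.strain in mat.columns:
            mat.loc[call.gene, call.strain] = 1
    return mat


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene -> cluster label
    inertia: float  # within-cluster dispersion W_k
    gap_table: pd.DataFrame | None = None  # per-k Gap(k), s_k, log W_k


def kmeans_cluster(
    matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """K-means on binary gene rows (Euclidean), best of ``n_init`` k-means++
    initializations; deterministic for a fixed seed."""
    if k < 1 or k > len(matrix):
        raise ValueError(f"k={k} out of range for {len(matrix)} genes")
    X = matrix.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=matrix.index, name="cluster"),
        inertia=float(km.inertia_),
    )


def select_k_gap(
    matrix: pd.DataFrame,
    k_max: int = 10,
    b_reference: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Choose k by the Tibshirani gap statistic.

    Gap(k) = E*[log W_k] - log W_k over ``b_reference`` uniform reference
    datasets drawn from the feature bounding box; the chosen k is the
    smallest with Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if len(matrix) < 2:
        raise ValueError("need at least 2 genes")
    k_max = min(k_max, len(matrix))
    X = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, rs: int) -> float:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs)
        km.fit(data)
        return float(np.log(max(km.inertia_, 1e-300)))

    rows = []
    for k in range(1, k_max + 1):
        lw = log_wk(X, k, seed)
        ref_lw = np.array(
            [
                log_wk(lo + rng.random(X.shape) * (hi - lo), k, seed + b + 1)
                for b in range(b_reference)
            ]
        )
        gap = float(ref_lw.mean() - lw)
        s_k = float(ref_lw.std(ddof=0) * np.sqrt(1.0 + 1.0 / b_reference))
        rows.append({"k": k, "log_wk": lw, "gap": gap, "s_k": s_k})
    table = pd.DataFrame(rows)
    chosen = k_max
    for i in range(len(table) - 1):
        if table.loc[i, "gap"] >= table.loc[i + 1, "gap"] - table.loc[i + 1, "s_k"]:
            chosen = int(table.loc[i, "k"])
            break
    result = kmeans_cluster(matrix, chosen, seed=seed, n_init=n_init)
    result.gap_table = table
    return result
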