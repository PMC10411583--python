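"""Accessory-genome (non-reference ORF) clustering and presence calls.

ORFs longer than 180 bp found on both strands are clustered greedily at 97%
nucleotide identity (length-sorted, representative = longest member;
identity = matching bases in the best alignment over the length of the
shorter sequence).  Clusters pass a three-step cascade -- focal-strain
membership, start/stop completeness, representative occurring full-length in
a focal strain -- before per-strain presence is classified full / partial /
absent from the best local-alignment hit: absent without a hit at E <= 1e-6
and bit-score ratio >= 0.4, full when query coverage >= 99% and identity
>= 97%, partial otherwise.  Alignment uses standard nucleotide-search
scoring (match +2, mismatch -3, gap open 5, gap extend 2) with the
corresponding Karlin-Altschul bit score (lambda = 0.625, K = 0.41); an
11-mer prefilter skips pairs sharing no 11-mer, which by pigeonhole cannot
exclude any pair at >= 97% identity for lengths >= 180 (a 180 bp sequence at
97% identity has at most 6 mismatches, which cannot break every one of the
170 overlapping 11-mers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")

BLAST_LAMBDA = 0.625
BLAST_K = 0.41
KMER_SIZE = 11


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class OrfSeq:
    """A predicted ORF in its coding orientation."""

    id: str
    strain: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty ORF sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def has_start(self) -> bool:
        return self.seq[:3] == "ATG"

    @property
    def has_stop(self) -> bool:
        return len(self.seq) % 3 == 0 and self.seq[-3:] in _STOPS


def find_orfs(
    contigs: dict[str, str], min_len_bp: int = 180, strain: str = ""
) -> list[OrfSeq]:
    """Scan both strands, all six frames, for ATG..stop ORFs.

    An ORF is the maximal ATG..stop span within one frame (the first ATG
    after the previous stop); only ORFs strictly longer than ``min_len_bp``
    are kept.  Reverse-strand ORFs are reported reverse-complemented, in
    their coding orientation.
    """
    orfs = []
    counter = 0
    for contig_id, forward in contigs.items():
        for strand, seq in (("+", forward.upper()), ("-", _revcomp(forward.upper()))):
            for frame in range(3):
                start_codon = None
                for i in range(frame, len(seq) - 2, 3):
                    codon = seq[i : i + 3]
                    if codon in _STOPS:
                        if start_codon is not None:
                            length = i + 3 - start_codon
                            if length > min_len_bp:
                                counter += 1
                                orfs.append(
                                    OrfSeq(
                                        id=f"{contig_id}|orf{counter}",
                                        strain=strain,
                                        seq=seq[start_codon : i + 3],
                                    )
                                )
                        start_codon = None
                    elif codon == "ATG" and start_codon is None:
                        start_codon = i
    return orfs


# ---------------------------------------------------------------------------
# alignment engine
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    # a gap of length L costs 5 + 2L
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentHit:
    """Best local hit of a query against a subject sequence."""

    query_id: str
    subject_id: str
    identity: float  # identities / aligned columns
    coverage: float  # aligned query span / query length
    score: float
    bit_score: float
    evalue: float
    bsr: float  # bit score / query self-hit bit score


def bit_score(raw_score: float) -> float:
    return (BLAST_LAMBDA * raw_score - math.log(BLAST_K)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    return BLAST_K * m * n * math.exp(-BLAST_LAMBDA * raw_score)


def _kmers(seq: str, k: int = KMER_SIZE) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def count_matches(a: str, b: str) -> int:
    """Identical aligned bases in the best local alignment of a and b."""
    alignments = _ALIGNER.align(a, b)
    if len(alignments) == 0:
        return 0
    counts = alignments[0].counts()
    return int(counts.identities)


def sequence_identity(a: str, b: str) -> float:
    """Matching bases in the best alignment over the shorter length."""
    return count_matches(a, b) / min(len(a), len(b))


def best_hit(
    query_id: str,
    query: str,
    subjects: dict[str, str],
    db_size: int | None = None,
    prefilter: bool = True,
) -> AlignmentHit | None:
    """Highest-scoring local hit of ``query`` among ``subjects``."""
    if not subjects:
        return None
    n_total = db_size if db_size is not None else sum(len(s) for s in subjects.values())
    qkmers = _kmers(query) if prefilter else None
    best: tuple[float, str, object] | None = None
    for sid, subject in subjects.items():
        if prefilter and qkmers and not (qkmers & _kmers(subject)):
            continue
        alignments = _ALIGNER.align(query, subject)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if best is None or aln.score > best[0]:
            best = (float(aln.score), sid, aln)
    if best is None:
        return None
    score, sid, aln = best
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    q_ranges = aln.aligned[0]
    q_span = int(q_ranges[-1][1] - q_ranges[0][0]) if len(q_ranges) else 0
    self_bit = bit_score(2.0 * len(query))
    return AlignmentHit(
        query_id=query_id,
        subject_id=sid,
        identity=counts.identities / aligned_cols if aligned_cols else 0.0,
        coverage=q_span / len(query),
        score=score,
        bit_score=bit_score(score),
        evalue=evalue(score, len(query), n_total),
        bsr=bit_score(score) / self_bit,
    )


# ---------------------------------------------------------------------------
# clustering and the filter cascade
# ---------------------------------------------------------------------------

@dataclass
class OrfCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    representative_length: int = 0


def greedy_cluster(
    orfs: list[OrfSeq], identity_threshold: float = 0.97
) -> list[OrfCluster]:
    """Greedy length-sorted clustering at >= ``identity_threshold`` identity.

    ORFs are visited longest first (ties by id); each joins the first
    existing cluster whose representative is at least the threshold
    identical (matches over the shorter length), else founds a new cluster.
    The founding member is the longest, so it is the representative.
    """
    if not orfs:
        raise ValueError("need at least one ORF")
    by_id = {o.id: o for o in orfs}
    ordered = sorted(orfs, key=lambda o: (-o.length, o.id))
    clusters: list[OrfCluster] = []
    cluster_kmers: list[set[str]] = []
    for orf in ordered:
        kmers = _kmers(orf.seq)
        placed = False
        for ci, cluster in enumerate(clusters):
            if kmers and cluster_kmers[ci] and not (kmers & cluster_kmers[ci]):
                continue
            rep = by_id[cluster.representative_id]
            if sequence_identity(rep.seq, orf.seq) >= identity_threshold:
                cluster.member_ids.append(orf.id)
                placed = True
                break
        if not placed:
            clusters.append(
                OrfCluster(
                    representative_id=orf.id,
                    member_ids=[orf.id],
                    representative_length=orf.length,
                )
            )
            cluster_kmers.append(kmers)
    return clusters


def filter_clusters(
    clusters: list[OrfCluster],
    orfs_by_id: dict[str, OrfSeq],
    focal_strains: set[str],
    identity_threshold: float = 0.97,
    full_length_coverage: float = 0.99,
) -> tuple[list[OrfCluster], pd.DataFrame]:
    """The three-step cluster filter cascade, with a step-count log.

    1. Drop clusters with no member from a focal strain.
    2. Drop member sequences lacking a start or a stop codon; drop clusters
       emptied by this (the representative is re-elected if removed).
    3. Keep a cluster only if its longest (representative) sequence occurs
       full-length (coverage >= ``full_length_coverage`` of the
       representative, identity >= ``identity_threshold``) in at least one
       focal strain.
    """
    counts = [("initial", len(clusters))]

    step1 = [
        c
        for c in clusters
        if any(orfs_by_id[m].strain in focal_strains for m in c.member_ids)
    ]
    counts.append(("focal_membership", len(step1)))

    step2 = []
    for cluster in step1:
        members = [
            m
            for m in cluster.member_ids
            if orfs_by_id[m].has_start and orfs_by_id[m].has_stop
        ]
        if not members:
            continue
        rep = max(members, key=lambda m: (orfs_by_id[m].length, m))
        step2.append(
            OrfCluster(
                representative_id=rep,
                member_ids=members,
                representative_length=orfs_by_id[rep].length,
            )
        )
    counts.append(("start_stop_complete", len(step2)))

    step3 = []
    for cluster in step2:
        rep = orfs_by_id[cluster.representative_id]
        ok = False
        for m in cluster.member_ids:
            orf = orfs_by_id[m]
            if orf.strain not in focal_strains:
                continue
            if min(orf.length, rep.length) / rep.length < full_length_coverage:
                continue
            if sequence_identity(rep.seq, orf.seq) >= identity_threshold:
                ok = True
                break
        if ok:
            step3.append(cluster)
    counts.append(("representative_in_focal", len(step3)))

    log = pd.DataFrame(counts, columns=["step", "n_clusters"])
    return step3, log


def classify_presence(
    representatives: dict[str, str],
    strain_seqs: dict[str, dict[str, str]],
    bsr_min: float = 0.4,
    e_max: float = 1e-6,
    full_coverage: float = 0.99,
    full_identity: float = 0.97,
) -> pd.DataFrame:
    """Cluster x strain presence matrix with values full / partial / absent.

    A strain is absent for a cluster without a hit at E <= ``e_max`` and
    bit-score ratio >= ``bsr_min``; full when the best hit additionally has
    query coverage >= ``full_coverage`` and identity >= ``full_identity``;
    partial otherwise.
    """
    strains = list(strain_seqs)
    out = pd.DataFrame("absent", index=list(representatives), columns=strains)
    for cluster_id, rep in representatives.items():
        for strain in strains:
            hit = best_hit(cluster_id, rep, strain_seqs[strain])
            if hit is None or hit.evalue > e_max or hit.bsr < bsr_min:
                continue
            if hit.coverage >= full_coverage and hit.identity >= full_identity:
                out.loc[cluster_id, strain] = "full"
            else:
                out.loc[cluster_id, strain] = "partial"
    return out
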