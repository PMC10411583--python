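"""Population-genetic statistics over strain groups.

Nucleotide diversity (per-site pi, invariant positions in the denominator),
Tajima's D with the standard 1989 constants, windowed Weir-Cockerham (1984)
Fst from the a/b/c variance components, and the frequency-weighted ABBA-BABA
(Patterson's D) statistic with a block-jackknife Z score.  Diploid genotypes
contribute allele counts (a het is one of each allele); no phasing is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from yeastcohort.variant_io import HET, GenotypeMatrix

__all__ = [
    "DiversityResult",
    "DstatResult",
    "nucleotide_diversity",
    "tajimas_d",
    "wc_fst",
    "wc_site_components",
    "abba_baba",
]


@dataclass
class DiversityResult:
    group: str
    pi: float | None = None
    S: int = 0
    tajimas_d: float | None = None
    n_haplotypes: int = 0


def _group_codes(matrix: GenotypeMatrix, strains: list[str]) -> np.ndarray:
    idx = [matrix.strain_index(s) for s in strains]
    return matrix.codes[:, idx]


def _site_allele_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (haplotype count n, alt allele count j) over non-missing
    diploid-coded genotypes."""
    called = codes >= 0
    n = 2 * called.sum(axis=1)
    j = np.where(called, codes, 0).sum(axis=1)
    return n, j


def nucleotide_diversity(
    matrix: GenotypeMatrix,
    strains: list[str],
    span_bp: int,
    group: str = "",
) -> DiversityResult:
    """Per-site nucleotide diversity pi for one strain group.

    pi = sum over polymorphic sites of the average pairwise difference
    2 j (n - j) / (n (n - 1)), divided by the number of spanned positions
    ``span_bp`` (monomorphic positions count in the denominator).
    """
    if len(strains) < 1:
        raise ValueError("group must contain at least one strain")
    if span_bp < 1:
        raise ValueError("span_bp must be >= 1")
    codes = _group_codes(matrix, strains)
    n, j = _site_allele_counts(codes)
    ok = n >= 2
    n = n[ok].astype(float)
    j = j[ok].astype(float)
    per_site = 2.0 * j * (n - j) / (n * (n - 1.0))
    S = int(np.count_nonzero((j > 0) & (j < n)))
    return DiversityResult(
        group=group,
        pi=float(per_site.sum()) / span_bp,
        S=S,
        n_haplotypes=2 * len(strains),
    )


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for n haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(matrix: GenotypeMatrix, strains: list[str], group: str = "") -> DiversityResult:
    """Tajima's D for one group; NA (None) when no segregating sites.

    Sites with any missing genotype inside the group are excluded so the
    haplotype count n = 2 x number of strains is constant across sites.
    """
    codes = _group_codes(matrix, strains)
    n_hap = 2 * len(strains)
    if n_hap < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes (2 diploids)")
    complete = (codes >= 0).all(axis=1)
    j = codes[complete].sum(axis=1).astype(float)
    seg = (j > 0) & (j < n_hap)
    S = int(np.count_nonzero(seg))
    result = DiversityResult(group=group, S=S, n_haplotypes=n_hap)
    if S == 0:
        return result
    js = j[seg]
    theta_pi = float((2.0 * js * (n_hap - js) / (n_hap * (n_hap - 1.0))).sum())
    k = tajima_constants(n_hap)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    result.tajimas_d = (theta_pi - theta_w) / np.sqrt(var)
    result.pi = theta_pi  # summed over sites; divide by span for per-site scale
    return result


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) Fst
# ---------------------------------------------------------------------------

def wc_site_components(pop_codes: list[np.ndarray]) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic site.

    ``pop_codes`` holds one dosage vector (0/1/2, -1 missing) per population;
    a is the among-population, b the among-individual-within-population and c
    the within-individual component.  Returns (nan, nan, nan) for sites with
    fewer than two populations sampled or no data.
    """
    sizes, freqs, hets = [], [], []
    for codes in pop_codes:
        called = codes[codes >= 0]
        if len(called) == 0:
            continue
        sizes.append(float(len(called)))
        freqs.append(called.sum() / (2.0 * len(called)))
        hets.append(np.count_nonzero(called == HET) / len(called))
    r = len(sizes)
    if r < 2:
        return (float("nan"),) * 3
    n_i = np.array(sizes)
    p_i = np.array(freqs)
    h_i = np.array(hets)
    n_bar = n_i.mean()
    if n_bar <= 1:
        return (float("nan"),) * 3
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1.0)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def wc_fst(
    matrix: GenotypeMatrix,
    group_a: list[str],
    group_b: list[str],
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Windowed two-population Weir-Cockerham Fst.

    Returns one row per window with the summed components and the two usual
    aggregates: ``weighted_fst`` = sum(a) / sum(a+b+c) and ``mean_fst`` = the
    mean of per-site ratios; both NA for windows without usable sites.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    codes_a = _group_codes(matrix, group_a)
    codes_b = _group_codes(matrix, group_b)
    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    comp = np.array(
        [wc_site_components([codes_a[i], codes_b[i]]) for i in range(matrix.n_sites)]
    ) if matrix.n_sites else np.empty((0, 3))
    rows = []
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        p = pos0[on]
        c = comp[on]
        if len(p) == 0:
            continue
        for start in range(0, int(p.max()) + 1, window_bp):
            end = start + window_bp
            inw = (p >= start) & (p < end)
            if not inw.any():
                continue
            a, b, cc = c[inw, 0], c[inw, 1], c[inw, 2]
            ok = np.isfinite(a)
            a, b, cc = a[ok], b[ok], cc[ok]
            denom = (a + b + cc).sum()
            site_denom = a + b + cc
            site_ok = site_denom != 0
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "n_sites": int(ok.sum()),
                    "sum_a": float(a.sum()), "sum_b": float(b.sum()), "sum_c": float(cc.sum()),
                    "weighted_fst": float(a.sum() / denom) if denom != 0 else float("nan"),
                    "mean_fst": float((a[site_ok] / site_denom[site_ok]).mean())
                    if site_ok.any() else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "sum_a", "sum_b", "sum_c",
                       "weighted_fst", "mean_fst"]
    )


# ---------------------------------------------------------------------------
# ABBA-BABA (Patterson's D)
# ---------------------------------------------------------------------------

@dataclass
class DstatResult:
    abba: float
    baba: float
    bbaa: float
    d: float | None
    z: float | None
    se: float | None
    n_blocks: int
    n_sites: int
    block_d: list[float] = field(default_factory=list)


def _pop_freqs(codes: np.ndarray) -> np.ndarray:
    called = codes >= 0
    n = 2.0 * called.sum(axis=1)
    j = np.where(called, codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, j / n, np.nan)


def abba_baba(
    matrix: GenotypeMatrix,
    p1: list[str],
    p2: list[str],
    p3: list[str],
    outgroup: list[str],
    block_count: int = 20,
) -> DstatResult:
    """Frequency-weighted Patterson's D with a block-jackknife Z score.

    Sites are polarized so that the outgroup's major allele is ancestral.
    ABBA = sum (1-f1) f2 f3 (1-f4); BABA = sum f1 (1-f2) f3 (1-f4); BBAA =
    sum f1 f2 (1-f3)(1-f4); D = (ABBA - BABA) / (ABBA + BABA).  Z comes from
    a delete-one jackknife over ``block_count`` contiguous equal-site blocks.
    """
    freqs = [
        _pop_freqs(_group_codes(matrix, grp)) for grp in (p1, p2, p3, outgroup)
    ]
    usable = np.all(np.isfinite(freqs), axis=0)
    f1, f2, f3, f4 = (f[usable] for f in freqs)
    # polarize on the outgroup major allele
    flip = f4 > 0.5
    f1, f2, f3, f4 = (np.where(flip, 1.0 - f, f) for f in (f1, f2, f3, f4))
    abba = (1 - f1) * f2 * f3 * (1 - f4)
    baba = f1 * (1 - f2) * f3 * (1 - f4)
    bbaa = f1 * f2 * (1 - f3) * (1 - f4)
    tot_abba, tot_baba, tot_bbaa = map(float, (abba.sum(), baba.sum(), bbaa.sum()))
    n_sites = int(usable.sum())
    if tot_abba + tot_baba == 0:
        return DstatResult(tot_abba, tot_baba, tot_bbaa, None, None, None, 0, n_sites)
    d = (tot_abba - tot_baba) / (tot_abba + tot_baba)
    blocks = np.array_split(np.arange(n_sites), min(block_count, max(n_sites, 1)))
    block_d = []
    for block in blocks:
        if len(block) == 0:
            continue
        mask = np.ones(n_sites, dtype=bool)
        mask[block] = False
        num = abba[mask].sum() - baba[mask].sum()
        den = abba[mask].sum() + baba[mask].sum()
        block_d.append(float(num / den) if den != 0 else d)
    bd = np.array(block_d)
    B = len(bd)
    se = float(np.sqrt((B - 1.0) / B * ((bd - bd.mean()) ** 2).sum())) if B > 1 else None
    if se is None:
        z = None
    elif se == 0.0:
        z = float("inf") * np.sign(d) if d != 0 else 0.0
    else:
        z = d / se
    return DstatResult(tot_abba, tot_baba, tot_bbaa, d, z, se, B, n_sites, block_d)
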