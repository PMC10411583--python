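"""Windowed heterozygosity, allele-balance ploidy calls and aneuploidy.

Heterozygosity is the fraction of a strain's variant calls in a 50 kb window
(25 kb step) that are heterozygous; the strain-level figure is 100 x the
median of window ratios over windows holding at least one variant.  Before
windowing, heterozygous calls with allelic balance (min allele depth / total)
below 0.3 are set to missing -- balance exactly 0.3 is kept.  Ploidy is read
from the distribution of alternate-allele depth fractions at heterozygous
sites: one dominant mode near 1/2 for diploids, modes near 1/3 and 2/3 for
triploids.  Aneuploidy is a sustained whole-chromosome shift of binned
coverage relative to the genome-wide median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from yeastcohort.variant_io import HET, MISSING, GenotypeMatrix, VariantSite

logger = logging.getLogger(__name__)


def allelic_balance_filter(
    sites: list[VariantSite], threshold: float = 0.3, on_missing_ad: str = "skip"
) -> list[VariantSite]:
    """Set heterozygous calls with allelic balance < ``threshold`` to missing.

    Balance exactly at the threshold is kept ("below" is strict).  Homozygous
    and missing calls are never changed.  Het calls without allele depths are
    skipped with a warning (``on_missing_ad="skip"``) or raise
    (``on_missing_ad="error"``).
    """
    out: list[VariantSite] = []
    for site in sites:
        new_calls = None
        for strain, call in site.calls.items():
            if call.genotype != HET:
                continue
            balance = call.allelic_balance
            if balance is None:
                if on_missing_ad == "error":
                    raise ValueError(
                        f"het call without allele depths at {site.chrom}:{site.pos} ({strain})"
                    )
                logger.warning(
                    "het call without allele depths at %s:%d (%s); kept",
                    site.chrom, site.pos, strain,
                )
                continue
            if balance < threshold:
                if new_calls is None:
                    new_calls = dict(site.calls)
                new_calls[strain] = replace(call, genotype=MISSING)
        if new_calls is None:
            out.append(site)
        else:
            out.append(VariantSite(site.chrom, site.pos, site.ref, site.alt, site.qual, new_calls))
    return out


@dataclass
class HetProfile:
    """Per-strain windowed heterozygosity.

    ``windows`` has columns chrom, start, end (0-based half-open),
    n_variants, n_het, ratio; ``percent_heterozygosity`` is 100 x the median
    ratio over windows with at least one variant (0 with a warning for a
    strain without variants).
    """

    strain: str
    windows: pd.DataFrame
    percent_heterozygosity: float


def _window_starts(chrom_len: int, window: int, step: int) -> list[int]:
    if chrom_len <= window:
        return [0]
    last = int(math.ceil((chrom_len - window) / step)) * step
    return list(range(0, last + 1, step))


def compute_heterozygosity(
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window_bp: int = 50_000,
    step_bp: int = 25_000,
) -> dict[str, HetProfile]:
    """Windowed heterozygosity per strain.

    Expects the allelic-balance filter to have been applied already.  A
    variant (site where the strain carries het or hom-alt) is counted in each
    window whose span contains it -- at most two given 50% overlap.  Trailing
    partial windows at chromosome ends are retained.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    profiles: dict[str, HetProfile] = {}
    for j, strain in enumerate(matrix.strains):
        codes = matrix.codes[:, j]
        rows = []
        for chrom, clen in chrom_lengths.items():
            on = chroms == chrom
            p = pos0[on]
            c = codes[on]
            for start in _window_starts(clen, window_bp, step_bp):
                end = min(start + window_bp, clen)
                inw = (p >= start) & (p < end)
                cw = c[inw]
                n_var = int(np.count_nonzero(cw > 0))
                n_het = int(np.count_nonzero(cw == HET))
                rows.append(
                    {"chrom": chrom, "start": start, "end": end,
                     "n_variants": n_var, "n_het": n_het,
                     "ratio": n_het / n_var if n_var else float("nan")}
                )
        windows = pd.DataFrame(rows)
        nonempty = windows.loc[windows["n_variants"] >= 1, "ratio"]
        if nonempty.empty:
            logger.warning("strain %s has no variants; heterozygosity set to 0%%", strain)
            percent = 0.0
        else:
            percent = 100.0 * float(nonempty.median())
        profiles[strain] = HetProfile(strain, windows, percent)
    return profiles


@dataclass
class PloidyCall:
    strain: str
    ploidy: int | None  # 2, 3 or None for indeterminate
    peaks: list[float] = field(default_factory=list)
    n_het_sites: int = 0

    @property
    def label(self) -> str:
        return str(self.ploidy) if self.ploidy else "indeterminate"


def infer_ploidy_from_fractions(
    fractions: np.ndarray,
    strain: str = "",
    min_het_sites: int = 200,
    n_bins: int = 25,
    peak_mass: float = 0.05,
    tolerance: float = 0.08,
) -> PloidyCall:
    """Classify ploidy from alt-depth fractions at heterozygous sites.

    Histogram with ``n_bins`` bins on (0, 1); peaks are local maxima holding
    more than ``peak_mass`` of total mass.  Triploid requires peaks within
    ``tolerance`` of both 1/3 and 2/3; diploid a peak within tolerance of
    1/2; anything else (or too few sites) is indeterminate.
    """
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions[np.isfinite(fractions)]
    n = len(fractions)
    if n < min_het_sites:
        return PloidyCall(strain, None, [], n)
    counts, edges = np.histogram(fractions, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    padded = np.concatenate([[-1], counts, [-1]])
    peaks = [
        float(centers[i])
        for i in range(n_bins)
        if padded[i + 1] > padded[i]
        and padded[i + 1] >= padded[i + 2]
        and counts[i] > peak_mass * n
    ]
    near = lambda target: any(abs(p - target) <= tolerance for p in peaks)
    if near(1 / 3) and near(2 / 3):
        return PloidyCall(strain, 3, peaks, n)
    if near(0.5):
        return PloidyCall(strain, 2, peaks, n)
    return PloidyCall(strain, None, peaks, n)


def infer_ploidy(
    sites: list[VariantSite], strain: str, min_het_sites: int = 200, **kwargs
) -> PloidyCall:
    """Ploidy call for one strain from its het-site allele depths."""
    fracs = []
    for site in sites:
        call = site.calls.get(strain)
        if call is None or call.genotype != HET or call.allele_depths is None:
            continue
        ref_d, alt_d = call.allele_depths
        if ref_d + alt_d > 0:
            fracs.append(alt_d / (ref_d + alt_d))
    return infer_ploidy_from_fractions(
        np.array(fracs), strain=strain, min_het_sites=min_het_sites, **kwargs
    )


@dataclass
class AneuploidyCall:
    strain: str
    chrom: str
    delta: int  # copy difference vs base ploidy, nonzero
    estimate: float  # ploidy-scaled median bin copy estimate


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def call_aneuploidy(
    coverage_bins: pd.DataFrame,
    strain: str,
    ploidy: int,
    min_bins: int = 3,
    copy_threshold: float = 0.5,
) -> list[AneuploidyCall]:
    """Whole-chromosome copy calls from binned coverage.

    Per chromosome the copy estimate is ``ploidy x median(bin depth) /
    genome-wide median(bin depth)``; a chromosome is called aneuploid when
    the estimate deviates from the ploidy by at least ``copy_threshold``
    copies.  Chromosomes with fewer than ``min_bins`` bins are skipped.
    """
    bins = coverage_bins[coverage_bins["strain"] == strain] if "strain" in coverage_bins else coverage_bins
    if bins.empty:
        return []
    genome_median = float(bins["depth"].median())
    if genome_median <= 0:
        raise ValueError("genome-wide median bin depth is zero")
    calls = []
    for chrom, sub in bins.groupby("chrom", sort=True):
        if len(sub) < min_bins:
            logger.warning("chromosome %s has < %d bins; skipped", chrom, min_bins)
            continue
        estimate = ploidy * float(sub["depth"].median()) / genome_median
        if abs(estimate - ploidy) >= copy_threshold:
            delta = _round_half_away(estimate) - ploidy
            if delta != 0:
                calls.append(AneuploidyCall(strain, str(chrom), delta, estimate))
    return calls
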