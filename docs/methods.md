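# Methods

This note documents the models and procedures implemented in `yeastcohort`,
the defaults they use, and what the synthetic cohort does and does not
emulate.

## The synthetic cohort

The generator produces a miniature multi-clade cohort whose *statistics*
match a short-read yeast resequencing study, without simulating reads.

**Genome and annotation.** Four chromosomes of 200 kb by default (large
enough for 50 kb / 25 kb heterozygosity windows and 10 kb coverage bins,
small enough for seconds-scale simulation), with 100 single-CDS genes of
100–500 codons on both strands.  Every CDS carries two sentinel TAT codons
(one substitution from TAA) at ~30% and at the second-to-last codon, so
early and late premature stops can always be planted in any gene.

**Clade structure.** A star phylogeny: each group descends from the common
ancestor (the reference) with a group-specific branch.  Half of a group's
divergence rate is planted as group-fixed homozygous alleles, half as
per-strain private homozygous alleles; there is no intra-group topology.
This is enough to order π by divergence rate, to give strongly positive
between-group Fst, and to produce the private-allele excess that drives
Tajima's D negative — the qualitative signatures the analyses must detect.
Default groups mirror a four-group wine/oak design: BCWE (n = 10, 3.8%
heterozygosity), PWCW (n = 9, 0%), RCW (n = 4, 13%), RNAO (n = 6, 0%), with
divergence rates 0.0044–0.0060 per site matched to median SNP densities of
~52–72 k over a 12 Mb genome.  Group sizes are scaled to roughly a quarter
of the study's 38/34/10/20 so a full simulation stays at desk scale; rates,
heterozygosity targets and depth are not scaled.

**Heterozygosity.** A group's target heterozygosity *h* is the fraction of
a strain's variant calls that are heterozygous; the generator plants
n_het = h/(1−h) × n_hom private heterozygous SNPs per strain, so the
emitted fraction equals the target up to rounding.

**Depths.** Per-site call depth is negative binomial with variance = 2 ×
mean (mean 100× by default, a scaled-down stand-in for deep short-read
coverage).  Allele depths at heterozygous sites are binomial in the strain's
allelic copy ratio: p = ½ for diploids, ⅓ or ⅔ for triploids — the basis of
the allele-balance ploidy caller.  Per-ORF and per-bin depths aggregate
per-base negative-binomial counts (variance = 2 × mean per base), so a
region of length L has relative depth noise √(2 / (mean × L)); a 300 bp ORF
at 50× still recovers planted copy number within a few percent, which is
what makes the ±10% CN-recovery check meaningful rather than marginal.

**Coding-truth exhaustiveness.** Background mutations are placed only
outside CDS intervals (±5 bp).  This is deliberately unrealistic: it means
the planted loss-of-function events are the *only* coding-impact variants,
so classifier sensitivity and specificity can be asserted to be exactly 1.0.
Consequently the tests say nothing about LOF calling amid dense coding
polymorphism; they validate the reconstruction/translation logic, the
frameshift-compensation rule and the 98% stop rule.

**Planted events.** LOF classes (frameshift, stop gained, start lost,
compensated frameshift pair, late stop), integer CN events (ORF depth
rescaled by CN/ploidy; CN 0 leaves a 0.2% mapping-noise floor), whole-
chromosome aneuploidies, accessory ORF content (one linked multi-gene
horizontally-transferred cluster whose genes co-occur full-length in
carriers, plus independent clusters with optional 60%-length truncations),
and introgression (a fraction of one group's fixed alleles copied into
another group).  Compensated pairs are planted by searching insertion
positions and bases until the shifted frame between the two insertions
contains no stop codon — the +1 frame can expose stops already present in
the sequence, so inserted bases alone are not always sufficient.

**Not emulated:** read-level errors, mapping artifacts, recombination,
selection, demography beyond the star topology, LOH tracts, the
mitochondrial genome, and coding background polymorphism (above).

## Variant filtering and LD pruning

Site filters follow the vcftools semantics: `max_missing = 1` allows no
missing calls; `mac` counts the minor allele over non-missing genotypes (a
het contributes one, a hom-alt two); indels are removed for the phylogeny
arm; site quality ≥ 10.  The per-sample depth ≥ 10 / quality ≥ 10 filter
used for the annotation arm sets failing calls to missing *before* the site
rules are evaluated — the quoted tool's behaviour is ambiguous here, and
setting-to-missing is the conservative reading.

LD pruning computes r² as the squared Pearson correlation of genotype
dosages (0/1/2; missing pairwise-deleted), since phase is unavailable.
Windows of 50 retained sites advance by 5; the later site of an offending
pair (r² > 0.5) is removed; passes repeat to a fixed point so pruning is
idempotent.  Triploid genotypes are coded by rounding dosage into {0, 1, 2}.

## Heterozygosity, ploidy and aneuploidy

Allelic balance is min(ref, alt depth) / total — symmetric, since neither
allele is privileged; calls *below* 0.3 are removed, the boundary is kept.
Windows with zero variants are excluded from the strain median (the ratio
is undefined there), and trailing partial windows at chromosome ends are
retained to avoid discarding subtelomeric signal.

The ploidy caller histograms alt-depth fractions at het sites into 25 bins
on (0,1); peaks are local maxima holding > 5% of mass; a triploid needs
peaks within ±0.08 of both ⅓ and ⅔, a diploid a peak within ±0.08 of ½;
anything else — including strains with fewer than 200 usable het sites —
is indeterminate.  The tolerance and bin count are stable for depth ≥ 30;
nearly homozygous strains are genuinely indeterminate by this method, as
they are in practice (flow cytometry is the primary assay there and is out
of scope).

Aneuploidy: per chromosome, copy estimate = ploidy × median(bin depth) /
genome-wide median(bin depth); a call requires |estimate − ploidy| ≥ 0.5.
The 0.5-copy rule formalizes what is otherwise a visual judgement on
coverage plots.  Using the median over 10 kb bins makes the "sustained over
the whole chromosome" requirement concrete and robust to focal CNVs.

## Population statistics

π is per-site: the sum over sites of 2j(n−j)/(n(n−1)) divided by the number
of spanned positions, monomorphic sites included in the denominator — this
keeps π on the 10⁻³ scale conventional for yeast.  Tajima's D uses the
standard 1989 constants; sites with missing genotypes inside the group are
excluded so n is constant; S = 0 reports NA.  Weir–Cockerham Fst computes
the per-site a, b, c components from sample sizes, allele frequencies and
observed heterozygosity, and windows report both the weighted ratio
Σa/Σ(a+b+c) and the mean of per-site ratios (the quoted tool's two
columns).  The ABBA-BABA statistic is frequency-weighted with sites
polarized by the outgroup major allele; Z comes from a delete-one jackknife
over 20 contiguous equal-site blocks (configurable).  f4-ratios and
f-branch are out of scope; D with pattern counts and Z covers the
qualitative introgression inference.

## Loss-of-function classification

All homozygous variants passing the per-sample filter are applied jointly
to the CDS (an explicit mutated→original coordinate map keeps indel
bookkeeping exact), the result is translated, and the first stop is mapped
back to original codon coordinates.  Classification: start codon no longer
ATG → start_lost; frame offset at the first novel stop (or at CDS end if no
stop) not divisible by 3 → frameshift; otherwise a stop at original codon
c is stop_gained iff c ≤ floor(0.98 × codon count) — the 98% rule is
measured in codons, the natural unit of a coding region.  Applying variants
jointly is what makes compensated frameshift pairs benign and is the point
of reimplementing the per-variant view of generic effect predictors.
Heterozygous variants never contribute.  Splice/intron structure is not
modeled (single-CDS gene models); an external deleteriousness scorer
(SIFT-style) is out of scope.

K-means on the binary LOF matrix uses Euclidean distance, 10 k-means++
restarts, fixed seed.  The gap statistic draws B = 50 uniform reference
datasets over the feature bounding box and chooses the smallest k with
Gap(k) ≥ Gap(k+1) − s(k+1).  On near-duplicate binary rows the criterion
can overshoot (splitting discrete noise still shrinks log W quickly), so
the planted-recovery test uses a 36 × 60 fixture at 2% bit-flip noise where
selection is stable; a fixed k (e.g. 16) can always be supplied for
report generation.

## Copy number, gene loss, differential CNV

log2 ratio = log2(segment depth / base coverage), base coverage being the
sample median of length-normalized ORF depths; zero depth is clamped to 0.5
reads so the ratio stays finite (such ORFs round to CN 0 downstream).
CN = ploidy × 2^(log2 ratio), so the median gene sits exactly at the ploidy
and the estimate is scale-invariant.  The binned log2 track is smoothed
with a fixed-parameter three-state Gaussian HMM (means −1/0/+1, σ from the
track's MAD with a 0.05 floor, stay-probability 0.99) and Viterbi-decoded;
adjacent same-state bins merge into segments.  No GC or mappability
correction is attempted (depth tables, not alignments, are the input).

Rounding: CN ≤ 0.7 → 0, else nearest integer half-away-from-zero (so
1.5 → 2, consistent with the gene-loss cap); gene-loss mode caps values
> 1.5 at 2.  Gene-loss accounting is literal: total = 2N − ΣCN,
hom = #{CN=0}, het = total − hom.  Note the literal definition makes a
homozygously lost ORF contribute one "heterozygous" unit as well; it is
kept because it preserves the Δtotal = Δhom + Δhet additivity used in
between-group comparisons, and #{CN=1} is reported alongside as the
unambiguous single-copy count.  Group comparisons use two-sided Wilcoxon
rank-sum tests with group means and mean differences reported; all-tied
comparisons report p = 1.

Differential CNV: keep ORFs at or above the median CN variance (exactly
⌈N/2⌉ when variances are distinct), round in differential mode, Kruskal–
Wallis across groups, Benjamini–Hochberg over all tested ORFs, then the
effect filter (rounded group mean > 2.5 or < 1 in ≥ 1 group).  BH is
applied before the effect filter so q-values do not depend on it.  Groups
with fewer than two strains are excluded; the analyses are defined for
diploids and non-diploid strains are dropped with a warning.

## Accessory genome

ORFs are maximal ATG..stop spans in all six frames, kept when strictly
longer than 180 bp, reported in coding orientation.  Greedy clustering
visits ORFs longest-first (ties by id); identity = matching bases in the
best local alignment divided by the shorter length, matching the greedy
incremental tool the procedure emulates; the founder (longest member) is
the representative.  The filter cascade drops clusters without focal-strain
members, then member sequences lacking start or stop (re-electing the
representative if needed), then clusters whose representative is not
carried full-length (≥ 99% of representative length at ≥ 97% identity) by
any focal strain — each step's count is logged.

Presence calls use local alignment with match +2 / mismatch −3 / gap
open 5 / extend 2 and the corresponding Karlin–Altschul bit score
(λ = 0.625, K = 0.41), standard nucleotide-search scoring: absent without a
hit at E ≤ 10⁻⁶ and bit-score ratio ≥ 0.4; full at query coverage ≥ 0.99
and identity ≥ 0.97; partial otherwise.  An 11-mer prefilter skips pairs
sharing no 11-mer; at ≥ 97% identity and length ≥ 180 a sequence has at
most ⌊L/34⌋ mismatches, too few to break every one of the L−10 overlapping
11-mers, so the prefilter cannot drop a qualifying pair.

## Problem sizes and determinism

The defaults are chosen so the full test suite runs in about a minute and
the acceptance script in under a minute on one CPU: default cohort
29 strains / 800 kb / ~69 k variants; planted-recovery cohort 40 strains /
300 kb; null calibration 1,000 ORFs × 40 strains; ploidy benchmark 100
strains × 1,000 sites.  Every stochastic step draws from a generator seeded
from a single configuration seed; identical seeds give byte-identical
outputs, which the pipeline manifest verifies by checksum.

## Known limitations

- The star phylogeny has no within-group structure, so estimators that
  exploit linkage or topology (beyond windowed statistics) are not
  stress-tested.
- LOF validation relies on the coding-truth exhaustiveness above.
- The ploidy caller distinguishes only diploid and triploid; higher
  ploidies and mosaic aneuploidy are out of scope.
- Fst windows use the two-population estimator only; multi-population
  variants of the components are not implemented.
- The alignment engine is exact but not optimized for large pangenomes;
  clustering thousands of ORFs is minutes-scale, not seconds-scale.
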