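"""Gene-loss accounting and differential copy-number analysis.

Continuous per-ORF CN is rounded with the study's rules: values at or below
0.7 are absent (CN 0), anything else rounds to the nearest integer (half
away from zero); gene-loss mode additionally caps values above 1.5 at 2, so
a diploid ORF is scored 0, 1 or 2.  Per strain, total gene loss is the
number of missing copies (2 x N_ORFs - sum of rounded CN), homozygous loss
the number of ORFs at CN 0, and the heterozygous metric their difference --
the study's literal definition, under which a homozygously lost ORF also
contributes one heterozygous-loss unit; the single-copy count #{CN=1} is
reported alongside as an alternative.  Differential CNV keeps the top half
of ORFs by CN variance, tests each across groups with Kruskal-Wallis,
adjusts with Benjamini-Hochberg, and flags genes whose group mean CN exceeds
2.5 or falls below 1 in at least one group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ABSENCE_THRESHOLD = 0.7
GENELOSS_CAP_ABOVE = 1.5
EFFECT_HIGH = 2.5
EFFECT_LOW = 1.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def round_cn(
    cn: pd.DataFrame,
    mode: str,
    ploidy: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Round continuous CN per the study's rules.

    Both modes: CN <= 0.7 -> 0, otherwise nearest integer (half away from
    zero).  ``geneloss`` mode additionally maps every value > 1.5 to 2, so
    outputs lie in {0, 1, 2}.  Strains with ploidy != 2 are excluded with a
    warning (the analyses are defined for diploids).  Idempotent.
    """
    if mode not in ("geneloss", "differential"):
        raise ValueError(f"unknown mode {mode!r}")
    table = cn.copy()
    if ploidy is not None:
        non_diploid = [s for s in table.index if ploidy.get(s, 2) != 2]
        if non_diploid:
            logger.warning("excluding non-diploid strains: %s", ", ".join(non_diploid))
            table = table.drop(index=non_diploid)
    values = table.to_numpy(dtype=float)
    out = np.where(values <= ABSENCE_THRESHOLD, 0.0, _round_half_away(values))
    if mode == "geneloss":
        out = np.where(values > GENELOSS_CAP_ABOVE, 2.0, out)
        out = np.minimum(out, 2.0)
    return pd.DataFrame(out.astype(int), index=table.index, columns=table.columns)


def gene_loss_accounting(rounded: pd.DataFrame) -> pd.DataFrame:
    """Per-strain loss summary from a gene-loss-mode table (values in {0,1,2}).

    total_loss = 2 x N_ORFs - sum(CN); hom_loss = #{CN=0};
    het_loss = total_loss - hom_loss; n_single_copy = #{CN=1}.
    """
    values = rounded.to_numpy()
    if not np.isin(values, (0, 1, 2)).all():
        raise ValueError("gene-loss accounting expects CN values in {0, 1, 2}")
    n_orfs = rounded.shape[1]
    total = 2 * n_orfs - values.sum(axis=1)
    hom = (values == 0).sum(axis=1)
    return pd.DataFrame(
        {
            "strain": rounded.index,
            "total_loss": total,
            "hom_loss": hom,
            "het_loss": total - hom,
            "n_single_copy": (values == 1).sum(axis=1),
        }
    ).set_index("strain")


def compare_group_loss(
    summaries: pd.DataFrame,
    assignment: dict[str, str],
    metrics: tuple[str, ...] = ("total_loss", "hom_loss", "het_loss"),
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of gene loss between groups.

    One row per (group pair, metric) with group means, the mean difference
    and the p-value; degenerate all-tied comparisons report p = 1.
    """
    groups: dict[str, list[str]] = {}
    for strain in summaries.index:
        label = assignment.get(strain)
        if label is not None:
            groups.setdefault(label, []).append(strain)
    labels = sorted(groups)
    for label in labels:
        if len(groups[label]) < 2:
            raise ValueError(f"group {label} has fewer than 2 strains")
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            for metric in metrics:
                a = summaries.loc[groups[ga], metric].to_numpy(dtype=float)
                b = summaries.loc[groups[gb], metric].to_numpy(dtype=float)
                if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                    p = 1.0
                    note = "all values tied"
                else:
                    p = float(stats.ranksums(a, b).pvalue)
                    note = ""
                rows.append(
                    {
                        "group_a": ga, "group_b": gb, "metric": metric,
                        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                        "mean_diff": float(a.mean() - b.mean()),
                        "p_value": p, "note": note,
                    }
                )
    return pd.DataFrame(rows)


def differential_cnv(
    cn: pd.DataFrame,
    assignment: dict[str, str],
    p_cutoff: float = 0.05,
    fdr: float = 0.05,
    variance_quantile: float = 0.5,
    effect_high: float = EFFECT_HIGH,
    effect_low: float = EFFECT_LOW,
) -> pd.DataFrame:
    """Differential ORF copy number across strain groups.

    Pipeline: (1) keep ORFs in the top half of CN variance across strains;
    (2) round (differential mode); (3) Kruskal-Wallis across groups per ORF;
    (4) Benjamini-Hochberg over all tested ORFs; (5) flag ORFs whose rounded
    group mean CN is > ``effect_high`` or < ``effect_low`` in at least one
    group.  ``significant`` requires p <= p_cutoff, q <= fdr and the effect
    flag.  Groups with fewer than 2 strains are excluded with a warning.
    """
    groups: dict[str, list[str]] = {}
    for strain in cn.index:
        label = assignment.get(strain)
        if label is not None:
            groups.setdefault(label, []).append(strain)
    for label in list(groups):
        if len(groups[label]) < 2:
            logger.warning("group %s has < 2 strains; excluded from the test", label)
            del groups[label]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 strains")
    labels = sorted(groups)

    variances = cn.var(axis=0, ddof=1)
    keep = variances >= variances.median()
    tested = cn.loc[:, keep.index[keep]]
    rounded = round_cn(tested, "differential")

    h_vals, p_vals = [], []
    for gene in rounded.columns:
        samples = [rounded.loc[groups[g], gene].to_numpy(dtype=float) for g in labels]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            h_vals.append(0.0)
            p_vals.append(1.0)
        else:
            res = stats.kruskal(*samples)
            h_vals.append(float(res.statistic))
            p_vals.append(float(res.pvalue))
    q_vals = multipletests(p_vals, alpha=fdr, method="fdr_bh")[1]

    records = []
    for gi, gene in enumerate(rounded.columns):
        means = {g: float(rounded.loc[groups[g], gene].mean()) for g in labels}
        effect = any(m > effect_high or m < effect_low for m in means.values())
        rec = {
            "gene": gene,
            "kruskal_h": h_vals[gi],
            "p_value": p_vals[gi],
            "q_value": float(q_vals[gi]),
            "variance": float(variances[gene]),
            "variance_rank_kept": True,
            "effect_flag": effect,
            "significant": bool(
                p_vals[gi] <= p_cutoff and q_vals[gi] <= fdr and effect
            ),
        }
        for g in labels:
            rec[f"mean_cn_{g}"] = means[g]
        records.append(rec)
    return pd.DataFrame(records)
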