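"""End-to-end orchestration of the cohort analyses.

``run_pipeline`` executes the stages in dependency order -- simulate,
variant filtering, heterozygosity/ploidy/aneuploidy, popgen statistics, LOF
annotation and clustering, copy number, gene loss and differential CNV, and
accessory-genome presence -- writing one TSV per stage plus a manifest
recording the seed, every threshold, per-stage row counts and output
checksums.  All thresholds default to the study's quoted values, collected
in :class:`PipelineDefaults`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from yeastcohort import synthetic
from yeastcohort.accessory import classify_presence, filter_clusters, greedy_cluster, OrfSeq
from yeastcohort.cn_comparative import (
    compare_group_loss,
    differential_cnv,
    gene_loss_accounting,
    round_cn,
)
from yeastcohort.copy_number import cn_profiles
from yeastcohort.het_ploidy import (
    allelic_balance_filter,
    call_aneuploidy,
    compute_heterozygosity,
    infer_ploidy,
)
from yeastcohort.lof import (
    GeneModel,
    build_lof_matrix,
    classify_cohort_lof,
    select_k_gap,
)
from yeastcohort.popgen import abba_baba, nucleotide_diversity, tajimas_d, wc_fst
from yeastcohort.variant_io import FilterSpec, filter_sites, ld_prune, to_genotype_matrix, write_vcf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineDefaults:
    """Every analysis threshold, at the study's quoted value."""

    max_missing: float = 1.0
    remove_indels: bool = True
    mac: int = 3
    min_qual: float = 10.0
    ld_window_sites: int = 50
    ld_step_sites: int = 5
    ld_r2: float = 0.5
    allelic_balance_min: float = 0.3
    het_window_bp: int = 50_000
    het_step_bp: int = 25_000
    fst_window_bp: int = 10_000
    min_sample_depth: int = 10
    min_sample_quality: float = 10.0
    cds_stop_fraction: float = 0.98
    cn_absent_threshold: float = 0.7
    cn_geneloss_cap: float = 1.5
    cn_effect_high: float = 2.5
    cn_effect_low: float = 1.0
    fdr: float = 0.05
    p_cutoff: float = 0.05
    cluster_identity: float = 0.97
    min_orf_bp: int = 180
    bsr_min: float = 0.4
    e_max: float = 1e-6
    full_coverage: float = 0.99
    dstat_blocks: int = 20
    aneuploidy_bin_bp: int = 10_000


DEFAULT_STAGES = (
    "simulate", "filter", "het_ploidy", "popgen", "lof", "copy_number", "pangenome",
)


@dataclass
class RunConfig:
    """Pipeline configuration: cohort scale, stage toggles and thresholds."""

    seed: int = 0
    cohort: synthetic.CohortConfig | None = None
    stages: tuple[str, ...] = DEFAULT_STAGES
    thresholds: PipelineDefaults = field(default_factory=PipelineDefaults)
    gap_k_max: int = 8
    gap_b_reference: int = 20


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the enabled stages; returns the manifest (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "seed": config.seed,
        "thresholds": asdict(thr),
        "stages": {},
    }
    enabled = set(config.stages)

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}

    if "simulate" not in enabled:
        raise ValueError("pipeline requires the simulate stage (no external inputs)")
    t0 = time.time()
    cohort_config = config.cohort or synthetic.CohortConfig(seed=config.seed)
    if cohort_config.seed != config.seed:
        cohort_config = synthetic.CohortConfig(
            **{**asdict_config(cohort_config), "seed": config.seed}
        )
    cohort = synthetic.simulate_cohort(cohort_config)
    genes = cohort.genes["gene_id"].tolist()
    strains = cohort.strains
    # default plantings exercise every downstream stage
    lof_spec = [
        (strains[0], genes[0], "frameshift"),
        (strains[1], genes[1], "stop_gained"),
        (strains[2], genes[2], "start_lost"),
        (strains[3], genes[3], "compensated_pair"),
        (strains[4], genes[4], "late_stop"),
    ]
    synthetic.plant_lof_variants(cohort, lof_spec)
    group_of = cohort.groups
    first_group = cohort.config.group_specs[0].label
    amplified = [s for s in strains if group_of[s] == first_group][:3]
    synthetic.plant_cn_events(
        cohort,
        [(s, genes[10], 4) for s in amplified] + [(strains[0], genes[11], 0)],
    )
    synthetic.plant_aneuploidy(cohort, [(strains[0], cohort.config.chrom_names[-1], 1)])
    synthetic.plant_accessory_content(
        cohort, n_clusters=8, hgt_cluster_size=5,
        carrier_fraction={g.label: f for g, f in zip(
            cohort.config.group_specs, (0.8, 0.3, 0.9, 0.0))},
    )
    synthetic.write_cohort(cohort, out / "cohort")
    record("simulate", t0, n_strains=len(strains), n_variants=len(cohort.variants))

    sites = cohort.variants
    chrom_lengths = {c: len(s) for c, s in cohort.reference.items()}
    groups_by_label: dict[str, list[str]] = {}
    for s in strains:
        groups_by_label.setdefault(group_of[s], []).append(s)

    if "filter" in enabled:
        t0 = time.time()
        spec = FilterSpec(
            max_missing=thr.max_missing, remove_indels=thr.remove_indels,
            mac=thr.mac, min_qual=thr.min_qual,
        )
        filtered = filter_sites(sites, spec)
        matrix = to_genotype_matrix(filtered, strains, snps_only=True)
        pruned = ld_prune(matrix, thr.ld_window_sites, thr.ld_step_sites, thr.ld_r2)
        write_vcf(filtered, str(out / "filtered.vcf"), strains, chrom_lengths)
        pruned.to_tsv(str(out / "ld_pruned_matrix.tsv"))
        record("filter", t0, n_input=len(sites), n_filtered=len(filtered),
               n_pruned=pruned.n_sites)

    if "het_ploidy" in enabled:
        t0 = time.time()
        ab_sites = allelic_balance_filter(sites, thr.allelic_balance_min)
        matrix_all = to_genotype_matrix(ab_sites, strains)
        profiles = compute_heterozygosity(
            matrix_all, chrom_lengths, thr.het_window_bp, thr.het_step_bp
        )
        het_df = pd.DataFrame(
            {
                "strain": strains,
                "group": [group_of[s] for s in strains],
                "percent_heterozygosity": [
                    profiles[s].percent_heterozygosity for s in strains
                ],
            }
        )
        het_df.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        ploidy_rows = []
        for s in strains:
            call = infer_ploidy(sites, s)
            ploidy_rows.append(
                {"strain": s, "ploidy": call.label, "n_het_sites": call.n_het_sites}
            )
        pd.DataFrame(ploidy_rows).to_csv(out / "ploidy.tsv", sep="\t", index=False)
        aneu_rows = []
        for s in strains:
            for call in call_aneuploidy(cohort.coverage_bins, s, cohort.ploidy[s]):
                aneu_rows.append(
                    {"strain": s, "chrom": call.chrom, "delta": call.delta,
                     "estimate": call.estimate}
                )
        pd.DataFrame(aneu_rows, columns=["strain", "chrom", "delta", "estimate"]).to_csv(
            out / "aneuploidy.tsv", sep="\t", index=False
        )
        record("het_ploidy", t0, n_strains=len(strains), n_aneuploidies=len(aneu_rows))

    if "popgen" in enabled:
        t0 = time.time()
        matrix = to_genotype_matrix(sites, strains, snps_only=True)
        span = sum(chrom_lengths.values())
        div_rows = []
        for label, members in groups_by_label.items():
            pi = nucleotide_diversity(matrix, members, span, group=label)
            taj = tajimas_d(matrix, members, group=label) if len(members) >= 2 else None
            div_rows.append(
                {"group": label, "pi": pi.pi, "S": pi.S,
                 "tajimas_d": None if taj is None else taj.tajimas_d,
                 "n_haplotypes": pi.n_haplotypes}
            )
        pd.DataFrame(div_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
        labels = sorted(groups_by_label)
        fst_frames = []
        for i, ga in enumerate(labels):
            for gb in labels[i + 1 :]:
                win = wc_fst(matrix, groups_by_label[ga], groups_by_label[gb],
                             thr.fst_window_bp)
                win.insert(0, "pair", f"{ga}-{gb}")
                fst_frames.append(win)
        fst_all = pd.concat(fst_frames, ignore_index=True)
        fst_all.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        dstat_row = []
        if len(labels) >= 4:
            p1, p2, p3, og = labels[:4]
            res = abba_baba(matrix, groups_by_label[p1], groups_by_label[p2],
                            groups_by_label[p3], groups_by_label[og],
                            thr.dstat_blocks)
            dstat_row.append(
                {"trio": f"({p1},{p2};{p3})", "outgroup": og, "abba": res.abba,
                 "baba": res.baba, "bbaa": res.bbaa, "d": res.d, "z": res.z}
            )
        pd.DataFrame(dstat_row).to_csv(out / "dstat.tsv", sep="\t", index=False)
        record("popgen", t0, n_groups=len(labels), n_fst_windows=len(fst_all))

    if "lof" in enabled:
        t0 = time.time()
        models = [GeneModel.from_annotation(r) for _, r in cohort.genes.iterrows()]
        calls = classify_cohort_lof(
            sites, models, cohort.reference, strains,
            thr.min_sample_depth, thr.min_sample_quality,
        )
        call_df = pd.DataFrame(
            [
                {"strain": c.strain, "gene": c.gene, "class": c.lof_class}
                for c in calls
                if c.is_lof
            ],
            columns=["strain", "gene", "class"],
        )
        call_df.to_csv(out / "lof_calls.tsv", sep="\t", index=False)
        lof_matrix = build_lof_matrix(calls, genes, strains)
        lof_matrix.to_csv(out / "lof_matrix.tsv", sep="\t", index_label="gene")
        affected = lof_matrix.loc[lof_matrix.sum(axis=1) > 0]
        if len(affected) >= 2:
            cluster = select_k_gap(
                affected, k_max=min(config.gap_k_max, len(affected)),
                b_reference=config.gap_b_reference, seed=config.seed,
            )
            cluster.assignments.to_csv(out / "lof_clusters.tsv", sep="\t",
                                       index_label="gene")
            cluster.gap_table.to_csv(out / "gap_curve.tsv", sep="\t", index=False)
            chosen_k = cluster.k
        else:
            chosen_k = 0
        record("lof", t0, n_lof_calls=len(call_df), n_lof_genes=int(
            (lof_matrix.sum(axis=1) > 0).sum()), chosen_k=chosen_k)

    if "copy_number" in enabled:
        t0 = time.time()
        profiles_cn = cn_profiles(cohort.orf_depth, cohort.ploidy)
        profiles_cn.to_csv(out / "cn_profiles.tsv", sep="\t", index_label="strain")
        diploids = {s: p for s, p in cohort.ploidy.items() if p == 2}
        cn_dip = profiles_cn.loc[list(diploids)]
        rounded = round_cn(cn_dip, "geneloss", cohort.ploidy)
        losses = gene_loss_accounting(rounded)
        losses.to_csv(out / "gene_loss.tsv", sep="\t")
        loss_tests = compare_group_loss(losses, group_of)
        loss_tests.to_csv(out / "gene_loss_tests.tsv", sep="\t", index=False)
        diff = differential_cnv(cn_dip, group_of, thr.p_cutoff, thr.fdr)
        diff.to_csv(out / "differential_cnv.tsv", sep="\t", index=False)
        record("copy_number", t0, n_diploids=len(cn_dip),
               n_diff_tested=len(diff),
               n_diff_significant=int(diff["significant"].sum()))

    if "pangenome" in enabled:
        t0 = time.time()
        all_orfs = [
            OrfSeq(oid, strain, seq)
            for strain, seqs in cohort.orf_seqs.items()
            for oid, seq in seqs.items()
        ]
        if all_orfs:
            clusters = greedy_cluster(all_orfs, thr.cluster_identity)
            orfs_by_id = {o.id: o for o in all_orfs}
            kept, cascade = filter_clusters(
                clusters, orfs_by_id, set(strains), thr.cluster_identity,
                thr.full_coverage,
            )
            cascade.to_csv(out / "cluster_cascade.tsv", sep="\t", index=False)
            reps = {c.representative_id: orfs_by_id[c.representative_id].seq
                    for c in kept}
            presence = classify_presence(
                reps, cohort.orf_seqs, thr.bsr_min, thr.e_max,
                thr.full_coverage, thr.cluster_identity,
            )
            presence.to_csv(out / "presence_matrix.tsv", sep="\t",
                            index_label="cluster")
            record("pangenome", t0, n_orfs=len(all_orfs), n_clusters=len(clusters),
                   n_kept=len(kept))
        else:
            record("pangenome", t0, n_orfs=0, n_clusters=0, n_kept=0)

    manifest["outputs"] = {
        p.name: _checksum(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def asdict_config(config: synthetic.CohortConfig) -> dict:
    d = asdict(config)
    d["group_specs"] = tuple(
        synthetic.GroupSpec(**g) if isinstance(g, dict) else g
        for g in d["group_specs"]
    )
    return d
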