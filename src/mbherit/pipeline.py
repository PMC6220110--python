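"""End-to-end orchestration: simulate -> QC -> taxa -> relatedness ->
diversity -> heritability -> GWAS -> summary report.

The pipeline runs on a synthetic cohort with known ground truth (or on
user-supplied files for individual stages via the library API), with every
analysis threshold at its standard default: QC at call
rate >= 0.95, MAF >= 0.05, HWE P > 5e-6; prevalence classes at >95% (core)
and 20-95% (random); heritable taxa at h^2 > 0.15; genome-wide and
suggestive Bonferroni thresholds 0.05/p and 1/p; lambda filter [0.99,
1.06]; LD clumping at r^2 >= 0.8.  A fixed seed makes the whole run
bit-identical.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simdata, io_qc, taxa, relatedness, diversity, heritability, mbgwas


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "mbherit_run"
    # cohort generation
    n_founder_pairs: int = 16
    n_halfsib_sires: int = 12
    offspring_per_mating: int = 3
    n_batches: int = 2
    n_snps: int = 1500
    maf_low: float = 0.10
    maf_high: float = 0.50
    missing_rate: float = 0.02
    n_hwe_violators: int = 2
    n_monomorphic: int = 3
    n_otus: int = 60
    n_heritable: int = 10
    pve_target: float = 0.40
    n_causal: int = 3
    zero_inflation_rate: float = 0.30
    depth_range: tuple[int, int] = (10_000, 20_000)
    n_genes: int = 120
    # genotype QC thresholds
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 5e-6
    # taxa
    core_min: float = 0.95
    random_min: float = 0.20
    # relatedness / diversity
    mantel_perms: int = 999
    diversity_mc: int = 1000
    # heritability
    h2_mcmc: int = 4000
    h2_threshold: float = 0.15
    h2_max_taxa: int = 15
    # GWAS
    r2_min: float = 0.8
    gc_unconditional: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "depth_range" in raw:
            raw["depth_range"] = tuple(raw["depth_range"])
        return cls(**raw)


@dataclass
class SummaryReport:
    seed: int
    n_samples: int = 0
    n_input_snps: int = 0
    n_pass_snps: int = 0
    genome_wide_threshold: float = 0.0
    suggestive_threshold: float = 0.0
    taxa_core: int = 0
    taxa_random: int = 0
    taxa_discarded: int = 0
    mantel_r: float = 0.0
    mantel_p: float = 1.0
    group_comparison_p: dict = field(default_factory=dict)
    n_heritable: int = 0
    n_h2_tested: int = 0
    n_assoc_genome_wide: int = 0
    n_assoc_suggestive: int = 0
    n_loci: int = 0
    loci: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def fraction_summary(labels: pd.Series | pd.DataFrame, grouping: str | None = None) -> pd.DataFrame:
    """Percentage tabulation of a classification column.

    Returns one row per group with numerator, denominator and
    percent = 100 * count / total rounded to 2 decimals.
    """
    if isinstance(labels, pd.DataFrame):
        if grouping is None:
            raise ValueError("grouping column required for a DataFrame input")
        series = labels[grouping]
    else:
        series = labels
    if len(series) == 0:
        raise ValueError("empty classification table")
    total = len(series)
    counts = series.value_counts()
    return pd.DataFrame({
        "group": counts.index,
        "count": counts.to_numpy(),
        "total": total,
        "percent": np.round(100.0 * counts.to_numpy() / total, 2),
    }).reset_index(drop=True)


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.default_rng([stage, base]).integers(2 ** 31))


def run_pipeline(cfg: PipelineConfig) -> SummaryReport:
    """Execute every stage, persisting intermediate tables under
    `cfg.out_dir` and returning (and writing) the summary report."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = SummaryReport(seed=cfg.seed)
    stage = "simdata"
    try:
        # --- simulate cohort -------------------------------------------------
        ped = simdata.simulate_pedigree(
            cfg.n_founder_pairs, cfg.n_halfsib_sires, cfg.offspring_per_mating,
            n_batches=cfg.n_batches, seed=_stage_seed(cfg.seed, 0))
        G_all = simdata.simulate_genotypes(
            ped, cfg.n_snps, cfg.maf_low, cfg.maf_high, cfg.missing_rate,
            cfg.n_hwe_violators, cfg.n_monomorphic, seed=_stage_seed(cfg.seed, 1))
        off = ped.offspring
        samples = list(off.animal_id)
        keep = [G_all.samples.index(a) for a in samples]
        G = io_qc.GenotypeMatrix(samples, G_all.snps.copy(), G_all.dosage[keep])
        ped.write_tsv(out / "pedigree.tsv")
        io_qc.write_genotypes(G, out / "genotypes.tsv", "dosage_tsv")
        report.n_samples = len(samples)

        # generative kinship for trait simulation (pre-QC, imputed)
        K_gen = relatedness.snp_kinship(io_qc.mean_impute(G))
        sex = off.sex.to_numpy()
        batch = off.batch.to_numpy()
        truths, traits_sim = [], []
        for t in range(cfg.n_heritable):
            truth = simdata.SimTruth(
                pve_target=cfg.pve_target, n_causal=cfg.n_causal,
                zero_inflation_rate=cfg.zero_inflation_rate,
                covariate_effects={"sex": 0.3, "batch": 0.3},
                seed=_stage_seed(cfg.seed, 100 + t))
            st = simdata.simulate_traits(G, K_gen, truth, sex=sex, batch=batch,
                                         taxon_id=f"OTU{t:04d}")
            truths.append(truth)
            traits_sim.append(st)
        otu_counts, tax, tree = simdata.simulate_otu_ecosystem(
            len(samples), cfg.n_otus, cfg.n_heritable, traits_sim,
            cfg.depth_range, seed=_stage_seed(cfg.seed, 2), sample_ids=samples)
        chrom_lengths = {c: int(G.snps.loc[G.snps.chrom == c, "pos"].max()) + 10_000
                         for c in G.snps.chrom.unique()}
        genes = simdata.simulate_gene_track(chrom_lengths, cfg.n_genes,
                                            seed=_stage_seed(cfg.seed, 3))
        otu_counts.write_tsv(out / "otu_counts.tsv")
        tax.write_tsv(out / "taxonomy.tsv")
        tree.write(str(out / "tree.nwk"))
        simdata.write_bed(genes, out / "genes.bed")
        simdata.write_truth_manifest(truths, out / "truth_manifest.json")

        # --- QC --------------------------------------------------------------
        stage = "qc"
        G_qc, qc_report = io_qc.qc_genotypes(G, cfg.call_rate_min, cfg.maf_min,
                                             cfg.hwe_p_min)
        qc_report.to_json(out / "qc_report.json")
        report.n_input_snps = qc_report.n_input_snps
        report.n_pass_snps = qc_report.n_pass
        G_imp = io_qc.mean_impute(G_qc)
        gw, sug = mbgwas.bonferroni_thresholds(G_qc.n_snps)
        report.genome_wide_threshold = gw
        report.suggestive_threshold = sug

        # --- taxa ------------------------------------------------------------
        stage = "taxa"
        relabund = taxa.relative_abundance(otu_counts)
        prevalence = taxa.classify_prevalence(relabund, cfg.core_min, cfg.random_min)
        by_cat = {c: [p for p in prevalence if p.category == c]
                  for c in ("core", "random", "discarded")}
        report.taxa_core = len(by_cat["core"])
        report.taxa_random = len(by_cat["random"])
        report.taxa_discarded = len(by_cat["discarded"])
        pd.DataFrame([(p.feature_id, p.prevalence, p.category) for p in prevalence],
                     columns=["feature_id", "prevalence", "category"]) \
            .to_csv(out / "prevalence.tsv", sep="\t", index=False)

        analyzed = by_cat["core"] + by_cat["random"]
        analyzed = sorted(analyzed, key=lambda p: (-p.prevalence, p.feature_id))
        traits: dict[str, taxa.TraitVector] = {}
        fidx = {f: j for j, f in enumerate(relabund.features)}
        for p in analyzed:
            try:
                traits[p.feature_id] = taxa.prepare_trait(
                    relabund.values[:, fidx[p.feature_id]], sex, batch, p.feature_id)
            except ValueError as exc:
                print(f"[pipeline] trait {p.feature_id} skipped: {exc}")

        # --- relatedness -----------------------------------------------------
        stage = "relatedness"
        K = relatedness.snp_kinship(G_imp)
        M = relatedness.microbiome_kinship(relabund)
        K.write_tsv(out / "kinship_snp.tsv")
        M.write_tsv(out / "kinship_microbiome.tsv")
        mantel = relatedness.mantel_test(K, M, cfg.mantel_perms,
                                         seed=_stage_seed(cfg.seed, 4))
        report.mantel_r = mantel.r
        report.mantel_p = mantel.p
        pcs = relatedness.genetic_pcs(K, 3)
        pd.DataFrame(pcs, index=samples, columns=["PC1", "PC2", "PC3"]) \
            .rename_axis("sample_id").to_csv(out / "genetic_pcs.tsv", sep="\t")

        # --- diversity -------------------------------------------------------
        stage = "diversity"
        pairs = diversity.relatedness_pairs(ped, cross_pen_only=True)
        comparison_rows = []
        for metric in ("unweighted_unifrac", "weighted_unifrac"):
            D = diversity.pairwise_distances(tree, relabund, metric)
            D.write_tsv(out / f"{metric.replace('_unifrac', '')}_unifrac.tsv")
            comps = diversity.compare_groups(D, pairs, cfg.diversity_mc,
                                             seed=_stage_seed(cfg.seed, 5))
            for c in comps:
                report.group_comparison_p[f"{metric}:{c.group_pair}"] = c.p_mc
                row = asdict(c)
                row["metric"] = metric
                comparison_rows.append(row)
        pd.DataFrame(comparison_rows) \
            .to_csv(out / "group_comparisons.tsv", sep="\t", index=False)

        # --- heritability ----------------------------------------------------
        stage = "heritability"
        h2_rows = []
        h2_taxa = list(traits)[: cfg.h2_max_taxa]
        for tid in h2_taxa:
            tv = traits[tid]
            mask = tv.presence
            Ksub = relatedness.KinshipMatrix(
                [samples[i] for i in np.flatnonzero(mask)],
                K.values[np.ix_(mask, mask)], "snp")
            cfg_b = heritability.BslmmConfig(
                n_mcmc=cfg.h2_mcmc,
                seed=(_stage_seed(cfg.seed, 6) + zlib.crc32(tid.encode())) % 2 ** 31)
            est = heritability.estimate_heritability(
                tv.adjusted, G_imp.dosage[mask], Ksub, cfg_b, tid, cfg.h2_threshold)
            h2_rows.append((tid, est.pve_point, est.ci_low, est.ci_high, est.heritable))
        h2_table = pd.DataFrame(h2_rows, columns=["taxon_id", "pve", "ci_low",
                                                  "ci_high", "heritable"])
        h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False)
        report.n_h2_tested = len(h2_table)
        report.n_heritable = int(h2_table.heritable.sum())

        # --- GWAS ------------------------------------------------------------
        stage = "gwas"
        covariates = np.column_stack([
            taxa._covariate_design(sex, batch)[:, 1:], pcs])
        assoc_frames, loci_all = [], []
        pclass_of = {p.feature_id: p for p in prevalence}
        for tid in h2_taxa:
            table, summaries = mbgwas.two_part_scan(
                traits[tid], G_imp, covariates, pclass_of[tid],
                gc_unconditional=cfg.gc_unconditional)
            if table.empty:
                continue
            kept_parts = {s.part for s in summaries if s.kept}
            table = table[table.part.isin(kept_parts)]
            assoc_frames.append(table)
            for part in kept_parts:
                sub = table[table.part == part]
                if (sub.p_gc < gw).any():
                    loci = mbgwas.define_locus(sub, G_imp, gw, cfg.r2_min)
                    for loc in loci:
                        mbgwas.nearest_gene(loc, genes)
                    loci_all.extend(loci)
        assoc = pd.concat(assoc_frames, ignore_index=True) if assoc_frames \
            else pd.DataFrame(columns=["p_gc"])
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        report.n_assoc_genome_wide = int((assoc.p_gc < gw).sum())
        report.n_assoc_suggestive = int((assoc.p_gc < sug).sum())
        report.n_loci = len(loci_all)
        report.loci = [asdict(l) for l in loci_all]
        pd.DataFrame(report.loci).to_csv(out / "loci.tsv", sep="\t", index=False)

        report.wall_time_s = round(time.time() - t0, 2)
        report.to_json(out / "report.json")
        _write_text_report(report, out / "report.txt")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_text_report(r: SummaryReport, path: Path) -> None:
    lines = [
        f"mbherit summary (seed {r.seed})",
        f"samples: {r.n_samples}",
        f"SNPs: {r.n_input_snps} input, {r.n_pass_snps} pass QC",
        f"thresholds: genome-wide {r.genome_wide_threshold:.3g}, "
        f"suggestive {r.suggestive_threshold:.3g}",
        f"taxa: {r.taxa_core} core / {r.taxa_random} random / "
        f"{r.taxa_discarded} discarded",
        f"Mantel (SNP vs microbiome kinship): r={r.mantel_r:.4f} p={r.mantel_p:.4g}",
        "group comparisons: " + ", ".join(f"{k} p={v:.4g}"
                                          for k, v in r.group_comparison_p.items()),
        f"heritable taxa (h2>0.15): {r.n_heritable} of {r.n_h2_tested} tested",
        f"associations: {r.n_assoc_genome_wide} genome-wide, "
        f"{r.n_assoc_suggestive} suggestive; {r.n_loci} loci",
        f"wall time: {r.wall_time_s}s",
    ]
    path.write_text("\n".join(lines) + "\n")
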