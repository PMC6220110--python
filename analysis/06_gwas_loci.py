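#!/usr/bin/env python
"""Two-part microbiome GWAS, genomic control, loci and nearest genes.

Scans every analyzable taxon: core taxa with the quantitative (log-normal
score) part only, random taxa with both the logistic presence/absence part
and the quantitative part.  Each part is lambda-corrected and filtered to
lambda in [0.99, 1.06]; significant SNPs are clumped into loci at
r^2 >= 0.8 and annotated with the nearest gene.  Writes association,
locus and Q-Q tables under results/gwas/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mbherit import io_qc, mbgwas, simdata, taxa
from mbherit.taxa import TraitVector

ROOT = Path(__file__).resolve().parent.parent / "results"


def _load_trait(path: Path) -> TraitVector:
    tr = pd.read_csv(path, sep="\t")
    mask = tr.presence.to_numpy(dtype=bool)
    return TraitVector(path.stem.removeprefix("trait_"), mask,
                       tr.log_abund.to_numpy(dtype=float)[mask],
                       tr.adjusted.to_numpy(dtype=float)[mask],
                       ["sex", "batch"])


def main(seed: int) -> None:
    out = ROOT / "gwas"
    out.mkdir(parents=True, exist_ok=True)
    G = io_qc.read_genotypes(ROOT / "qc" / "genotypes_imputed.tsv", "dosage_tsv")
    prev = pd.read_csv(ROOT / "traits" / "prevalence.tsv", sep="\t")
    pclass = {r.feature_id: taxa.PrevalenceClass(r.feature_id, r.prevalence,
                                                 r.category)
              for r in prev.itertuples(index=False)}
    pcs = pd.read_csv(ROOT / "relatedness" / "genetic_pcs.tsv", sep="\t",
                      index_col=0).to_numpy()
    ped = simdata.Pedigree.read_tsv(ROOT / "cohort" / "pedigree.tsv")
    off = ped.offspring.set_index("animal_id").loc[G.samples]
    covariates = np.column_stack([
        taxa._covariate_design(off.sex.to_numpy(), off.batch.to_numpy())[:, 1:],
        pcs])
    genes = simdata.read_bed(ROOT / "cohort" / "genes.bed")

    gw, sug = mbgwas.bonferroni_thresholds(G.n_snps)
    print(f"{G.n_snps} SNPs: genome-wide threshold {gw:.3g}, suggestive {sug:.3g}")

    frames, loci_all, summ_rows = [], [], []
    for path in sorted((ROOT / "traits").glob("trait_*.tsv")):
        tv = _load_trait(path)
        table, summaries = mbgwas.two_part_scan(tv, G, covariates,
                                                pclass[tv.taxon_id])
        if table.empty:
            continue
        for s in summaries:
            summ_rows.append({"taxon_id": s.taxon_id, "part": s.part,
                              "lambda": s.lam, "kept": s.kept,
                              "n_snps": s.n_snps})
        kept_parts = {s.part for s in summaries if s.kept}
        table = table[table.part.isin(kept_parts)]
        frames.append(table)
        for part in kept_parts:
            sub = table[table.part == part]
            if (sub.p_gc < gw).any():
                for loc in mbgwas.define_locus(sub, G, gw):
                    mbgwas.nearest_gene(loc, genes)
                    loci_all.append(loc)

    assoc = pd.concat(frames, ignore_index=True)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(summ_rows).to_csv(out / "scan_summaries.tsv", sep="\t",
                                   index=False)
    e, o = mbgwas.qq_data(assoc.p_raw.dropna().to_numpy())
    pd.DataFrame({"expected": e, "observed": o}).to_csv(
        out / "qq_quantitative.tsv", sep="\t", index=False)
    from dataclasses import asdict
    pd.DataFrame([asdict(l) for l in loci_all]).to_csv(
        out / "loci.tsv", sep="\t", index=False)
    print(f"{int((assoc.p_gc < gw).sum())} genome-wide and "
          f"{int((assoc.p_gc < sug).sum())} suggestive associations; "
          f"{len(loci_all)} loci defined")
    for loc in loci_all[:10]:
        print(f"  {loc.taxon_id} {loc.part} chr{loc.chrom}:"
              f"{loc.interval_start}-{loc.interval_end} top={loc.top_snp} "
              f"p={loc.top_p:.2e} gene={loc.nearest_gene} "
              f"(d={loc.gene_distance})")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
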