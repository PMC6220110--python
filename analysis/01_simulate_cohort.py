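#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates a pedigreed pig population: full-sib families from pairs of
parents, half-sib families from shared sires, offspring randomly penned,
SNP genotypes transmitted Mendelianly from founders (with planted QC
artifacts), 20 host-heritable taxa (generative PVE 0.4, 20% zero
inflation) among 60 OTUs, a random phylogeny, lineages and a gene track.

Writes everything under results/cohort/.
"""

import argparse
from pathlib import Path

import numpy as np

from mbherit import io_qc, relatedness, simdata

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ped = simdata.simulate_pedigree(20, 20, 4, seed=seed)
    off = ped.offspring
    print(f"pedigree: {len(off)} offspring, "
          f"{len(ped.table) - len(off)} founders, "
          f"{off.pen.nunique()} pens")

    G_all = simdata.simulate_genotypes(ped, 2000, 0.1, 0.5,
                                       missing_rate=0.02, n_hwe_violators=3,
                                       n_monomorphic=4, seed=seed + 1)
    keep = [G_all.samples.index(a) for a in off.animal_id]
    G = io_qc.GenotypeMatrix(list(off.animal_id), G_all.snps.copy(),
                             G_all.dosage[keep])
    K = relatedness.snp_kinship(io_qc.mean_impute(G))

    rng = np.random.default_rng(seed + 4)
    snp_ids = list(G.snps.snp_id)
    truths, traits = [], []
    for t in range(20):
        # five taxa also carry a SNP shifting the presence liability,
        # giving the logistic GWAS part a detectable planted signal
        liability_snp = snp_ids[int(rng.integers(len(snp_ids)))] if t < 5 else None
        truth = simdata.SimTruth(pve_target=0.4, n_causal=3,
                                 zero_inflation_rate=0.2,
                                 binary_effect_snp=liability_snp,
                                 covariate_effects={"sex": 0.3, "batch": 0.3},
                                 seed=seed + 100 + t)
        st = simdata.simulate_traits(G, K, truth, sex=off.sex.to_numpy(),
                                     batch=off.batch.to_numpy(),
                                     taxon_id=f"OTU{t:04d}")
        truths.append(truth)
        traits.append(st)
    print(f"simulated 20 heritable taxa, realized PVE "
          f"{np.mean([t.realized_pve for t in traits]):.3f}")

    table, tax, tree = simdata.simulate_otu_ecosystem(
        len(off), 60, 20, traits, (10_000, 20_000), seed=seed + 2,
        sample_ids=list(off.animal_id))
    chrom_lengths = {c: int(G.snps.loc[G.snps.chrom == c, "pos"].max()) + 10_000
                     for c in G.snps.chrom.unique()}
    genes = simdata.simulate_gene_track(chrom_lengths, 150, seed=seed + 3)

    ped.write_tsv(OUT / "pedigree.tsv")
    io_qc.write_genotypes(G, OUT / "genotypes.tsv", "dosage_tsv")
    table.write_tsv(OUT / "otu_counts.tsv")
    tax.write_tsv(OUT / "taxonomy.tsv")
    tree.write(str(OUT / "tree.nwk"))
    simdata.write_bed(genes, OUT / "genes.bed")
    simdata.write_truth_manifest(truths, OUT / "truth_manifest.json")
    print(f"cohort written to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
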