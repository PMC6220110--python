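#!/usr/bin/env python
"""Host kinship vs microbiome composition.

Computes the centered genomic relationship matrix from the QC'd genotypes
and the analogous composition-based kinship from OTU relative abundances,
tests their correlation with a Mantel permutation test, extracts the top
genetic principal components, and compares UniFrac distances among
full-sib, half-sib and unrelated (cross-pen) pairs with Monte-Carlo
t-tests.  Writes matrices and comparison tables under results/relatedness/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from mbherit import diversity, io_qc, relatedness, simdata, taxa

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    out = ROOT / "relatedness"
    out.mkdir(parents=True, exist_ok=True)
    G = io_qc.read_genotypes(ROOT / "qc" / "genotypes_imputed.tsv", "dosage_tsv")
    counts = taxa.OTUTable.read_tsv(ROOT / "cohort" / "otu_counts.tsv")
    rel = taxa.relative_abundance(counts)
    ped = simdata.Pedigree.read_tsv(ROOT / "cohort" / "pedigree.tsv")
    tree = TreeNode.read(str(ROOT / "cohort" / "tree.nwk"))

    K = relatedness.snp_kinship(G)
    Mk = relatedness.microbiome_kinship(rel)
    K.write_tsv(out / "kinship_snp.tsv")
    Mk.write_tsv(out / "kinship_microbiome.tsv")

    res = relatedness.mantel_test(K, Mk, n_perm=9999, seed=seed)
    print(f"Mantel(SNP kinship, microbiome kinship): r={res.r:.4f} "
          f"p={res.p:.4g} ({res.n_perm} permutations)")

    pcs = relatedness.genetic_pcs(K, 3)
    pd.DataFrame(pcs, index=K.samples, columns=["PC1", "PC2", "PC3"]) \
        .rename_axis("sample_id").to_csv(out / "genetic_pcs.tsv", sep="\t")

    pairs = diversity.relatedness_pairs(ped, cross_pen_only=True)
    print("cross-pen pairs:", {k: len(v) for k, v in pairs.items()})
    rows = []
    for metric in ("unweighted_unifrac", "weighted_unifrac"):
        D = diversity.pairwise_distances(tree, rel, metric)
        D.write_tsv(out / f"{metric}.tsv")
        idx = {s: i for i, s in enumerate(D.samples)}
        means = {g: np.mean([D.values[idx[a], idx[b]] for a, b in pl])
                 for g, pl in pairs.items()}
        print(f"{metric}: mean distance fullsib={means['fullsib']:.4f} "
              f"halfsib={means['halfsib']:.4f} unrelated={means['unrelated']:.4f}")
        for c in diversity.compare_groups(D, pairs, n_mc=1000, seed=seed):
            print(f"  {c.group_pair}: t={c.t_stat:.3f} p={c.p_mc:.4g}")
            rows.append({"metric": metric, "group_pair": c.group_pair,
                         "t": c.t_stat, "p_mc": c.p_mc,
                         "n_a": c.n_a, "n_b": c.n_b})
    pd.DataFrame(rows).to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    pd.DataFrame([{"r": res.r, "p": res.p, "n_perm": res.n_perm}]) \
        .to_csv(out / "mantel.tsv", sep="\t", index=False)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
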