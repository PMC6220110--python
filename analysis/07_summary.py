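#!/usr/bin/env python
"""Collect the headline numbers from all stages into one summary table.

Reads the persisted outputs of steps 02-06 and prints/writes the style of
tabulation the analysis reports: SNP attrition, taxa per prevalence class,
heritable-taxon counts and the fraction belonging to each phylum,
association and locus counts.
"""

import json
from pathlib import Path

import pandas as pd

from mbherit import taxa
from mbherit.pipeline import fraction_summary

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    qc = json.loads((ROOT / "qc" / "qc_report.json").read_text())
    prev = pd.read_csv(ROOT / "traits" / "prevalence.tsv", sep="\t")
    h2 = pd.read_csv(ROOT / "heritability" / "heritability.tsv", sep="\t")
    mantel = pd.read_csv(ROOT / "relatedness" / "mantel.tsv", sep="\t").iloc[0]
    loci = pd.read_csv(ROOT / "gwas" / "loci.tsv", sep="\t")
    tax = taxa.TaxonomyMap.read_tsv(ROOT / "cohort" / "taxonomy.tsv")

    lines = [
        f"SNPs: {qc['n_input_snps']} -> {qc['n_pass']} after QC",
        "taxa: " + ", ".join(f"{k}={v}" for k, v in
                             prev.category.value_counts().items()),
        f"Mantel r={mantel.r:.4f} p={mantel.p:.4g}",
        f"heritable taxa (h2>0.15): {int(h2.heritable.sum())}/{len(h2)}",
        f"loci: {len(loci)}",
    ]
    heritable = h2[h2.heritable]
    if len(heritable):
        phyla = heritable.taxon_id.map(
            lambda t: tax.lineages[t][1] if t in tax.lineages else "unassigned")
        frac = fraction_summary(phyla)
        lines.append("heritable taxa by phylum:")
        for r in frac.itertuples(index=False):
            lines.append(f"  {r.group}: {r.percent}% ({r.count}/{r.total})")
    text = "\n".join(lines)
    print(text)
    (ROOT / "summary.txt").write_text(text + "\n")


if __name__ == "__main__":
    main()
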