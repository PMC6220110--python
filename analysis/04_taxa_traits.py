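#!/usr/bin/env python
"""Taxon traits: relative abundance, genus aggregation, prevalence classes,
covariate-adjusted log abundances.

Classifies OTU-level features into core (>95% prevalence), random (20-95%)
and discarded (<20%), aggregates at the genus rank, and exports the
two-part trait (presence mask + sex/batch-adjusted log abundance) for
every analyzable feature under results/traits/.
"""

from pathlib import Path

import pandas as pd

from mbherit import simdata, taxa

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "traits"
    out.mkdir(parents=True, exist_ok=True)
    counts = taxa.OTUTable.read_tsv(ROOT / "cohort" / "otu_counts.tsv")
    tax = taxa.TaxonomyMap.read_tsv(ROOT / "cohort" / "taxonomy.tsv")
    ped = simdata.Pedigree.read_tsv(ROOT / "cohort" / "pedigree.tsv")
    off = ped.offspring.set_index("animal_id").loc[counts.samples]

    rel = taxa.relative_abundance(counts)
    genus = taxa.aggregate_taxa(rel, tax, "genus")
    genus.write_tsv(out / "abundance_genus.tsv")

    classes = taxa.classify_prevalence(rel)
    tab = pd.DataFrame([(c.feature_id, c.prevalence, c.category) for c in classes],
                       columns=["feature_id", "prevalence", "category"])
    tab.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    print(tab.category.value_counts().to_dict())

    n_exported = 0
    fidx = {f: j for j, f in enumerate(rel.features)}
    for c in classes:
        if c.category == "discarded":
            continue
        try:
            tv = taxa.prepare_trait(rel.values[:, fidx[c.feature_id]],
                                    off.sex.to_numpy(), off.batch.to_numpy(),
                                    c.feature_id)
        except ValueError as exc:
            print(f"  {c.feature_id}: {exc}")
            continue
        tv.write_tsv(out / f"trait_{c.feature_id}.tsv", rel.samples)
        n_exported += 1
    print(f"exported {n_exported} taxon traits to {out}")


if __name__ == "__main__":
    main()
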