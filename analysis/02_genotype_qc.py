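#!/usr/bin/env python
"""Genotype quality control on the simulated cohort.

Applies the chip-QC filters (call rate >= 95%, MAF >= 5%, exact HWE
P > 5e-6), reports per-filter attrition, mean-imputes the survivors and
writes the cleaned matrix plus the QC report under results/qc/.
"""

from pathlib import Path

from mbherit import io_qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    G = io_qc.read_genotypes(ROOT / "cohort" / "genotypes.tsv", "dosage_tsv")
    G_qc, report = io_qc.qc_genotypes(G)
    print(f"{report.n_input_snps} SNPs in; {report.n_pass} pass "
          f"({report.n_fail_callrate} call-rate, {report.n_fail_maf} MAF, "
          f"{report.n_fail_hwe} HWE failures)")
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    io_qc.write_genotypes(io_qc.mean_impute(G_qc), out / "genotypes_imputed.tsv",
                          "dosage_tsv")
    report.to_json(out / "qc_report.json")
    print(f"imputed matrix and report written to {out}")


if __name__ == "__main__":
    main()
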