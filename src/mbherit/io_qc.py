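"""Genotype containers, format I/O and chip-style quality control.

Genotypes are held as alternate-allele dosages in {0, 1, 2} with NaN for
missing calls.  Two on-disk dialects are supported: GT-only VCF 4.2 and a
dosage TSV (header row of SNP ids, one sample per row).  QC applies the
standard chip filters — call rate, minor allele frequency and an exact
Hardy–Weinberg equilibrium test — attributing each failing SNP to the first
rule it fails, in the fixed order call rate -> MAF -> HWE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; message names the line."""


@dataclass
class GenotypeMatrix:
    """n samples x p SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    samples : list of str
        Unique ordered sample ids (length n).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``.
        Positions are 1-based, as in VCF.
    dosage : ndarray of shape (n, p)
        Alternate-allele dosage in {0, 1, 2}; NaN marks a missing call.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        dup = self.snps.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("SNP positions must be unique per chromosome")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), self.snps.reset_index(drop=True).copy(), self.dosage.copy()
        )


@dataclass
class QCReport:
    """Per-filter SNP accounting; a SNP is counted once, by first failing rule."""

    n_input_snps: int
    n_pass: int
    n_fail_callrate: int
    n_fail_maf: int
    n_fail_hwe: int
    call_rate_min: float
    maf_min: float
    hwe_p_min: float

    def __post_init__(self) -> None:
        total = self.n_pass + self.n_fail_callrate + self.n_fail_maf + self.n_fail_hwe
        if total != self.n_input_snps:
            raise ValueError("QC counts do not partition the input SNPs")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write genotypes as GT-only VCF 4.2 or as a dosage TSV."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(G, path)
    elif format == "dosage_tsv":
        _write_dosage_tsv(G, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF 4.2 (GT field) or dosage TSV.

    Multi-allelic VCF records are skipped (a note is printed); the
    round-trip ``read(write(G)) == G`` is lossless for biallelic data.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + list(G.samples)))
    for j, rec in enumerate(G.snps.itertuples(index=False)):
        col = G.dosage[:, j]
        gts = ["./." if np.isnan(d) else _GT_BY_DOSAGE[int(d)] for d in col]
        lines.append("\t".join(
            [str(rec.chrom), str(int(rec.pos)), str(rec.snp_id), rec.ref, rec.alt,
             ".", "PASS", ".", "GT"] + gts))
    path.write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    recs, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            print(f"[io_qc] skipping multi-allelic record {var.CHROM}:{var.POS}")
            continue
        recs.append((var.ID or f"{var.CHROM}_{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0,
                       np.where(gt == 3, 2.0, np.nan)))
        cols.append(dos)
    vcf.close()
    snps = pd.DataFrame(recs, columns=SNP_COLUMNS)
    dosage = (np.column_stack(cols) if cols
              else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples, snps, dosage)


def _write_dosage_tsv(G: GenotypeMatrix, path: Path) -> None:
    # Sidecar .snps.tsv keeps chrom/pos/ref/alt so the TSV dialect round-trips.
    def fmt(d: float) -> str:
        if np.isnan(d):
            return "NA"
        return str(int(d)) if d == int(d) else repr(float(d))

    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(G.snps["snp_id"]) + "\n")
        for i, s in enumerate(G.samples):
            fh.write(s + "\t" + "\t".join(fmt(d) for d in G.dosage[i]) + "\n")
    G.snps.to_csv(path.with_suffix(path.suffix + ".snps.tsv"), sep="\t", index=False)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise GenotypeParseError(f"malformed dosage TSV {path}: {exc}") from exc
    if df.index.name != "sample_id":
        raise GenotypeParseError(
            f"malformed header in {path} line 1: first column must be 'sample_id'")
    meta_path = path.with_suffix(path.suffix + ".snps.tsv")
    if meta_path.exists():
        snps = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    else:
        snps = pd.DataFrame({"snp_id": df.columns, "chrom": "0",
                             "pos": np.arange(1, df.shape[1] + 1),
                             "ref": "A", "alt": "B"})
    vals = df.to_numpy(dtype=float)
    samples = [str(s) for s in df.index]
    fractional = np.any(vals[~np.isnan(vals)] % 1 != 0)
    cls = _Imputed if fractional else GenotypeMatrix
    return cls(samples, snps, vals)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of tables no more probable than the
    observed one.  Returns p in (0, 1]; symmetric in (n_AA, n_aa).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = n_Aa + 2 * n_aa  # minor-or-major, symmetry makes the choice moot
    n_A = n_Aa + 2 * n_AA
    rare = min(n_A, n_a)
    # het counts share the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)
    logp = []
    lognfact = math.lgamma(n + 1)
    logafact = math.lgamma(n_A + 1) + math.lgamma(n_a + 1) - math.lgamma(2 * n + 1)
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        lp = (lognfact + logafact + h * math.log(2)
              - math.lgamma(h + 1) - math.lgamma(hom_rare + 1)
              - math.lgamma(hom_common + 1))
        logp.append(lp)
    logp = np.array(logp)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = (n_Aa - rare % 2) // 2
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# QC and imputation
# ---------------------------------------------------------------------------

def qc_genotypes(
    G: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 5e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by call rate, MAF (on non-missing calls) and exact HWE.

    A SNP is retained when call rate >= `call_rate_min`, MAF >= `maf_min`
    and HWE p > `hwe_p_min`.  Failures are attributed to the first rule
    violated, in that order.
    """
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    D = G.dosage
    n = G.n_samples
    nonmiss = ~np.isnan(D)
    call_rate = nonmiss.sum(axis=0) / n

    keep = np.zeros(G.n_snps, dtype=bool)
    fail_cr = fail_maf = fail_hwe = 0
    for j in range(G.n_snps):
        if call_rate[j] < call_rate_min:
            fail_cr += 1
            continue
        col = D[nonmiss[:, j], j]
        freq_alt = col.sum() / (2 * len(col))
        maf = min(freq_alt, 1 - freq_alt)
        if maf < maf_min:
            fail_maf += 1
            continue
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        if hwe_exact_test(n_AA, n_Aa, n_aa) <= hwe_p_min:
            fail_hwe += 1
            continue
        keep[j] = True

    report = QCReport(G.n_snps, int(keep.sum()), fail_cr, fail_maf, fail_hwe,
                      call_rate_min, maf_min, hwe_p_min)
    if not keep.any():
        print("[io_qc] warning: all SNPs removed by QC")
    filtered = GenotypeMatrix(
        list(G.samples), G.snps.loc[keep].reset_index(drop=True), D[:, keep])
    return filtered, report


def mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-SNP mean of observed calls.

    The result leaves the {0,1,2} domain, so it is returned as a plain
    (samples, snps, ndarray) GenotypeMatrix-like object with float dosages;
    downstream kinship/GWAS consume the array directly.
    """
    D = G.dosage.copy()
    miss = np.isnan(D)
    if miss.all(axis=0).any():
        raise ValueError("SNP with all calls missing cannot be imputed")
    means = np.nanmean(D, axis=0)
    D[miss] = np.broadcast_to(means, D.shape)[miss]
    out = G.copy()
    out.dosage = D
    # bypass domain re-validation: imputed values are fractional by design
    return _Imputed(out.samples, out.snps, D)


class _Imputed(GenotypeMatrix):
    """GenotypeMatrix with fractional (imputed) dosages allowed."""

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if np.isnan(self.dosage).any():
            raise ValueError("imputed matrix must be complete")
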