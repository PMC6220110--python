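"""Two-part microbiome GWAS with genomic control and locus definition.

Zero-inflated taxon abundances are scanned in two parts: a log-normal
score test on the covariate-adjusted log relative abundance over samples
where the taxon is present (the only part used for core taxa), and a
logistic likelihood-ratio test on presence/absence over all samples (added
for random taxa).  Each part is corrected by genomic control; scans whose
inflation factor lies outside [0.99, 1.06] are flagged for removal.
Significant SNPs are clumped greedily into loci by LD (r^2 >= 0.8 with the
top SNP), and each locus is annotated with the gene nearest its top SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .taxa import PrevalenceClass, TraitVector

CHI2_1_MEDIAN = 0.4549364231195724  # median of the 1-df chi-square


class AssocStat(NamedTuple):
    beta: float
    chi2: float
    p: float
    testable: bool = True


@dataclass
class ScanSummary:
    taxon_id: str
    part: str                 # quantitative | binary
    lam: float
    kept: bool
    n_snps: int
    genome_wide: float
    suggestive: float


@dataclass
class Locus:
    taxon_id: str
    part: str
    chrom: str
    interval_start: int       # 1-based inclusive bp
    interval_end: int
    top_snp: str
    top_pos: int
    top_p: float
    n_sig_snps: int
    nearest_gene: str | None = None
    gene_distance: int | None = None
    r2_threshold: float = 0.8


# ---------------------------------------------------------------------------
# Single-SNP tests
# ---------------------------------------------------------------------------

def score_test_quantitative(y_adj: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Score test for a quantitative trait: chi2 = n * r^2(g, y), 1 df.

    `y_adj` must already be residualized on the covariates; `g` is the
    dosage vector over the same (present) samples.
    """
    y = np.asarray(y_adj, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    if sxx == 0:
        raise ValueError("constant genotype in the tested subsample")
    syy = yc @ yc
    if syy == 0:
        raise ValueError("constant trait")
    sxy = gc @ yc
    chi2 = n * sxy * sxy / (sxx * syy)
    beta = sxy / sxx
    return float(beta), float(chi2), float(stats.chi2.sf(chi2, df=1))


def quantitative_scan(y_adj: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized score test across all SNP columns of G.

    Returns (beta, chi2, p); untestable SNPs (constant dosage) are NaN.
    """
    y = np.asarray(y_adj, dtype=float)
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc * Gc).sum(axis=0)
    syy = yc @ yc
    sxy = yc @ Gc
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(sxx > 0, n * sxy ** 2 / (sxx * syy), np.nan)
        beta = np.where(sxx > 0, sxy / sxx, np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(np.nan_to_num(chi2), df=1))
    return beta, chi2, p


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Newton-Raphson logistic fit; returns (beta, loglik, ok)."""
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        w = mu * (1 - mu)
        if w.max() < 1e-10:
            return beta, ll, False  # fitted probabilities degenerate: separation
        grad = X.T @ (y - mu)
        H = (X.T * w) @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # step-halving for stability
        for _ in range(20):
            cand = beta + step
            eta_c = np.clip(X @ cand, -30, 30)
            ll_c = float(y @ eta_c - np.logaddexp(0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if abs(ll_c - ll_old) < 1e-10:
            if np.abs(beta).max() > 15:
                return beta, ll_c, False  # drifting to infinity: separation
            return beta, ll_c, True
        ll_old = ll_c
    return beta, ll_old, False


def logistic_assoc(
    presence: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None
) -> AssocStat:
    """Likelihood-ratio test (1 df) for presence/absence on a SNP dosage,
    with covariates always in both models.  Complete separation yields a
    result flagged untestable."""
    y = np.asarray(presence, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    n1 = int(y.sum())
    if min(n1, n - n1) < 5:
        raise ValueError("need at least 5 samples in each presence class")
    base = np.ones((n, 1)) if covariates is None else \
        np.column_stack([np.ones(n), covariates])
    b0, ll0, ok0 = _logistic_fit(base, y)
    b1, ll1, ok1 = _logistic_fit(np.column_stack([base, g]), y)
    if not (ok0 and ok1):
        return AssocStat(np.nan, np.nan, np.nan, testable=False)
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    return AssocStat(float(b1[-1]), chi2, float(stats.chi2.sf(chi2, df=1)), True)


# ---------------------------------------------------------------------------
# Genomic control, thresholds, Q-Q
# ---------------------------------------------------------------------------

def genomic_control(
    chi2_vector: np.ndarray, unconditional: bool = False
) -> tuple[float, np.ndarray, np.ndarray]:
    """Inflation factor lambda = median(chi2) / 0.4549364 and corrected stats.

    By default statistics are divided by max(lambda, 1) so that deflation
    (lambda < 1) never inflates significance; set `unconditional` to divide
    by lambda as-is.
    """
    chi2 = np.asarray(chi2_vector, dtype=float)
    chi2 = chi2[~np.isnan(chi2)]
    if chi2.size == 0:
        raise ValueError("no testable statistics for genomic control")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    divisor = lam if unconditional else max(lam, 1.0)
    chi2_gc = chi2 / divisor
    return lam, chi2_gc, stats.chi2.sf(chi2_gc, df=1)


def lambda_filter(s: ScanSummary, lo: float = 0.99, hi: float = 1.06) -> bool:
    """Keep a scan iff its inflation factor lies in [lo, hi] (inclusive)."""
    return lo <= s.lam <= hi


def bonferroni_thresholds(n_snps: int) -> tuple[float, float]:
    """(genome-wide, suggestive) = (0.05 / n_snps, 1 / n_snps)."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    return 0.05 / n_snps, 1.0 / n_snps


def qq_data(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) quantile pairs on the raw p scale, both sorted
    ascending; expected_i = (i - 0.5) / m.  Take -log10 for plotting."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    observed = np.sort(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return expected, observed


# ---------------------------------------------------------------------------
# Two-part scan
# ---------------------------------------------------------------------------

def two_part_scan(
    trait: TraitVector,
    G,
    covariates: np.ndarray | None,
    pclass: PrevalenceClass,
    gc_unconditional: bool = False,
    min_present: int = 20,
) -> tuple[pd.DataFrame, list[ScanSummary]]:
    """Scan one taxon across all SNPs.

    core: quantitative part only (trait present in essentially all
    samples); random: binary part over all samples plus quantitative part
    over present samples.  Each part receives genomic control and a
    lambda-filter verdict separately.  `covariates` is the full-sample
    covariate matrix (sex/batch/PC columns, no intercept).
    """
    if pclass.category == "discarded":
        raise ValueError(f"taxon {trait.taxon_id} is below the prevalence floor")
    dosage = np.asarray(getattr(G, "dosage", G), dtype=float)
    snps = getattr(G, "snps", None)
    if snps is None:
        snps = pd.DataFrame({"snp_id": [f"snp{j}" for j in range(dosage.shape[1])],
                             "chrom": "0", "pos": np.arange(1, dosage.shape[1] + 1)})
    present = trait.presence
    if present.sum() < min_present:
        print(f"[mbgwas] skipping {trait.taxon_id}: only {present.sum()} present samples")
        return pd.DataFrame(), []

    gw, sug = bonferroni_thresholds(dosage.shape[1])
    frames: list[pd.DataFrame] = []
    summaries: list[ScanSummary] = []

    # quantitative part: residualize the adjusted trait on the covariates
    y = trait.adjusted.copy()
    if covariates is not None:
        C = np.column_stack([np.ones(present.sum()), covariates[present]])
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        y = y - C @ coef
    beta, chi2, p_raw = quantitative_scan(y, dosage[present])
    frames.append(_part_frame(trait.taxon_id, snps, "quantitative", beta, chi2,
                              p_raw, int(present.sum())))
    summaries.append(_summarize(trait.taxon_id, "quantitative", chi2, frames[-1],
                                gc_unconditional, gw, sug))

    if pclass.category == "random":
        n = len(present)
        n1 = int(present.sum())
        if min(n1, n - n1) >= 5:
            res = np.full((dosage.shape[1], 3), np.nan)
            for j in range(dosage.shape[1]):
                st = _binary_single(present, dosage[:, j], covariates)
                if st is not None and st.testable:
                    res[j] = (st.beta, st.chi2, st.p)
            frames.append(_part_frame(trait.taxon_id, snps, "binary",
                                      res[:, 0], res[:, 1], res[:, 2], n))
            summaries.append(_summarize(trait.taxon_id, "binary", res[:, 1],
                                        frames[-1], gc_unconditional, gw, sug))
        else:
            print(f"[mbgwas] {trait.taxon_id}: binary part skipped "
                  f"(class sizes {n1}/{n - n1})")

    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, summaries


def _binary_single(presence, g, covariates) -> AssocStat | None:
    gc = g - g.mean()
    if np.abs(gc).max() == 0:
        return None
    try:
        return logistic_assoc(presence, g, covariates)
    except ValueError:
        return None


def _part_frame(taxon, snps, part, beta, chi2, p_raw, n_used) -> pd.DataFrame:
    return pd.DataFrame({
        "taxon_id": taxon, "snp_id": snps["snp_id"].to_numpy(),
        "chrom": snps["chrom"].astype(str).to_numpy(),
        "pos": snps["pos"].to_numpy(), "part": part,
        "beta": beta, "chi2": chi2, "p_raw": p_raw, "n_used": n_used})


def _summarize(taxon, part, chi2, frame, unconditional, gw, sug) -> ScanSummary:
    testable = ~np.isnan(np.asarray(chi2, dtype=float))
    lam, chi2_gc, p_gc = genomic_control(np.asarray(chi2, dtype=float)[testable],
                                         unconditional)
    frame["p_gc"] = np.nan
    frame.loc[np.flatnonzero(testable), "p_gc"] = p_gc
    frame["lambda"] = lam
    s = ScanSummary(taxon, part, lam, True, int(testable.sum()), gw, sug)
    s.kept = lambda_filter(s)
    return s


# ---------------------------------------------------------------------------
# LD, loci, genes
# ---------------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of unphased dosages over
    shared non-missing samples."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant dosage vector; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def define_locus(
    results: pd.DataFrame,
    G,
    sig_threshold: float,
    r2_min: float = 0.8,
    p_col: str = "p_gc",
) -> list[Locus]:
    """Greedy LD clumping of one taxon's (single-part) results.

    Repeatedly takes the smallest-p significant SNP (ties broken by lower
    position) as a locus top; the interval spans the min/max positions of
    same-chromosome SNPs with r^2 >= r2_min to the top SNP; significant
    SNPs claimed by the interval's LD set seed no further loci.
    """
    dosage = np.asarray(getattr(G, "dosage", G), dtype=float)
    snps = getattr(G, "snps")
    col_of = {s: j for j, s in enumerate(snps["snp_id"])}
    res = results.dropna(subset=[p_col])
    sig = res[res[p_col] < sig_threshold].copy()
    if sig.empty:
        raise ValueError("no SNP below the significance threshold")
    loci: list[Locus] = []
    sig = sig.sort_values([p_col, "pos"], kind="stable")
    remaining = sig.copy()
    while not remaining.empty:
        top = remaining.iloc[0]
        gt = dosage[:, col_of[top.snp_id]]
        chrom_res = res[res["chrom"] == top.chrom]
        partners = []
        for rec in chrom_res.itertuples(index=False):
            gj = dosage[:, col_of[rec.snp_id]]
            if gj.std() == 0:
                continue
            try:
                if ld_r2(gt, gj) >= r2_min:
                    partners.append(rec)
            except ValueError:
                continue
        positions = [r.pos for r in partners] + [int(top.pos)]
        partner_ids = {r.snp_id for r in partners} | {top.snp_id}
        n_sig = int(remaining["snp_id"].isin(partner_ids).sum())
        loci.append(Locus(
            taxon_id=str(top.taxon_id), part=str(top.part), chrom=str(top.chrom),
            interval_start=int(min(positions)), interval_end=int(max(positions)),
            top_snp=str(top.snp_id), top_pos=int(top.pos), top_p=float(top[p_col]),
            n_sig_snps=max(1, n_sig), r2_threshold=r2_min))
        remaining = remaining[~remaining["snp_id"].isin(partner_ids)]
    return loci


def nearest_gene(locus: Locus, genes: pd.DataFrame) -> tuple[str | None, int | None]:
    """Gene minimizing distance from the locus top SNP (BED intervals,
    0-based half-open; distance 0 inside).  Ties break toward the smaller
    start coordinate; no gene on the chromosome returns (None, None)."""
    sub = genes[genes["chrom"].astype(str) == str(locus.chrom)]
    if sub.empty:
        print(f"[mbgwas] warning: no genes on chromosome {locus.chrom}")
        return None, None
    pos0 = locus.top_pos - 1  # BED coordinates
    best: tuple[int, int, str] | None = None
    for rec in sub.itertuples(index=False):
        if rec.start <= pos0 < rec.end:
            dist = 0
        elif pos0 < rec.start:
            dist = int(rec.start - pos0)
        else:
            dist = int(pos0 - (rec.end - 1))
        key = (dist, int(rec.start), str(rec.name))
        if best is None or key < best:
            if best is not None and dist == best[0]:
                print(f"[mbgwas] nearest-gene tie at distance {dist}; "
                      f"keeping lower-start {key[2]!r}")
            best = key
    locus.nearest_gene, locus.gene_distance = best[2], best[0]
    return best[2], best[0]
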