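"""Synthetic pedigreed cohorts with heritable, zero-inflated microbial traits.

The generator emulates the structure the downstream analysis assumes: a
two-generation pig pedigree with full-sib families (pairs of parents) and
half-sib families (one sire mated to several dams), offspring randomly
grouped into pens; SNP genotypes drawn for founders and transmitted
Mendelianly to offspring, with designated Hardy–Weinberg-violating and
monomorphic SNPs injected to exercise QC; taxon abundances generated from
the additive model y = mu + X beta + u + e with a polygenic term whose
covariance is proportional to the genomic relationship matrix, zero
inflation through a Gaussian liability threshold, and per-sample
compositional renormalization; plus a random bifurcating phylogeny,
GreenGenes-style lineages, and a BED gene track for locus annotation.

Every stochastic quantity is driven by an explicit seed; fixed seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_qc import GenotypeMatrix, SNP_COLUMNS
from .taxa import OTUTable, TaxonomyMap, RANKS

SEXES = ("F", "castrated_M")

# log-scale baseline for heritable taxon abundances (exp(-4) ~ 1.8% of a sample)
BASELINE_LOG_ABUND = -4.0
# liability-scale shift per alternate allele of the designated presence SNP
BINARY_LIABILITY_EFFECT = 0.75


@dataclass
class Pedigree:
    """Two-generation pedigree table.

    Columns: animal_id, sire_id, dam_id (null for founders), sex, pen,
    batch, generation.  Full-sibs share both parents; half-sibs share
    exactly one.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"animal_id", "sire_id", "dam_id", "sex", "pen", "batch", "generation"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"pedigree table missing columns {need - set(self.table.columns)}")
        gen = dict(zip(self.table.animal_id, self.table.generation))
        for rec in self.table.itertuples(index=False):
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and not (isinstance(parent, float) and np.isnan(parent)):
                    if gen.get(parent, -1) >= rec.generation:
                        raise ValueError(f"parent {parent} not of an earlier generation")

    @property
    def animals(self) -> list[str]:
        return list(self.table.animal_id)

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table.generation > 0].reset_index(drop=True)

    def parents_of(self, animal_id: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table.animal_id == animal_id].iloc[0]
        sire = row.sire_id if isinstance(row.sire_id, str) else None
        dam = row.dam_id if isinstance(row.dam_id, str) else None
        return sire, dam

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t")
        for col in ("sire_id", "dam_id"):
            df[col] = df[col].where(df[col].notna(), None)
        return cls(df)


@dataclass
class SimTruth:
    """Generative ground truth for one heritable taxon trait."""

    pve_target: float
    n_causal: int
    causal_snp_ids: list[str] = field(default_factory=list)
    causal_effects: list[float] = field(default_factory=list)
    zero_inflation_rate: float = 0.0
    binary_effect_snp: str | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pve_target <= 1:
            raise ValueError("pve_target must lie in [0, 1]")
        if not 0 <= self.zero_inflation_rate <= 1:
            raise ValueError("zero_inflation_rate must lie in [0, 1]")


@dataclass
class SimulatedTrait:
    """Realized trait components for one taxon, with its SimTruth."""

    taxon_id: str
    y: np.ndarray                  # latent log abundance (all samples)
    presence: np.ndarray           # bool mask from the liability threshold
    abundance: np.ndarray          # exp(y) * presence, pre-normalization
    genetic_component: np.ndarray  # X beta + u
    noise: np.ndarray
    realized_pve: float
    truth: SimTruth


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founder_pairs: int,
    n_halfsib_sires: int,
    offspring_per_mating: int,
    n_pens: int | None = None,
    n_batches: int = 2,
    seed: int = 0,
    dams_per_halfsib_sire: int = 2,
) -> Pedigree:
    """Two-generation pedigree with full-sib and half-sib families.

    Each founder pair produces `offspring_per_mating` full-sibs; each
    half-sib sire is mated to `dams_per_halfsib_sire` dams, producing
    maternal half-sib groups.  Offspring are shuffled into pens of 7–8
    animals (or into `n_pens` pens as evenly as possible when given) and
    assigned a sampling batch at random.
    """
    if n_founder_pairs < 1 or offspring_per_mating < 1:
        raise ValueError("need at least one founder pair and one offspring per mating")
    if n_halfsib_sires < 0 or n_batches < 1:
        raise ValueError("invalid family counts")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def founder(aid: str, sex: str) -> None:
        rows.append(dict(animal_id=aid, sire_id=None, dam_id=None, sex=sex,
                         pen=0, batch=0, generation=0))

    matings: list[tuple[str, str]] = []
    for i in range(n_founder_pairs):
        s, d = f"FS_sire{i}", f"FS_dam{i}"
        founder(s, "castrated_M")
        founder(d, "F")
        matings.append((s, d))
    for i in range(n_halfsib_sires):
        s = f"HS_sire{i}"
        founder(s, "castrated_M")
        for j in range(dams_per_halfsib_sire):
            d = f"HS_dam{i}_{j}"
            founder(d, "F")
            matings.append((s, d))

    kid = 0
    offspring: list[dict] = []
    for sire, dam in matings:
        for _ in range(offspring_per_mating):
            offspring.append(dict(
                animal_id=f"pig{kid:04d}", sire_id=sire, dam_id=dam,
                sex=SEXES[rng.integers(2)], pen=-1,
                batch=int(rng.integers(n_batches)), generation=1))
            kid += 1

    n_off = len(offspring)
    if n_pens is None:
        n_pens = max(1, int(round(n_off / 7.5)))
    order = rng.permutation(n_off)
    sizes = np.full(n_pens, n_off // n_pens)
    sizes[: n_off % n_pens] += 1
    pos = 0
    for pen, size in enumerate(sizes):
        for idx in order[pos: pos + size]:
            offspring[idx]["pen"] = pen
        pos += size

    return Pedigree(pd.DataFrame(rows + offspring))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    missing_rate: float = 0.0,
    n_hwe_violators: int = 0,
    n_monomorphic: int = 0,
    seed: int = 0,
    n_chrom: int = 5,
) -> GenotypeMatrix:
    """Founder genotypes from binomial(2, f) with f ~ U(maf_low, maf_high);
    offspring receive one Bernoulli(dosage/2) allele per parent.

    `n_hwe_violators` SNPs are drawn with no heterozygotes at all (an
    extreme equilibrium departure, emulating genotyping artifacts) and
    `n_monomorphic` SNPs are all-reference; both bypass Mendelian
    transmission.  Missing calls are masked uniformly at `missing_rate`.
    """
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if n_hwe_violators + n_monomorphic > n_snps:
        raise ValueError("special SNPs exceed n_snps")
    rng = np.random.default_rng(seed)
    tab = pedigree.table
    animals = list(tab.animal_id)
    idx = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    n_regular = n_snps - n_hwe_violators - n_monomorphic

    D = np.full((n, n_snps), np.nan)
    f = rng.uniform(maf_low, maf_high, size=n_regular)

    founders = tab.generation == 0
    D[np.asarray(founders), :n_regular] = rng.binomial(
        2, f, size=(int(founders.sum()), n_regular)).astype(float)
    for rec in tab[~founders].sort_values("generation").itertuples(index=False):
        if rec.sire_id is None or rec.dam_id is None:
            raise ValueError(f"non-founder {rec.animal_id} lacks recorded parents")
        ds, dd = D[idx[rec.sire_id], :n_regular], D[idx[rec.dam_id], :n_regular]
        D[idx[rec.animal_id], :n_regular] = (
            rng.binomial(1, ds / 2.0) + rng.binomial(1, dd / 2.0)).astype(float)

    # HWE violators: hom-only genotypes at an intermediate frequency
    for k in range(n_hwe_violators):
        fv = rng.uniform(0.3, 0.5)
        D[:, n_regular + k] = 2.0 * rng.binomial(1, fv, size=n)
    # monomorphic: all reference
    D[:, n_regular + n_hwe_violators:] = 0.0

    if missing_rate > 0:
        D[rng.random(D.shape) < missing_rate] = np.nan

    suffix = ([""] * n_regular + ["_hwe"] * n_hwe_violators + ["_mono"] * n_monomorphic)
    chrom = np.repeat(np.arange(1, n_chrom + 1), int(np.ceil(n_snps / n_chrom)))[:n_snps]
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, n_chrom + 1):
        m = chrom == c
        pos[m] = np.cumsum(rng.integers(1_000, 10_000, size=int(m.sum())))
    refalt = np.array(["A", "C", "G", "T"])
    ra = rng.integers(0, 4, size=(n_snps, 2))
    ra[:, 1] = (ra[:, 0] + 1 + ra[:, 1] % 3) % 4  # alt differs from ref
    snps = pd.DataFrame({
        "snp_id": [f"snp{j:05d}{suffix[j]}" for j in range(n_snps)],
        "chrom": chrom.astype(str), "pos": pos,
        "ref": refalt[ra[:, 0]], "alt": refalt[ra[:, 1]]})
    return GenotypeMatrix(animals, snps, D)


def mendelian_violations(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Boolean (offspring x SNP) matrix of transmissions impossible under
    the recorded parents; injected QC-artifact SNPs are expected to light up."""
    idx = {a: i for i, a in enumerate(G.samples)}
    transmissible = {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}
    off = ped.offspring
    out = np.zeros((len(off), G.n_snps), dtype=bool)
    for r, rec in enumerate(off.itertuples(index=False)):
        child = G.dosage[idx[rec.animal_id]]
        sire = G.dosage[idx[rec.sire_id]]
        dam = G.dosage[idx[rec.dam_id]]
        for j in range(G.n_snps):
            trio = (child[j], sire[j], dam[j])
            if any(np.isnan(v) for v in trio):
                continue
            ok = {a + b for a in transmissible[sire[j]] for b in transmissible[dam[j]]}
            out[r, j] = child[j] not in ok
    return out


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    G: GenotypeMatrix,
    K: "np.ndarray | object",
    truth: SimTruth,
    sex: np.ndarray | None = None,
    batch: np.ndarray | None = None,
    taxon_id: str = "taxon",
) -> SimulatedTrait:
    """Draw one taxon trait from y = mu + X beta + u + e.

    The sparse term uses `truth.n_causal` SNPs (chosen at random unless
    `causal_snp_ids` is given); u is a polygenic draw with covariance
    proportional to K; sparse and polygenic terms get equal generative
    variance when both are present.  Components are rescaled so the
    realized var(X beta + u) / var(y - mu) equals `pve_target`.  Presence
    follows a Gaussian liability threshold placed at the empirical
    quantile matching `zero_inflation_rate`, optionally shifted by the
    dosage of `binary_effect_snp`.
    """
    if truth.pve_target >= 1:
        raise ValueError("pve_target must be < 1 (zero noise variance undefined)")
    Kv = getattr(K, "values", K)
    Kv = np.asarray(Kv, dtype=float)
    rng = np.random.default_rng(truth.seed)
    n = G.n_samples
    if Kv.shape != (n, n):
        raise ValueError("K must be n x n over the genotype samples")

    X = G.dosage.copy()
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(col_means, X.shape)[miss]

    ids = list(G.snps["snp_id"])
    if truth.causal_snp_ids:
        causal_idx = [ids.index(s) for s in truth.causal_snp_ids]
    else:
        causal_idx = sorted(rng.choice(G.n_snps, size=truth.n_causal, replace=False)) \
            if truth.n_causal else []
        truth.causal_snp_ids = [ids[j] for j in causal_idx]

    # polygenic draw u ~ N(0, K)
    w, V = np.linalg.eigh(Kv)
    w = np.clip(w, 0, None)
    u = V @ (np.sqrt(w) * rng.standard_normal(n))

    sparse = np.zeros(n)
    if causal_idx:
        Xc = X[:, causal_idx] - X[:, causal_idx].mean(axis=0)
        beta = np.array(truth.causal_effects, dtype=float) if truth.causal_effects \
            else rng.standard_normal(len(causal_idx))
        raw = Xc @ beta
        if raw.std() > 0:
            sparse = raw / raw.std()
            beta = beta / raw.std()  # effective slopes on the emitted scale
        truth.causal_effects = [float(b) for b in beta]
    if u.std() > 0:
        u = u / u.std()
    if not causal_idx:
        sparse = np.zeros(n)

    g = sparse + u if causal_idx else u
    if truth.pve_target == 0:
        g = np.zeros(n)
        e = rng.standard_normal(n)
    else:
        gv = g.var()
        if gv == 0:
            raise ValueError("degenerate genetic component")
        e = rng.standard_normal(n)
        e = e / e.std() * np.sqrt(gv * (1 - truth.pve_target) / truth.pve_target)

    y = BASELINE_LOG_ABUND + g + e
    for cov, arr in (("sex", sex), ("batch", batch)):
        eff = truth.covariate_effects.get(cov, 0.0)
        if eff and arr is not None:
            codes = pd.factorize(np.asarray(arr))[0].astype(float)
            y = y + eff * codes

    liability = rng.standard_normal(n)
    if truth.binary_effect_snp is not None:
        j = ids.index(truth.binary_effect_snp)
        liability = liability + BINARY_LIABILITY_EFFECT * (X[:, j] - X[:, j].mean())
    thr = np.quantile(liability, truth.zero_inflation_rate) \
        if truth.zero_inflation_rate > 0 else -np.inf
    presence = liability >= thr

    abundance = np.exp(y) * presence
    denom = g.var() + e.var()
    realized = float(g.var() / denom) if denom > 0 else 0.0
    return SimulatedTrait(taxon_id, y, presence, abundance, g, e, realized, truth)


# ---------------------------------------------------------------------------
# OTU ecosystem
# ---------------------------------------------------------------------------

def simulate_otu_ecosystem(
    n_samples: int,
    n_otus: int,
    n_heritable: int,
    truth_list: list[SimulatedTrait],
    depth_range: tuple[int, int] = (10_000, 30_000),
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[OTUTable, TaxonomyMap, TreeNode]:
    """Multinomial OTU counts over generative compositions, plus a random
    bifurcating phylogeny and nested GreenGenes-style lineages.

    The first `n_heritable` OTUs take their (unnormalized) abundances from
    the supplied simulated traits; the rest are per-sample log-normal
    noise.  Rows are renormalized before multinomial sampling, so the
    heritable signal lives on the compositional scale the analysis sees.
    """
    if n_heritable > n_otus:
        raise ValueError("n_heritable cannot exceed n_otus")
    if len(truth_list) != n_heritable:
        raise ValueError("truth_list length must equal n_heritable")
    if depth_range[0] < 1:
        raise ValueError("sequencing depth must be at least 1")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n_samples)]

    otu_ids = [f"OTU{j:04d}" for j in range(n_otus)]
    comp = np.empty((n_samples, n_otus))
    for j in range(n_heritable):
        ab = truth_list[j].abundance
        if len(ab) != n_samples:
            raise ValueError("trait length does not match n_samples")
        comp[:, j] = ab
    n_noise = n_otus - n_heritable
    if n_noise:
        mu = rng.uniform(-6.0, -2.0, size=n_noise)
        comp[:, n_heritable:] = np.exp(
            mu + rng.standard_normal((n_samples, n_noise)))
    totals = comp.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a sample has zero total generative abundance")
    comp /= totals

    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_samples)
    counts = np.vstack([rng.multinomial(depths[i], comp[i]) for i in range(n_samples)])
    table = OTUTable(list(sample_ids), otu_ids, counts.astype(float), "counts")

    tree = _random_bifurcating_tree(otu_ids, rng)
    tax = _nested_taxonomy(otu_ids, rng)
    return table, tax, tree


def _random_bifurcating_tree(leaf_names: list[str], rng: np.random.Generator) -> TreeNode:
    nodes = [TreeNode(name=name, length=float(rng.exponential(0.1) + 0.01))
             for name in leaf_names]
    if len(nodes) == 1:
        root = TreeNode(name="root")
        root.append(nodes[0])
        return root
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode(length=float(rng.exponential(0.1) + 0.01))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    root.name = "root"
    return root


def _nested_taxonomy(otu_ids: list[str], rng: np.random.Generator) -> TaxonomyMap:
    """Nested lineages in which multiple OTUs share genera and families;
    ~10% of OTUs are left unassigned below family."""
    n = len(otu_ids)
    n_gen = max(2, n // 3)
    lineages = {}
    for j, otu in enumerate(otu_ids):
        g = int(rng.integers(n_gen))
        f, o = g // 2, g // 4
        c, p = o // 2, o // 4
        names = ["Bacteria", f"P{p}", f"C{c}", f"O{o}", f"F{f}", f"G{g}", otu]
        if rng.random() < 0.10:
            names[5] = names[6] = ""  # unassigned genus/species
        lineages[otu] = names
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# Gene track
# ---------------------------------------------------------------------------

def simulate_gene_track(
    chrom_lengths: dict[str, int], n_genes: int, seed: int = 0
) -> pd.DataFrame:
    """Random non-degenerate gene intervals (BED: 0-based half-open),
    sorted by (chrom, start), with unique names, within chromosome bounds."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    rows = []
    for k in range(n_genes):
        c = chroms[int(rng.integers(len(chroms)))]
        L = chrom_lengths[c]
        length = int(rng.integers(500, max(1500, L // 20)))
        length = min(length, L - 1)
        start = int(rng.integers(0, L - length))
        rows.append((c, start, start + length, f"gene{k:04d}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name"],
                       dtype={"chrom": str})


def write_truth_manifest(truths: list[SimTruth], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(t) for t in truths], indent=2) + "\n")


def read_truth_manifest(path: str | Path) -> list[SimTruth]:
    return [SimTruth(**d) for d in json.loads(Path(path).read_text())]
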