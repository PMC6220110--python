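"""Sample relatedness from SNPs or microbial composition, and their correlation.

The genomic relationship matrix is the centered (unstandardized) form
K = (1/p) * X_c X_c^T, where X_c is the dosage matrix with each SNP column
mean-centered.  The same formula applied to a samples x OTU relative-
abundance matrix yields a microbiome-composition "kinship" M; a Mantel
permutation test measures whether genetically similar hosts carry similar
microbial communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix
from .taxa import OTUTable


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray
    source: str  # snp | microbiome

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over the sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship must be symmetric")

    @property
    def n(self) -> int:
        return len(self.samples)

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.samples)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, source: str = "snp") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy(dtype=float), source)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def _centered_cross_product(mat: np.ndarray) -> np.ndarray:
    p = mat.shape[1]
    if p == 0:
        raise ValueError("at least one feature column required")
    Xc = mat - mat.mean(axis=0, keepdims=True)
    return (Xc @ Xc.T) / p


def snp_kinship(G: GenotypeMatrix | np.ndarray, samples: list[str] | None = None) -> KinshipMatrix:
    """Centered genomic relationship matrix K = (1/p) sum_i (x_i - x̄_i 1)(x_i - x̄_i 1)^T.

    Requires complete dosages (mean-impute first).
    """
    if isinstance(G, GenotypeMatrix):
        mat, samples = G.dosage, list(G.samples)
    else:
        mat = np.asarray(G, dtype=float)
        samples = list(samples) if samples is not None else [f"s{i}" for i in range(mat.shape[0])]
    if np.isnan(mat).any():
        raise ValueError("kinship requires complete genotypes; run mean_impute first")
    K = _centered_cross_product(mat)
    return KinshipMatrix(samples, K, "snp")


def microbiome_kinship(t: OTUTable) -> KinshipMatrix:
    """The same centering formula applied to the samples x OTU relative abundances."""
    if t.mode != "relabund":
        raise ValueError("microbiome kinship is computed on relative abundances")
    if len(t.features) < 2:
        print("[relatedness] warning: single OTU gives a rank-1 kinship")
    M = _centered_cross_product(t.values)
    return KinshipMatrix(list(t.samples), M, "microbiome")


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    A: KinshipMatrix, B: KinshipMatrix, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """Two-sided Mantel permutation test between two square sample matrices.

    r is the Pearson correlation of upper-triangle entries; the p-value is
    (1 + #{permutations with |r*| >= |r|}) / (n_perm + 1), permuting one
    matrix's rows and columns jointly.
    """
    if A.samples != B.samples:
        raise ValueError("matrices must share the same sample order")
    n = A.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    a = _upper(A.values)
    if a.std() == 0 or _upper(B.values).std() == 0:
        raise ValueError("constant off-diagonal entries; correlation undefined")
    a = (a - a.mean()) / a.std()
    rng = np.random.default_rng(seed)
    Bv = B.values

    def corr_with(perm: np.ndarray) -> float:
        b = _upper(Bv[np.ix_(perm, perm)])
        bs = b.std()
        return float((a * (b - b.mean())).mean() / bs)

    r_obs = corr_with(np.arange(n))
    exceed = 0
    for _ in range(n_perm):
        if abs(corr_with(rng.permutation(n))) >= abs(r_obs) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, seed)


def genetic_pcs(K: KinshipMatrix, n_pcs: int = 3) -> np.ndarray:
    """Top eigenvectors of the kinship matrix, unit norm.

    Sign convention: the largest-magnitude loading of each PC is positive.
    """
    if n_pcs > K.n:
        raise ValueError("cannot extract more PCs than samples")
    w, v = np.linalg.eigh(K.values)
    order = np.argsort(w)[::-1][:n_pcs]
    if np.all(np.abs(w) < 1e-12):
        raise ValueError("kinship has no nonzero eigenvalues; PCs undefined")
    pcs = v[:, order]
    for j in range(pcs.shape[1]):
        k = np.argmax(np.abs(pcs[:, j]))
        if pcs[k, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
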