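"""Phylogenetic beta diversity and its comparison across relatedness groups.

Unweighted UniFrac is the fraction of shared-ancestry branch length unique
to either of two communities; weighted UniFrac accumulates branch lengths
times the absolute difference in the fraction of each community descending
through the branch.  Pairwise distances between full-sib, half-sib and
unrelated animal pairs (drawn from different pens, to remove the
cohabitation signal) are compared with two-sample t statistics whose null
distribution comes from Monte-Carlo re-partitioning of the pooled
pair-level distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .simdata import Pedigree
from .taxa import OTUTable


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValueError("self-distances must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.samples)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class GroupComparison:
    group_pair: str
    t_stat: float
    p_mc: float
    n_mc: int
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# Branch bookkeeping
# ---------------------------------------------------------------------------

def _branches(tree: TreeNode, leaf_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, membership) for every non-root branch; membership[b, k] is
    True when leaf k descends through branch b."""
    index = {name: k for k, name in enumerate(leaf_order)}
    lengths, members = [], []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        leaves = [tip.name for tip in node.tips()] if not node.is_tip() else [node.name]
        row = np.zeros(len(leaf_order), dtype=bool)
        for name in leaves:
            if name not in index:
                raise KeyError(f"tree leaf {name!r} not among the requested OTUs")
            row[index[name]] = True
        lengths.append(float(node.length))
        members.append(row)
    return np.array(lengths), np.array(members)


def _as_vector(x, leaf_order: list[str]) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([float(x.get(name, 0.0)) for name in leaf_order])
    return np.asarray(x, dtype=float)


def unweighted_unifrac(tree: TreeNode, presence_a, presence_b) -> float:
    """Unique-branch-length fraction between two presence sets.

    Arguments may be sets of leaf names or boolean/abundance vectors in the
    tree's tip order; any positive abundance counts as present.
    """
    leaf_order = [tip.name for tip in tree.tips()]
    if isinstance(presence_a, (set, frozenset, list, tuple)) and \
            all(isinstance(v, str) for v in presence_a):
        pa = np.array([name in set(presence_a) for name in leaf_order])
        pb = np.array([name in set(presence_b) for name in leaf_order])
    else:
        pa = _as_vector(presence_a, leaf_order) > 0
        pb = _as_vector(presence_b, leaf_order) > 0
    if not pa.any() and not pb.any():
        raise ValueError("both samples are empty")
    lengths, members = _branches(tree, leaf_order)
    in_a = (members & pa).any(axis=1)
    in_b = (members & pb).any(axis=1)
    either = in_a | in_b
    unique = in_a ^ in_b
    denom = lengths[either].sum()
    if denom == 0:
        return 0.0
    return float(lengths[unique].sum() / denom)


def weighted_unifrac(tree: TreeNode, abund_a, abund_b, normalized: bool = False) -> float:
    """Sum over branches of length * |A_b - B_b|, where A_b is the fraction
    of sample a descending through branch b.  With `normalized`, divided by
    the maximum attainable value sum(length * (A_b + B_b))."""
    leaf_order = [tip.name for tip in tree.tips()]
    a = _as_vector(abund_a, leaf_order)
    b = _as_vector(abund_b, leaf_order)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    lengths, members = _branches(tree, leaf_order)
    A = members @ a
    B = members @ b
    raw = float(lengths @ np.abs(A - B))
    if not normalized:
        return raw
    denom = float(lengths @ (A + B))
    return raw / denom if denom > 0 else 0.0


def pairwise_distances(
    tree: TreeNode, t: OTUTable, metric: str = "unweighted_unifrac",
    normalized: bool = False,
) -> DistanceMatrix:
    """All-pairs UniFrac over an OTU table (relative abundances)."""
    if metric not in ("unweighted_unifrac", "weighted_unifrac"):
        raise ValueError(f"unknown metric {metric!r}")
    leaf_order = [tip.name for tip in tree.tips()]
    missing = set(t.features) - set(leaf_order)
    if missing:
        raise KeyError(f"OTU {sorted(missing)[0]!r} absent from the tree")
    # column-align table to tree tip order
    col = {f: j for j, f in enumerate(t.features)}
    vals = np.column_stack([
        t.values[:, col[name]] if name in col else np.zeros(t.n_samples)
        for name in leaf_order])
    lengths, members = _branches(tree, leaf_order)
    P = members.astype(float) @ vals.T          # branch x sample fractions
    n = t.n_samples
    D = np.zeros((n, n))
    if metric == "weighted_unifrac":
        denom_norm = None
        for i in range(n):
            diffs = np.abs(P[:, i, None] - P[:, i + 1:])
            D[i, i + 1:] = lengths @ diffs
            if normalized:
                sums = P[:, i, None] + P[:, i + 1:]
                with np.errstate(invalid="ignore", divide="ignore"):
                    D[i, i + 1:] = np.where((lengths @ sums) > 0,
                                            D[i, i + 1:] / (lengths @ sums), 0.0)
    else:
        pres = P > 0
        for i in range(n):
            both = pres[:, i, None] | pres[:, i + 1:]
            uniq = pres[:, i, None] ^ pres[:, i + 1:]
            den = lengths @ both
            with np.errstate(invalid="ignore", divide="ignore"):
                D[i, i + 1:] = np.where(den > 0, (lengths @ uniq) / den, 0.0)
    D = D + D.T
    tag = metric if not (metric == "weighted_unifrac" and normalized) \
        else "weighted_unifrac_normalized"
    return DistanceMatrix(list(t.samples), D, tag)


# ---------------------------------------------------------------------------
# Relatedness groups and Monte-Carlo comparison
# ---------------------------------------------------------------------------

def relatedness_pairs(
    ped: Pedigree, cross_pen_only: bool = True
) -> dict[str, list[tuple[str, str]]]:
    """Classify offspring pairs by shared parents: 2 -> fullsib, 1 ->
    halfsib, 0 -> unrelated.  With `cross_pen_only`, pairs sharing a pen
    are excluded from every group (cohabitation control)."""
    off = ped.offspring
    out: dict[str, list[tuple[str, str]]] = {"fullsib": [], "halfsib": [], "unrelated": []}
    recs = list(off.itertuples(index=False))
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.sire_id is None or a.dam_id is None or b.sire_id is None or b.dam_id is None:
                print(f"[diversity] warning: dropping pair with unknown parentage "
                      f"({a.animal_id}, {b.animal_id})")
                continue
            if cross_pen_only and a.pen == b.pen:
                continue
            shared = int(a.sire_id == b.sire_id) + int(a.dam_id == b.dam_id)
            key = ("unrelated", "halfsib", "fullsib")[shared]
            out[key].append((a.animal_id, b.animal_id))
    return out


def compare_groups(
    D: DistanceMatrix,
    pairs: dict[str, list[tuple[str, str]]],
    n_mc: int = 1000,
    seed: int = 0,
) -> list[GroupComparison]:
    """Two-sample t statistics on within-group pair distances, with
    Monte-Carlo p-values from re-partitioning the pooled distances into
    groups of the original sizes.  Ties count as exceedances."""
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(D.samples)}
    vals = {}
    for grp, plist in pairs.items():
        vals[grp] = np.array([D.values[idx[a], idx[b]] for a, b in plist])
    results = []
    combos = [("fullsib", "unrelated"), ("halfsib", "unrelated"), ("fullsib", "halfsib")]
    for ga, gb in combos:
        if ga not in vals or gb not in vals:
            continue
        xa, xb = vals[ga], vals[gb]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {ga if len(xa) < 2 else gb} has fewer than 2 pairs")
        t_obs = _two_sample_t(xa, xb)
        pooled = np.concatenate([xa, xb])
        na = len(xa)
        exceed = 0
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            t_star = _two_sample_t(perm[:na], perm[na:])
            if abs(t_star) >= abs(t_obs) - 1e-15:
                exceed += 1
        p = (1 + exceed) / (n_mc + 1)
        results.append(GroupComparison(f"{ga}_vs_{gb}", t_obs, p, n_mc, len(xa), len(xb)))
    return results


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = (a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
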