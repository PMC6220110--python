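"""OTU tables, taxonomy aggregation and covariate-adjusted taxon traits.

The analysis treats each bacterial taxon's relative abundance as a
zero-inflated quantitative trait: a presence/absence mask plus the natural
log of the relative abundance over the samples where the taxon was
detected, residualized on sex and sampling batch.  Taxa are stratified by
prevalence into *core* (detected in >95% of samples), *random* (20–95%)
and *discarded* (<20%) classes, which decide the association model applied
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
RANK_PREFIX = dict(zip(RANKS, ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]))

UNASSIGNED = "unassigned"


@dataclass
class OTUTable:
    """Samples x features abundance matrix, in counts or relative-abundance mode."""

    samples: list[str]
    features: list[str]
    values: np.ndarray
    mode: str = "counts"  # counts | relabund

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("value matrix shape does not match sample/feature ids")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.mode not in ("counts", "relabund"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relabund":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relabund rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, mode: str = "counts") -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.index], [str(c) for c in df.columns],
                   df.to_numpy(dtype=float), mode)


@dataclass
class TaxonomyMap:
    """otu_id -> 7-rank lineage; missing ranks are empty strings."""

    lineages: dict[str, list[str]]

    def lineage_string(self, otu_id: str) -> str:
        parts = self.lineages[otu_id]
        return ";".join(RANK_PREFIX[r] + parts[i] for i, r in enumerate(RANKS))

    def truncated(self, otu_id: str, level: str) -> str:
        """Lineage string truncated at `level`; empty name at level -> ''. """
        idx = RANKS.index(level)
        parts = self.lineages[otu_id][: idx + 1]
        if not parts[idx]:
            return ""
        return ";".join(RANK_PREFIX[r] + parts[i] for i, r in enumerate(RANKS[: idx + 1]))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("otu_id\tlineage\n")
            for otu in self.lineages:
                fh.write(f"{otu}\t{self.lineage_string(otu)}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        lineages = {}
        for otu, lin in zip(df["otu_id"], df["lineage"]):
            parts = lin.split(";") if lin else []
            names = []
            for i, r in enumerate(RANKS):
                raw = parts[i] if i < len(parts) else ""
                names.append(raw[len(RANK_PREFIX[r]):] if raw.startswith(RANK_PREFIX[r]) else raw)
            lineages[otu] = names
        return cls(lineages)


@dataclass
class PrevalenceClass:
    feature_id: str
    prevalence: float
    category: str  # core | random | discarded


@dataclass
class TraitVector:
    """One taxon's abundance as a two-part trait.

    `log_abund` and `adjusted` are defined only over samples where
    `presence` is true; `adjusted` holds residuals of log abundance on an
    intercept plus sex and batch indicators.
    """

    taxon_id: str
    presence: np.ndarray          # bool, length n
    log_abund: np.ndarray         # length presence.sum()
    adjusted: np.ndarray          # length presence.sum()
    covariates_used: list[str] = field(default_factory=list)

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())

    def write_tsv(self, path: str | Path, samples: list[str]) -> None:
        rows, k = [], 0
        for i, s in enumerate(samples):
            if self.presence[i]:
                rows.append((s, 1, self.log_abund[k], self.adjusted[k]))
                k += 1
            else:
                rows.append((s, 0, np.nan, np.nan))
        pd.DataFrame(rows, columns=["sample_id", "presence", "log_abund", "adjusted"]) \
            .to_csv(path, sep="\t", index=False)


def relative_abundance(t: OTUTable) -> OTUTable:
    """Row-normalize a count table; zeros are preserved."""
    if t.mode != "counts":
        raise ValueError("input must be in counts mode")
    totals = t.values.sum(axis=1)
    empty = np.flatnonzero(totals < 1)
    if empty.size:
        raise ValueError(f"sample {t.samples[empty[0]]!r} has zero total count")
    return OTUTable(list(t.samples), list(t.features), t.values / totals[:, None],
                    mode="relabund")


def aggregate_taxa(t: OTUTable, tax: TaxonomyMap, level: str) -> OTUTable:
    """Sum feature abundances within lineages truncated at `level`.

    OTUs with no assignment at `level` pool into an ``unassigned`` feature.
    Total abundance per sample is conserved at every rank.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}")
    groups: dict[str, list[int]] = {}
    for j, otu in enumerate(t.features):
        key = tax.truncated(otu, level) if otu in tax.lineages else ""
        groups.setdefault(key or UNASSIGNED, []).append(j)
    names = sorted(groups)
    vals = np.column_stack([t.values[:, groups[name]].sum(axis=1) for name in names])
    return OTUTable(list(t.samples), names, vals, mode=t.mode)


def classify_prevalence(
    t: OTUTable, core_min: float = 0.95, random_min: float = 0.20
) -> list[PrevalenceClass]:
    """Stratify features by detection prevalence.

    core: prevalence > core_min (strict); random: random_min <= prevalence
    <= core_min (both boundaries inclusive); discarded: below random_min.
    """
    if core_min <= random_min:
        raise ValueError("core_min must exceed random_min")
    if not t.features:
        raise ValueError("empty table")
    prev = (t.values > 0).mean(axis=0)
    out = []
    for fid, pv in zip(t.features, prev):
        if pv > core_min:
            cat = "core"
        elif pv >= random_min:
            cat = "random"
        else:
            cat = "discarded"
        out.append(PrevalenceClass(fid, float(pv), cat))
    return out


def prepare_trait(
    abund: np.ndarray,
    sex: np.ndarray,
    batch: np.ndarray,
    taxon_id: str = "",
) -> TraitVector:
    """Build the two-part trait for one taxon.

    presence = abund > 0; log_abund = ln(abund) over present samples (no
    pseudocount — zeros are handled by the binary part, never logged);
    adjusted = residuals of log_abund on intercept + sex + batch
    indicators, fit over the present samples only.
    """
    abund = np.asarray(abund, dtype=float)
    if (abund < 0).any():
        raise ValueError("abundances must be non-negative")
    if not (len(abund) == len(sex) == len(batch)):
        raise ValueError("abund, sex and batch must have equal length")
    presence = abund > 0
    if presence.sum() < 3:
        raise ValueError("fewer than 3 present samples; trait unfittable")
    log_abund = np.log(abund[presence])
    design = _covariate_design(np.asarray(sex)[presence], np.asarray(batch)[presence])
    beta, *_ = np.linalg.lstsq(design, log_abund, rcond=None)
    adjusted = log_abund - design @ beta
    return TraitVector(taxon_id, presence, log_abund, adjusted, ["sex", "batch"])


def _covariate_design(sex: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Intercept + drop-first indicator coding for sex and batch."""
    cols = [np.ones(len(sex))]
    for arr in (sex, batch):
        levels = pd.unique(arr)
        for lev in levels[1:]:
            cols.append((arr == lev).astype(float))
    return np.column_stack(cols)
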