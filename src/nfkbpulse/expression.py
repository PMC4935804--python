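"""Gene-expression utilities for panel-count data.

Implements the count-normalization recipe used for nCounter-style panels
(positive-control scaling by geometric means, stringent background
correction from negative controls, housekeeping scaling), median log2
fold-change tables, and the correlation of per-gene fold changes with
integrated nuclear NF-κB activity across stimulation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["CountMatrix", "normalize_counts", "fold_change_table",
           "correlate_activity"]

GENE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")


@dataclass
class CountMatrix:
    """Raw panel counts: genes × samples with gene classes and sample
    condition labels (e.g. U, T, TT, T_T, TTT, TIT, I) and replicate index."""

    counts: pd.DataFrame            # genes × samples, non-negative
    gene_class: pd.Series           # per gene, one of GENE_CLASSES
    condition: pd.Series            # per sample
    replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        for cls in ("housekeeping", "positive_control", "negative_control"):
            if not (self.gene_class == cls).any():
                raise ValueError(f"need at least one {cls} gene")
        if self.replicate is None:
            reps = {}
            counts: dict[str, int] = {}
            for s in self.counts.columns:
                c = self.condition[s]
                counts[c] = counts.get(c, 0) + 1
                reps[s] = counts[c]
            self.replicate = pd.Series(reps)

    def genes_of(self, cls: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == cls]

    def save(self, path, sep: str = "\t") -> None:
        out = self.counts.copy()
        out.insert(0, "gene_class", self.gene_class)
        out.to_csv(path, sep=sep)
        meta = pd.DataFrame({"condition": self.condition,
                             "replicate": self.replicate})
        meta.to_csv(str(path) + ".samples", sep=sep)

    @classmethod
    def load(cls, path, sep: str = "\t") -> "CountMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        gene_class = df.pop("gene_class")
        meta = pd.read_csv(str(path) + ".samples", sep=sep, index_col=0)
        return cls(df, gene_class, meta["condition"], meta.get("replicate"))


def _geomean(x: pd.DataFrame | pd.Series, axis: int = 0) -> pd.Series | float:
    # counts + 0.5 so zero counts do not zero out the whole mean
    return np.exp(np.log(x + 0.5).mean(axis=axis))


def normalize_counts(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-step panel normalization; returns (linear, log2) matrices.

    1. per-sample scaling by grand-geometric-mean / sample-geometric-mean of
       the positive controls;
    2. stringent background correction: mean + 2 s.d. of the negative
       controls subtracted, floored at zero;
    3. per-sample scaling by the housekeeping geometric-mean ratio.
    """
    pos = cm.counts.loc[cm.genes_of("positive_control")]
    pos_gm = _geomean(pos, axis=0)
    if (pos_gm <= 0.5).any():
        raise ValueError("zero geometric mean in positive controls")
    scale1 = float(np.exp(np.log(pos_gm).mean())) / pos_gm
    x = cm.counts * scale1

    neg = x.loc[cm.genes_of("negative_control")]
    background = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    x = (x - background).clip(lower=0.0)

    hk = x.loc[cm.genes_of("housekeeping")]
    hk_gm = _geomean(hk, axis=0)
    if (hk_gm <= 0.5).any():
        raise ValueError("zero geometric mean in housekeeping controls")
    scale2 = float(np.exp(np.log(hk_gm).mean())) / hk_gm
    x = x * scale2
    return x, np.log2(x + 1.0)


def fold_change_table(normalized: pd.DataFrame, cm: CountMatrix,
                      reference: str = "U", cluster: bool = True,
                      ) -> pd.DataFrame:
    """Median log2 fold change per endogenous gene and condition vs the
    reference (untreated) condition, median over replicate pairings.

    Genes whose reference counts are all zero get missing values.  Rows are
    ordered by hierarchical clustering of the fold-change profiles when
    ``cluster`` is set (display order, average linkage on euclidean
    distance).
    """
    conds = cm.condition
    if reference not in set(conds):
        raise ValueError(f"reference condition {reference!r} not present")
    genes = cm.genes_of("endogenous")
    ref_cols = conds.index[conds == reference]
    ref = normalized.loc[genes, ref_cols]
    out = {}
    for cond in sorted(set(conds) - {reference}):
        cols = conds.index[conds == cond]
        ratios = []
        for c in cols:
            for r in ref_cols:
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios.append(np.log2(normalized.loc[genes, c] + 1.0)
                                  - np.log2(ref[r] + 1.0))
        out[cond] = pd.concat(ratios, axis=1).median(axis=1)
    fc = pd.DataFrame(out)
    all_zero = (ref.sum(axis=1) == 0)
    fc[all_zero] = np.nan
    if cluster and len(fc) > 2:
        filled = fc.fillna(0.0)
        order = leaves_list(linkage(pdist(filled.to_numpy()), method="average"))
        fc = fc.iloc[order]
    return fc


def correlate_activity(fold_changes: pd.DataFrame,
                       activity: Mapping[str, float]) -> pd.Series:
    """Pearson correlation, per gene, between linear fold change and
    integrated nuclear NF-κB activity across conditions.

    Zero-variance genes are omitted from the result (flagged by absence).
    """
    conds = [c for c in fold_changes.columns if c in activity]
    if len(conds) < 3:
        raise ValueError("need at least 3 overlapping conditions")
    act = np.array([activity[c] for c in conds], dtype=float)
    out = {}
    for gene, row in fold_changes[conds].iterrows():
        vals = 2.0 ** row.to_numpy(dtype=float)     # back to linear ratios
        if np.isnan(vals).any() or np.std(vals) == 0 or np.std(act) == 0:
            continue
        out[gene] = float(np.corrcoef(vals, act)[0, 1])
    return pd.Series(out, name="pearson_r")
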