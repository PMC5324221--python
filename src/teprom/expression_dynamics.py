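"""Expression filtering, stage fold-changes, and the gene/sample groupings
used downstream: hierarchical clusters of stage profiles, k-means tissue
clusters, fold-change rank bins, and blastocyst sample subtypes.

Clustering follows the early-embryo convention: genes with a maximum below
5 expression units are removed, survivors are ranked by standard deviation
and the most variable kept, rows are standardized (mean 0, SD 1), and
agglomeration uses 1 - Pearson correlation with average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix

__all__ = ["FoldChangeTable", "GeneClusters", "filter_genes", "fold_change",
           "hierarchical_cluster", "kmeans_cluster", "rank_bins",
           "split_blastocyst_types", "row_standardize"]


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold-change between two named stages."""

    values: pd.Series           # gene_id -> log2 FC
    stage_pair: tuple           # (from_stage, to_stage)
    pseudocount: float

    @property
    def genes(self):
        return list(self.values.index)


@dataclass
class GeneClusters:
    """A partition of genes (or samples) into labelled groups."""

    labels: pd.Series           # id -> label
    method: str                 # hierarchical | kmeans | rank_bin
    k: int | None = None
    group_size: int | None = None
    extra: dict = field(default_factory=dict)

    def members(self, label):
        return list(self.labels.index[self.labels == label])

    def label_order(self):
        if self.method == "rank_bin":
            return sorted(self.labels.unique())
        return sorted(self.labels.unique(), key=lambda x: (isinstance(x, str), x))


def row_standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row mean 0, SD 1 (population SD); zero-variance rows -> NaN."""
    mat = values.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mat - mu) / sd
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def filter_genes(expr: ExpressionMatrix, min_level: float = 5.0,
                 top_n: int = 12000) -> list:
    """Drop genes never reaching ``min_level``; keep the ``top_n`` most
    variable of the survivors (by sample SD, descending; ties by gene_id)."""
    vals = expr.values
    keep = vals.max(axis=1) >= min_level
    survivors = vals.loc[keep]
    sd = survivors.std(axis=1, ddof=1).fillna(0.0)
    order = sorted(survivors.index, key=lambda g: (-sd[g], g))
    return order[:top_n]


def fold_change(expr: ExpressionMatrix, from_stage: str, to_stage: str,
                pseudocount: float = 1.0, genes=None) -> FoldChangeTable:
    """log2((mean_to + pc) / (mean_from + pc)) per gene, means over the
    samples of each stage."""
    for stage in (from_stage, to_stage):
        if stage not in expr.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        if not expr.stage_samples(stage):
            raise ValueError(f"stage {stage!r} has no samples")
    vals = expr.values if genes is None else expr.values.loc[list(genes)]
    m_from = vals[expr.stage_samples(from_stage)].mean(axis=1)
    m_to = vals[expr.stage_samples(to_stage)].mean(axis=1)
    fc = np.log2((m_to + pseudocount) / (m_from + pseudocount))
    return FoldChangeTable(fc, (from_stage, to_stage), pseudocount)


def _correlation_linkage(values: pd.DataFrame):
    """Average-linkage tree on the 1 - Pearson distance of the rows."""
    dist = pdist(values.to_numpy(dtype=float), metric="correlation")
    return average(dist)


def hierarchical_cluster(expr, k: int, row_standardize_first: bool = True,
                         genes=None) -> GeneClusters:
    """Agglomerative clustering of gene stage-profiles into exactly k groups.

    Distance is 1 - Pearson correlation, linkage is average.  Rows are
    sorted by gene_id before agglomeration so the result is invariant to
    input row order; zero-variance rows are excluded with a warning.
    Returns a GeneClusters whose ``extra['linkage']`` holds the scipy
    linkage matrix and ``extra['row_order']`` the row ids used.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if genes is not None:
        vals = vals.loc[list(genes)]
    vals = vals.sort_index()
    sd = vals.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance rows")
        vals = vals.loc[sd > 0]
    if k > len(vals):
        raise ValueError(f"k={k} exceeds {len(vals)} usable rows")
    if row_standardize_first:
        vals = row_standardize(vals)
    link = _correlation_linkage(vals)
    raw = fcluster(link, t=k, criterion="maxclust")
    labels = _canonical_labels(raw, vals.index)
    return GeneClusters(labels, "hierarchical", k=k,
                        extra={"linkage": link, "row_order": list(vals.index)})


def _canonical_labels(raw, index) -> pd.Series:
    """Relabel clusters 1..k in order of first appearance along the index."""
    mapping, nxt = {}, 1
    out = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out.append(mapping[lab])
    return pd.Series(out, index=index)


def kmeans_cluster(expr, k: int = 25, seed: int = 0, n_init: int = 10,
                   genes=None) -> GeneClusters:
    """Lloyd's k-means on row-standardized profiles, best of n_init restarts."""
    from sklearn.cluster import KMeans

    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if genes is not None:
        vals = vals.loc[list(genes)]
    sd = vals.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance rows")
        vals = vals.loc[sd > 0]
    if k > len(vals):
        raise ValueError(f"k={k} exceeds {len(vals)} usable rows")
    z = row_standardize(vals)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(z.to_numpy())
    labels = _canonical_labels(raw + 1, vals.index)
    return GeneClusters(labels, "kmeans", k=k,
                        extra={"seed": seed, "inertia": float(km.inertia_)})


def rank_bins(fc: FoldChangeTable, group_size: int = 500) -> GeneClusters:
    """Sort genes by fold-change (descending, ties by gene_id) and cut into
    consecutive bins of ``group_size``.

    A trailing remainder of at least half a bin is kept (flagged in
    ``extra['remainder_kept']``); a smaller one is dropped with a warning.
    Labels are 1-based bin numbers, bin 1 = highest fold-changes.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    order = sorted(fc.values.index, key=lambda g: (-fc.values[g], g))
    n_full = len(order) // group_size
    remainder = len(order) - n_full * group_size
    labels, ids = [], []
    for b in range(n_full):
        ids.extend(order[b * group_size:(b + 1) * group_size])
        labels.extend([b + 1] * group_size)
    remainder_kept = False
    if remainder:
        if remainder >= group_size / 2:
            ids.extend(order[n_full * group_size:])
            labels.extend([n_full + 1] * remainder)
            remainder_kept = True
        else:
            warnings.warn(f"dropping trailing remainder bin of {remainder} genes")
    return GeneClusters(pd.Series(labels, index=ids), "rank_bin",
                        group_size=group_size,
                        extra={"remainder_kept": remainder_kept})


def split_blastocyst_types(expr: ExpressionMatrix, stage: str = "blastocyst",
                           k: int = 3) -> GeneClusters:
    """Hierarchically cluster the samples of one stage into k subtypes.

    Same metric/linkage as gene clustering, applied to the sample columns.
    Labels 1..k are assigned by decreasing cluster size (ties by smallest
    sample id).
    """
    samples = expr.stage_samples(stage)
    if len(samples) < k:
        raise ValueError(f"need >= {k} samples in stage {stage!r}, have {len(samples)}")
    sub = expr.values[samples].T  # samples in rows
    sub = sub.sort_index()
    sub = sub.loc[:, sub.std(axis=0, ddof=0) > 0]
    if k == 1:
        return GeneClusters(pd.Series(1, index=sub.index), "hierarchical", k=1)
    link = _correlation_linkage(row_standardize(sub))
    raw = fcluster(link, t=k, criterion="maxclust")
    tmp = pd.Series(raw, index=sub.index)
    sizes = tmp.value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], min(tmp.index[tmp == lab])))
    relabel = {old: i + 1 for i, old in enumerate(order)}
    return GeneClusters(tmp.map(relabel), "hierarchical", k=k)
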