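"""The statistical battery linking promoter repeat content to expression
dynamics: cluster enrichment (chi-square / Fisher + BH FDR), presence
t-tests, dosage and distance curves, rank-bin correlation, multiple linear
regression of fold-change on feature counts, expression-count correlation,
ortholog-difference association, and gene-set over-representation.

Conventions used throughout: t-tests are Welch's (unequal variance,
two-sided); multiple testing is Benjamini-Hochberg; the enrichment
background is all other clusters combined.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_dynamics import FoldChangeTable, GeneClusters
from .repeat_features import (distance_bin_labels, distance_bins,
                              dosage_bin, dosage_categories)

__all__ = ["bh_fdr", "cluster_enrichment", "presence_fc_test",
           "dosage_analysis", "distance_analysis", "bin_correlation",
           "multiple_regression", "expression_count_correlation",
           "ortholog_delta_association", "geneset_enrichment", "welch_t"]

MIN_GENES_PER_FEATURE = 20  # features rarer than this are skipped in per-type tests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def welch_t(a, b):
    """Welch two-sided t-test; (t, p) with degenerate zero-variance handling.

    If both groups have zero variance: p=1.0 when means are equal, NaN
    (degenerate) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, np.nan)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cluster enrichment (Fig 2 analogue)
# ---------------------------------------------------------------------------

def cluster_enrichment(binary: pd.DataFrame, clusters: GeneClusters) -> pd.DataFrame:
    """Per (feature, cluster) 2x2 enrichment of promoter feature presence.

    ``binary``: genes x features boolean (has >= 1 occurrence).  For each
    feature and cluster, the table {in cluster vs all other clusters
    combined} x {present vs absent} is tested by Pearson chi-square without
    continuity correction, or Fisher's exact test when any expected cell is
    below 5.  BH FDR is applied over all tests jointly.
    """
    labels = clusters.labels
    label_values = clusters.label_order()
    if len(label_values) < 2:
        raise ValueError("need >= 2 clusters")
    genes = [g for g in binary.index if g in labels.index]
    binary = binary.loc[genes]
    labels = labels.loc[genes]

    rows = []
    for feature in binary.columns:
        present = binary[feature].to_numpy(dtype=bool)
        if not present.any():
            warnings.warn(f"feature {feature} absent everywhere; skipped")
            continue
        for lab in label_values:
            inc = (labels == lab).to_numpy()
            n_with = int((present & inc).sum())
            n_without = int((~present & inc).sum())
            n_with_bg = int((present & ~inc).sum())
            n_without_bg = int((~present & ~inc).sum())
            table = np.array([[n_with, n_without], [n_with_bg, n_without_bg]])
            in_frac = n_with / max(inc.sum(), 1)
            bg_frac = n_with_bg / max((~inc).sum(), 1)
            fold = in_frac / bg_frac if bg_frac > 0 else np.nan
            if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                chi2, p, test = np.nan, np.nan, "degenerate"
            else:
                expected = stats.contingency.expected_freq(table)
                if (expected < 5).any():
                    _, p = stats.fisher_exact(table)
                    chi2, test = np.nan, "fisher"
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    test = "chi2"
            rows.append(dict(feature=feature, cluster=lab, n_with=n_with,
                             n_without=n_without, n_with_bg=n_with_bg,
                             n_without_bg=n_without_bg, frac_genes_with=in_frac,
                             frac_bg=bg_frac, fold_enrichment=fold,
                             chi2=chi2, p=p, test=test))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
    return out


def presence_fc_test(binary: pd.DataFrame, fc: FoldChangeTable,
                     min_genes: int = MIN_GENES_PER_FEATURE) -> pd.DataFrame:
    """Welch t-test of fold-change, genes with >=1 occurrence vs none,
    per feature, BH FDR across features."""
    genes = [g for g in binary.index if g in fc.values.index]
    binary = binary.loc[genes]
    y = fc.values.loc[genes]
    rows = []
    for feature in binary.columns:
        mask = binary[feature].to_numpy(dtype=bool)
        a, b = y[mask], y[~mask]
        if mask.sum() < max(2, min_genes) or (~mask).sum() < 2:
            rows.append(dict(feature=feature, n_with=int(mask.sum()),
                             n_without=int((~mask).sum()), mean_with=np.nan,
                             mean_without=np.nan, diff=np.nan, t=np.nan,
                             p=np.nan, flag="too_few"))
            continue
        t, p = welch_t(a, b)
        rows.append(dict(feature=feature, n_with=int(mask.sum()),
                         n_without=int((~mask).sum()),
                         mean_with=float(a.mean()), mean_without=float(b.mean()),
                         diff=float(a.mean() - b.mean()), t=t, p=p,
                         flag="degenerate" if np.isnan(p) else ""))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
    return out


# ---------------------------------------------------------------------------
# dosage and distance curves (Fig 5 analogue)
# ---------------------------------------------------------------------------

def _stars(p) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def dosage_analysis(counts: pd.Series, fc: FoldChangeTable, cap: int = 5) -> pd.DataFrame:
    """Mean fold-change by copy-number category 0,1,...,>=cap with Welch
    tests between adjacent categories.

    Returns one row per category: n_genes, mean/SE of log2 FC, and the
    p-value versus the previous (lower) occupied category.
    """
    genes = [g for g in counts.index if g in fc.values.index]
    counts = counts.loc[genes]
    y = fc.values.loc[genes]
    cats = dosage_categories(cap)
    groups = {c: y[[dosage_bin(int(v), cap) == c for v in counts]] for c in cats}
    rows, prev = [], None
    for c in cats:
        g = groups[c]
        n = len(g)
        mean = float(g.mean()) if n else np.nan
        se = float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        p_adj = np.nan
        if prev is not None and n >= 2 and len(groups[prev]) >= 2:
            _, p_adj = welch_t(g, groups[prev])
        rows.append(dict(category=c, n_genes=n, mean_fc=mean, se=se,
                         p_vs_prev=p_adj, stars=_stars(p_adj) if not np.isnan(p_adj) else ""))
        if n:
            prev = c
    return pd.DataFrame(rows)


def distance_analysis(nearest: pd.Series, fc: FoldChangeTable, edges) -> pd.DataFrame:
    """Mean fold-change by nearest-occurrence distance bin.

    Genes with no occurrence form the reference category; each bin reports
    its mean, SE, contrast versus the reference mean, and a Welch p-value
    against the reference group.
    """
    genes = [g for g in nearest.index if g in fc.values.index]
    nearest = nearest.loc[genes]
    y = fc.values.loc[genes]
    ref = y[nearest.isna()]
    ref_mean = float(ref.mean()) if len(ref) else np.nan
    rows = [dict(bin="none", n_genes=len(ref), mean_fc=ref_mean,
                 se=float(ref.std(ddof=1) / np.sqrt(len(ref))) if len(ref) > 1 else np.nan,
                 contrast=0.0, t=np.nan, p=np.nan)]
    assigned = nearest.map(lambda d: distance_bins(d, edges))
    for lab in distance_bin_labels(edges):
        g = y[assigned == lab]
        n = len(g)
        if n == 0:
            rows.append(dict(bin=lab, n_genes=0, mean_fc=np.nan, se=np.nan,
                             contrast=np.nan, t=np.nan, p=np.nan))
            continue
        t, p = welch_t(g, ref) if n >= 2 and len(ref) >= 2 else (np.nan, np.nan)
        rows.append(dict(bin=lab, n_genes=n, mean_fc=float(g.mean()),
                         se=float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                         contrast=float(g.mean() - ref_mean), t=t, p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-bin correlation (Fig 4d analogue)
# ---------------------------------------------------------------------------

def bin_correlation(bins: GeneClusters, binary: pd.Series, fc: FoldChangeTable):
    """Pearson correlation between per-bin mean fold-change and per-bin
    fraction of genes carrying the feature.

    Returns (pcc, p, per_bin DataFrame).  The p-value is the two-sided
    t-transform with n_bins - 2 df.  A constant fraction across bins makes
    the PCC undefined (NaN, flagged in the DataFrame attrs).
    """
    labels = bins.labels
    if bins.method != "rank_bin":
        raise ValueError("bin_correlation expects rank_bin clusters")
    order = bins.label_order()
    if len(order) < 3:
        raise ValueError("need >= 3 bins")
    recs = []
    for lab in order:
        members = bins.members(lab)
        frac = float(binary.loc[members].mean())
        mean_fc = float(fc.values.loc[members].mean())
        recs.append(dict(bin=lab, n_genes=len(members), mean_fc=mean_fc,
                         frac_with=frac))
    per_bin = pd.DataFrame(recs)
    x, y = per_bin["mean_fc"], per_bin["frac_with"]
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        per_bin.attrs["flag"] = "constant"
        return np.nan, np.nan, per_bin
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), per_bin


# ---------------------------------------------------------------------------
# multiple regression (Fig 5e analogue)
# ---------------------------------------------------------------------------

def _drop_collinear(X: pd.DataFrame):
    """Greedily keep a maximal independent column set, in lexicographic
    order, so that which column of a collinear group is dropped is
    deterministic.  Returns (kept columns, dropped columns)."""
    cols = sorted(X.columns)
    kept, dropped = [], []
    mat = np.empty((len(X), 0))
    rank = 0
    for c in cols:
        cand = np.column_stack([mat, X[c].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(c)
            mat, rank = cand, r
        else:
            dropped.append(c)
    return kept, dropped


def multiple_regression(fc: FoldChangeTable, X: pd.DataFrame):
    """OLS of log2 fold-change on promoter feature columns.

    Zero-variance columns are dropped with a note; perfectly collinear
    groups keep only their lexicographically first member.  Returns a tidy
    per-feature DataFrame (coef, se, t, p, fdr) whose ``attrs`` carry n,
    r_squared, and the dropped-column lists.
    """
    import statsmodels.api as sm

    genes = [g for g in X.index if g in fc.values.index]
    X = X.loc[genes].astype(float)
    y = fc.values.loc[genes].astype(float)

    zero_var = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if zero_var:
        warnings.warn(f"dropping zero-variance features: {zero_var}")
        X = X.drop(columns=zero_var)
    kept, collinear = _drop_collinear(X)
    if collinear:
        warnings.warn(f"dropping collinear features: {collinear}")
    X = X[kept]
    if len(X) <= X.shape[1]:
        raise ValueError(f"n={len(X)} genes <= p={X.shape[1]} features")

    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    feats = list(X.columns)
    out = pd.DataFrame({
        "feature": feats,
        "coef": fit.params[feats].to_numpy(),
        "se": fit.bse[feats].to_numpy(),
        "t": fit.tvalues[feats].to_numpy(),
        "p": fit.pvalues[feats].to_numpy(),
    })
    out["fdr"] = bh_fdr(out["p"])
    out.attrs.update(n=int(fit.nobs), r_squared=float(fit.rsquared),
                     dropped_zero_variance=zero_var, dropped_collinear=collinear,
                     intercept=float(fit.params["const"]))
    return out


# ---------------------------------------------------------------------------
# expression-count correlation (Fig 5f analogue)
# ---------------------------------------------------------------------------

def _partial_corr(x, y, z):
    """Correlation of x and y after residualizing both on z (with intercept)."""
    z = np.column_stack([np.ones(len(z)), np.asarray(z, dtype=float)])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    # a residual that is zero to numerical precision carries no signal
    for r, orig in ((rx, x), (ry, y)):
        if r.std() <= 1e-10 * max(1.0, np.abs(orig).max()):
            return 0.0, np.nan
    return stats.pearsonr(rx, ry)


def expression_count_correlation(expr, counts: pd.Series, pseudocount: float = 1.0,
                                 control: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample Pearson correlation of log2(expression + pc) with promoter
    copy counts; optionally partial, controlling a covariate (e.g. CpG-island
    count) by residual-on-residual correlation."""
    genes = [g for g in counts.index if g in expr.values.index]
    counts_v = counts.loc[genes].to_numpy(dtype=float)
    rows = []
    for sample in expr.samples:
        x = np.log2(expr.values.loc[genes, sample].to_numpy(dtype=float) + pseudocount)
        r, p = stats.pearsonr(x, counts_v) if counts_v.std() > 0 and x.std() > 0 else (np.nan, np.nan)
        row = dict(sample=sample, stage=expr.design[sample], pcc=float(r), p=float(p))
        if control is not None:
            pr, pp = _partial_corr(x, counts_v, control.loc[genes].to_numpy(dtype=float))
            row["partial_pcc"], row["partial_p"] = float(pr), float(pp)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ortholog conservation (Fig 7 analogue)
# ---------------------------------------------------------------------------

def ortholog_delta_association(pairs: pd.DataFrame, counts_a: pd.Series,
                               counts_b: pd.Series, fc_a: FoldChangeTable | None = None,
                               fc_b: FoldChangeTable | None = None) -> dict:
    """Cross-species conservation of promoter copy counts.

    ``pairs`` has columns (gene_a, gene_b).  Reports the Pearson correlation
    of counts across ortholog pairs, and, when fold-changes are given, the
    regression of delta-fold-change on delta-count.
    """
    usable = pairs[(pairs.iloc[:, 0].isin(counts_a.index))
                   & (pairs.iloc[:, 1].isin(counts_b.index))]
    if not len(usable):
        raise ValueError("no usable ortholog pairs")
    ca = counts_a.loc[usable.iloc[:, 0]].to_numpy(dtype=float)
    cb = counts_b.loc[usable.iloc[:, 1]].to_numpy(dtype=float)
    if ca.std() == 0 or cb.std() == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(ca, cb)
    out = dict(n_pairs=int(len(usable)), count_pcc=float(r), count_p=float(p))
    if fc_a is not None and fc_b is not None:
        mask = (usable.iloc[:, 0].isin(fc_a.values.index)
                & usable.iloc[:, 1].isin(fc_b.values.index)).to_numpy()
        sub = usable[mask]
        d_count = (counts_a.loc[sub.iloc[:, 0]].to_numpy(dtype=float)
                   - counts_b.loc[sub.iloc[:, 1]].to_numpy(dtype=float))
        d_fc = (fc_a.values.loc[sub.iloc[:, 0]].to_numpy(dtype=float)
                - fc_b.values.loc[sub.iloc[:, 1]].to_numpy(dtype=float))
        if len(sub) > 2 and d_count.std() > 0:
            slope, intercept, rr, pp, se = stats.linregress(d_count, d_fc)
            out.update(delta_n=int(len(sub)), delta_slope=float(slope),
                       delta_r=float(rr), delta_p=float(pp), delta_se=float(se))
    return out


# ---------------------------------------------------------------------------
# gene-set over-representation (Fig 7e-h analogue)
# ---------------------------------------------------------------------------

def geneset_enrichment(query, universe, collections: dict) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene set.

    For each collection set S: P(X >= |query & S|) drawing |query| genes
    from a universe of which |S & universe| are in S.  Fold is the ratio of
    in-query to in-universe fractions; BH FDR across sets.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("query is empty (after intersecting with universe)")
    M, n = len(universe), len(query)
    rows = []
    for name, value in collections.items():
        members = set(value[1] if isinstance(value, tuple) else value) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        expected = n * K / M
        fold = k / expected if expected > 0 else np.nan
        rows.append(dict(set=name, n_set=K, n_overlap=k, expected=expected,
                         fold=fold, p=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    return out
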