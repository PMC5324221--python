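"""Genome-wide repeat statistics: lognormal copy-number fits, inter-repeat
distance spectra, gene-region enrichment, and strand preference near genes.

Region classification paints each chromosome base with one label using the
precedence promoter > exon > intron > downstream > intergenic, and assigns a
repeat to the label at its midpoint; expected counts under the null are
proportional to total region length, which makes the length-weighted mean
fold exactly 1 per repeat name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_fdr

__all__ = ["LognormalFit", "StrandBiasResult", "copy_number_fit",
           "inter_repeat_distances", "region_enrichment", "strand_preference",
           "REGIONS", "paint_regions"]

REGIONS = ["intergenic", "promoter", "exon", "intron", "downstream"]
_RCODE = {name: i for i, name in enumerate(REGIONS)}


@dataclass
class LognormalFit:
    mu: float                   # mean of natural-log copy counts
    sigma: float                # population SD of natural-log copy counts
    n_types: int
    ks_stat: float
    ks_p: float                 # approximate: parameters were estimated
    counts: pd.Series = None


def copy_number_fit(repeats) -> LognormalFit:
    """MLE lognormal fit to the per-name copy-count distribution.

    mu is the mean and sigma the population SD of log counts; the KS
    goodness-of-fit p-value is flagged approximate because the parameters
    are estimated from the same data.
    """
    names = pd.Series([r.name for r in repeats])
    counts = names.value_counts().sort_index()
    if not len(counts):
        raise ValueError("no repeats")
    logc = np.log(counts.to_numpy(dtype=float))
    mu = float(logc.mean())
    sigma = float(logc.std(ddof=0))
    if sigma > 0:
        ks_stat, ks_p = stats.kstest(logc, "norm", args=(mu, sigma))
    else:
        ks_stat, ks_p = np.nan, np.nan
    return LognormalFit(mu, sigma, len(counts), float(ks_stat), float(ks_p),
                        counts=counts)


def inter_repeat_distances(repeats, name: str, n_bins: int = 20):
    """Distances between consecutive same-name repeat starts per chromosome.

    Returns (distances, histogram DataFrame on log10 bins, log-log slope of
    the empirical density).  No distributional fit is asserted; the slope is
    a descriptive tail statistic.
    """
    starts: dict[str, list] = {}
    for r in repeats:
        if r.name == name:
            starts.setdefault(r.chrom, []).append(r.start)
    dists = []
    for chrom_starts in starts.values():
        s = np.sort(np.asarray(chrom_starts))
        if len(s) > 1:
            dists.extend(np.diff(s).tolist())
    dists = np.asarray([d for d in dists if d > 0], dtype=float)
    if len(dists) < 2:
        return dists, pd.DataFrame(columns=["bin_lo", "bin_hi", "count", "density"]), np.nan
    edges = np.logspace(np.log10(dists.min()), np.log10(dists.max() + 1), n_bins + 1)
    counts, _ = np.histogram(dists, bins=edges)
    widths = np.diff(edges)
    density = counts / widths / len(dists)
    hist = pd.DataFrame(dict(bin_lo=edges[:-1], bin_hi=edges[1:],
                             count=counts, density=density))
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = density > 0
    slope = np.nan
    if mask.sum() >= 3:
        slope = float(np.polyfit(np.log10(centers[mask]), np.log10(density[mask]), 1)[0])
    return dists, hist, slope


def paint_regions(genes, tss_map, contig_lengths, promoter_spec=(2000, 0),
                  downstream_bp: int = 2000) -> dict:
    """Per-chromosome uint8 label arrays (one label per base).

    Painted in increasing precedence — downstream, intron, exon, promoter —
    so higher-precedence labels overwrite lower ones; unpainted bases are
    intergenic.
    """
    from .promoter_model import make_promoters

    labels = {chrom: np.zeros(length, dtype=np.uint8)
              for chrom, length in contig_lengths.items()}

    def paint(chrom, start, end, code):
        arr = labels[chrom]
        s, e = max(0, start), min(len(arr), end)
        if s < e:
            arr[s:e] = code

    for g in genes:
        if g.strand == "+":
            paint(g.chrom, g.end, g.end + downstream_bp, _RCODE["downstream"])
        else:
            paint(g.chrom, g.start - downstream_bp, g.start, _RCODE["downstream"])
    for g in genes:
        paint(g.chrom, g.start, g.end, _RCODE["intron"])
    for g in genes:
        for tx in g.transcripts:
            for (s, e) in tx.exons:
                paint(g.chrom, s, e, _RCODE["exon"])
    for w in make_promoters(genes, tss_map, promoter_spec, contig_lengths):
        paint(w.chrom, w.start, w.end, _RCODE["promoter"])
    return labels


def region_enrichment(repeats, genes, tss_map, contig_lengths, level: str = "klass",
                      promoter_spec=(2000, 0), downstream_bp: int = 2000) -> pd.DataFrame:
    """Observed/expected repeat counts per (name|family|klass, region).

    A repeat is assigned to the region at its midpoint; expected counts are
    proportional to the total length of each region class.  Each (key,
    region) cell gets a 1-df chi-square of {in region vs not} against the
    length expectation; BH FDR across all cells.
    """
    labels = paint_regions(genes, tss_map, contig_lengths, promoter_spec, downstream_bp)
    region_len = np.zeros(len(REGIONS), dtype=np.int64)
    for arr in labels.values():
        region_len += np.bincount(arr, minlength=len(REGIONS))
    genome_len = int(region_len.sum())
    usable_regions = [r for r in REGIONS if region_len[_RCODE[r]] > 0]

    obs: dict = {}
    for r in repeats:
        arr = labels.get(r.chrom)
        if arr is None:
            continue
        region = REGIONS[arr[min(r.midpoint, len(arr) - 1)]]
        key = r.level(level)
        obs.setdefault(key, np.zeros(len(REGIONS), dtype=np.int64))[_RCODE[region]] += 1

    rows = []
    for key in sorted(obs):
        total = int(obs[key].sum())
        for region in usable_regions:
            frac = region_len[_RCODE[region]] / genome_len
            expected = total * frac
            observed = int(obs[key][_RCODE[region]])
            fold = observed / expected if expected > 0 else np.nan
            if 0 < expected < total:
                chi2, p = stats.chisquare([observed, total - observed],
                                          [expected, total - expected])
            else:
                chi2, p = np.nan, np.nan
            rows.append({"key": key, "region": region, "n_total": total,
                         "observed": observed, "expected": expected,
                         "region_length": int(region_len[_RCODE[region]]),
                         "fold": fold, "chi2": float(chi2), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
    return out


@dataclass
class StrandBiasResult:
    name: str
    region: str
    n_same: int
    n_opposite: int
    ratio: float
    chi2: float
    p: float
    fdr: float = np.nan


def strand_preference(repeats, genes, tss_map, contig_lengths,
                      region: str = "gene_body", promoter_spec=(2000, 0)) -> list:
    """Same- vs opposite-strand counts of each repeat name inside gene
    regions, chi-squared against a 50:50 null, BH FDR across names.

    region: 'gene_body' (the gene span), 'intron', or 'promoter'.  A repeat
    (by midpoint) inside regions of genes on both strands is excluded.
    """
    from .promoter_model import IntervalIndex, make_promoters

    idx = IntervalIndex()
    if region == "gene_body":
        for g in genes:
            idx.add(g.chrom, g.start, g.end, g.strand)
    elif region == "promoter":
        for w in make_promoters(genes, tss_map, promoter_spec, contig_lengths):
            idx.add(w.chrom, w.start, w.end, w.strand)
    elif region == "intron":
        for g in genes:
            exons = sorted({iv for tx in g.transcripts for iv in tx.exons})
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 < s2:
                    idx.add(g.chrom, e1, s2, g.strand)
    else:
        raise ValueError(f"unknown region {region!r}")

    tallies: dict = {}
    for r in repeats:
        hits = set(idx.query(r.chrom, r.midpoint, r.midpoint + 1))
        if len(hits) != 1:
            continue  # outside, or genes on both strands
        gene_strand = next(iter(hits))
        same = r.strand == gene_strand
        t = tallies.setdefault(r.name, [0, 0])
        t[0 if same else 1] += 1

    results = []
    for name in sorted(tallies):
        n_same, n_opp = tallies[name]
        n = n_same + n_opp
        ratio = n_same / n_opp if n_opp else np.nan
        if n >= 2:
            chi2, p = stats.chisquare([n_same, n_opp])
            chi2, p = float(chi2), float(p)
        else:
            chi2, p = np.nan, np.nan
        results.append(StrandBiasResult(name, region, n_same, n_opp, ratio, chi2, p))
    fdrs = bh_fdr([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def strand_bias_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
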