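"""Per-gene promoter feature tables: orientation-split repeat counts,
coverage, nearest distances, CpG and TFBS features.

Counting unit is the repeat record (fragment) — partial copies count — and a
repeat overlapping two promoters counts for both genes.  Orientation is the
repeat strand relative to the gene strand (``same``/``opposite``);
unstranded intervals (strand '.') contribute to both orientations' pooled
``any`` counts only through the dedicated CpG/TFBS columns, which are never
orientation-split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .promoter_model import IntervalIndex, distance_to_tss

__all__ = ["PromoterFeatureTable", "build_feature_table", "dosage_bin",
           "distance_bins", "merged_coverage"]


def merged_coverage(intervals, start, end) -> float:
    """Fraction of [start, end) covered by the union of the intervals."""
    clipped = sorted((max(s, start), min(e, end)) for s, e in intervals
                     if e > start and s < end)
    covered, cur_s, cur_e = 0, None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / (end - start)


class PromoterFeatureTable:
    """Genes-by-features table with typed column accessors.

    Column naming: ``count.<level>.<key>.<same|opposite|any>``,
    ``coverage.<level>.<key>``, ``dist.<level>.<key>``, plus
    ``cpg_island_count``, ``cpg_island_coverage``, ``cpg_dinucleotide_count``
    and ``tfbs_count.<tf>``.
    """

    def __init__(self, df: pd.DataFrame, level: str):
        self.df = df
        self.level = level

    @property
    def genes(self):
        return list(self.df.index)

    def counts(self, orientation: str = "any") -> pd.DataFrame:
        prefix = f"count.{self.level}."
        suffix = f".{orientation}"
        cols = [c for c in self.df.columns if c.startswith(prefix) and c.endswith(suffix)]
        out = self.df[cols].copy()
        out.columns = [c[len(prefix):-len(suffix)] for c in cols]
        return out

    def binarized(self, orientation: str = "any") -> pd.DataFrame:
        return (self.counts(orientation) > 0)

    def coverage(self) -> pd.DataFrame:
        prefix = f"coverage.{self.level}."
        cols = [c for c in self.df.columns if c.startswith(prefix)]
        out = self.df[cols].copy()
        out.columns = [c[len(prefix):] for c in cols]
        return out

    def nearest_distance(self, key: str) -> pd.Series:
        return self.df[f"dist.{self.level}.{key}"]

    def tfbs_counts(self) -> pd.DataFrame:
        cols = [c for c in self.df.columns if c.startswith("tfbs_count.")]
        out = self.df[cols].copy()
        out.columns = [c[len("tfbs_count."):] for c in cols]
        return out

    def write(self, path):
        from .io_formats import write_tsv
        write_tsv(self.df, path, index_label="gene_id")


def build_feature_table(promoters, repeats, level="name", cpg_intervals=None,
                        tfbs_intervals=None, genome=None,
                        orientation_filter_distance=None) -> PromoterFeatureTable:
    """Tabulate repeat (and optional CpG/TFBS) features per promoter window.

    Any >=1 bp overlap with the window counts one occurrence per repeat
    record.  Coverage is computed on merged intervals clipped to the window.
    ``dist.<level>.<key>`` is the minimum absolute TSS distance over that
    key's occurrences (orientation-pooled, unless
    ``orientation_filter_distance`` restricts it to 'same' or 'opposite'
    copies), NaN when absent.  If ``genome``
    (a {chrom: sequence} mapping or pyfaidx.Fasta) is given, 'CG'
    dinucleotides are counted on the window's plus-strand sequence
    (strand-symmetric by complementarity).
    """
    if not promoters:
        raise ValueError("no promoter windows")
    keys = sorted({r.level(level) for r in repeats})
    ridx = IntervalIndex.from_records(repeats)
    cidx = IntervalIndex.from_records(cpg_intervals) if cpg_intervals else None
    tidx = IntervalIndex.from_records(tfbs_intervals) if tfbs_intervals else None
    tf_names = sorted({iv.name for iv in tfbs_intervals}) if tfbs_intervals else []

    warned_chroms = set()
    rows = {}
    for w in promoters:
        if w.chrom not in ridx._trees and w.chrom not in warned_chroms:
            import warnings
            warnings.warn(f"chromosome {w.chrom} absent from repeat annotation; zero counts")
            warned_chroms.add(w.chrom)
        hits = ridx.query(w.chrom, w.start, w.end)
        row = {}
        per_key_hits = {}
        for r in hits:
            per_key_hits.setdefault(r.level(level), []).append(r)
        for key in keys:
            khits = per_key_hits.get(key, [])
            same = sum(1 for r in khits if r.strand == w.strand)
            opp = sum(1 for r in khits if r.strand in "+-" and r.strand != w.strand)
            row[f"count.{level}.{key}.same"] = same
            row[f"count.{level}.{key}.opposite"] = opp
            row[f"count.{level}.{key}.any"] = same + opp
            row[f"coverage.{level}.{key}"] = (
                merged_coverage([(r.start, r.end) for r in khits], w.start, w.end)
                if khits else 0.0)
            dhits = khits
            if orientation_filter_distance == "same":
                dhits = [r for r in khits if r.strand == w.strand]
            elif orientation_filter_distance == "opposite":
                dhits = [r for r in khits if r.strand in "+-" and r.strand != w.strand]
            dists = [abs(distance_to_tss(r, w)) for r in dhits]
            row[f"dist.{level}.{key}"] = min(dists) if dists else np.nan
        if cidx is not None:
            chits = cidx.query(w.chrom, w.start, w.end)
            row["cpg_island_count"] = len(chits)
            row["cpg_island_coverage"] = merged_coverage(
                [(iv.start, iv.end) for iv in chits], w.start, w.end)
        if tidx is not None:
            thits = tidx.query(w.chrom, w.start, w.end)
            for tf in tf_names:
                row[f"tfbs_count.{tf}"] = sum(1 for iv in thits if iv.name == tf)
        if genome is not None:
            seq = str(genome[w.chrom][w.start:w.end]).upper()
            row["cpg_dinucleotide_count"] = seq.count("CG")
        rows[w.gene_id] = row

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return PromoterFeatureTable(df, level)


def dosage_bin(count: int, cap: int = 5) -> str:
    """Collapse a copy count into {'0','1',...,'cap-1','>=cap'}."""
    if count < 0:
        raise ValueError("negative count")
    if count >= cap:
        return f">={cap}"
    return str(int(count))


def dosage_categories(cap: int = 5):
    return [str(i) for i in range(cap)] + [f">={cap}"]


def distance_bins(distance, edges):
    """Assign a distance (bp, nonnegative) to a right-open bin [e_i, e_{i+1}).

    Returns the bin label string '[e_i,e_{i+1})', or None when the distance
    is NaN or falls outside [edges[0], edges[-1]).
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if distance is None or (isinstance(distance, float) and np.isnan(distance)):
        return None
    for lo, hi in zip(edges, edges[1:]):
        if lo <= distance < hi:
            return f"[{lo},{hi})"
    return None


def distance_bin_labels(edges):
    edges = list(edges)
    return [f"[{lo},{hi})" for lo, hi in zip(edges, edges[1:])]
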