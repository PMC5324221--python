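"""TSS selection and strand-aware promoter windows.

One TSS is chosen per gene (the highest-expressed isoform's TSS when
transcript-level expression is available, the 5'-most TSS otherwise) and a
fixed window around it is cut in gene orientation: ``upstream_bp`` bases
before the TSS and ``downstream_bp`` after it.  The minus-strand arithmetic
mirrors the plus strand exactly, so the TSS base itself is included iff
``downstream_bp >= 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io_formats import GeneRecord

__all__ = ["PromoterWindow", "IntervalIndex", "select_tss", "make_promoters",
           "distance_to_tss"]


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    upstream_bp: int
    downstream_bp: int
    clipped: bool = False

    def __len__(self):
        return self.end - self.start


class IntervalIndex:
    """Per-chromosome interval lookup over half-open intervals with payloads.

    query(chrom, start, end) returns exactly the payloads an exhaustive scan
    would (any >=1 bp overlap).
    """

    def __init__(self, items=None):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        if items:
            for chrom, start, end, payload in items:
                self.add(chrom, start, end, payload)

    def add(self, chrom, start, end, payload):
        if start >= end:
            raise ValueError("empty interval")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)
        self._n += 1

    @classmethod
    def from_records(cls, records):
        """Index objects with .chrom/.start/.end attributes, payload = record."""
        idx = cls()
        for r in records:
            idx.add(r.chrom, r.start, r.end, r)
        return idx

    def query(self, chrom, start, end):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def __len__(self):
        return self._n


def select_tss(genes, tx_expression=None):
    """Pick one TSS per gene: highest mean-expressed transcript isoform.

    Parameters
    ----------
    genes : list of GeneRecord
    tx_expression : DataFrame or None
        Transcript-by-sample expression, rows indexed by transcript_id.
        When None (or a gene has no expressed transcript), the fallback is
        the outermost (5'-most in gene orientation) TSS.

    Returns
    -------
    (tss_map, provenance) : ({gene_id: tss}, {gene_id: transcript_id})
    Ties in mean expression break to the lexicographically smallest
    transcript_id.
    """
    means = None
    if tx_expression is not None:
        means = tx_expression.mean(axis=1)

    tss_map, provenance = {}, {}
    for gene in genes:
        chosen = None
        if means is not None:
            expressed = [(tx, float(means[tx.transcript_id]))
                         for tx in gene.transcripts if tx.transcript_id in means.index]
            expressed = [(tx, m) for tx, m in expressed if m > 0]
            if expressed:
                # max mean; ties -> smallest transcript_id
                chosen = min(expressed, key=lambda p: (-p[1], p[0].transcript_id))[0]
        if chosen is None:
            if gene.strand == "+":
                chosen = min(gene.transcripts, key=lambda t: (t.tss, t.transcript_id))
            else:
                chosen = min(gene.transcripts, key=lambda t: (-t.tss, t.transcript_id))
        tss_map[gene.gene_id] = chosen.tss
        provenance[gene.gene_id] = chosen.transcript_id
    return tss_map, provenance


def make_promoters(genes, tss_map, window_spec, contig_lengths):
    """Build strand-oriented promoter windows around each gene's TSS.

    window_spec = (upstream_bp, downstream_bp), both >= 0.
    Plus strand: [tss-upstream, tss+downstream); minus strand:
    [tss-downstream+1, tss+upstream+1).  Windows are clipped to
    [0, contig_length); windows that become empty are dropped with a warning.
    """
    upstream, downstream = window_spec
    if upstream < 0 or downstream < 0:
        raise ValueError("window_spec components must be >= 0")
    gene_by_id = {g.gene_id: g for g in genes} if genes and isinstance(genes[0], GeneRecord) else None
    windows = []
    for gene_id, tss in tss_map.items():
        if gene_by_id is not None:
            gene = gene_by_id[gene_id]
            chrom, strand = gene.chrom, gene.strand
        else:  # genes given as {gene_id: (chrom, strand)}
            chrom, strand = genes[gene_id]
        clen = contig_lengths[chrom]
        if not (0 <= tss < clen):
            raise ValueError(f"gene {gene_id}: tss {tss} outside contig {chrom} (length {clen})")
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        cstart, cend = max(0, start), min(clen, end)
        clipped = (cstart, cend) != (start, end)
        if cstart >= cend:
            warnings.warn(f"gene {gene_id}: empty promoter window dropped")
            continue
        windows.append(PromoterWindow(gene_id, chrom, strand, cstart, cend, tss,
                                      upstream, downstream, clipped))
    windows.sort(key=lambda w: (w.chrom, w.start, w.gene_id))
    return windows


def distance_to_tss(repeat, window: PromoterWindow) -> int:
    """Signed bp distance from a repeat to the window's TSS.

    Measured against gene orientation: upstream positive, downstream
    negative, 0 when the repeat covers the TSS.  The nearest base of the
    repeat is used.
    """
    tss = window.tss
    if repeat.start <= tss < repeat.end:
        return 0
    if repeat.end <= tss:          # repeat left of tss
        d = tss - (repeat.end - 1)
        genomic_upstream = True
    else:                          # repeat right of tss
        d = repeat.start - tss
        genomic_upstream = False
    if window.strand == "+":
        return d if genomic_upstream else -d
    return d if not genomic_upstream else -d


def promoters_to_bed(windows, path):
    from .io_formats import write_bed
    from .io_formats import Interval
    write_bed([Interval(w.chrom, w.start, w.end, name=w.gene_id, strand=w.strand)
               for w in windows], path)
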