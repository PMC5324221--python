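"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are normalized to a single internal convention at the
I/O boundary: 0-based, half-open ``[start, end)``.  GTF and RepeatMasker
``.out`` files are 1-based closed on disk; BED is already half-open.
Writers are bit-exact (tab-separated, ``.`` for missing, floats with six
significant digits) so that diffs of pipeline outputs are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptRecord",
    "GeneRecord",
    "RepeatRecord",
    "ExpressionMatrix",
    "Interval",
    "read_gtf",
    "read_repeatmasker",
    "read_expression",
    "read_bed",
    "read_fasta",
    "read_gmt",
    "read_meme",
    "write_meme",
    "write_bed",
    "write_tsv",
    "write_gtf",
    "write_repeatmasker",
]

MISSING = "."


def _fmt(value) -> str:
    """Format one field for TSV/BED output: '.' for missing, %.6g for floats."""
    if value is None:
        return MISSING
    if isinstance(value, float):
        if np.isnan(value):
            return MISSING
        if float(value).is_integer() and abs(value) < 1e15:
            return str(int(value))
        return f"{value:.6g}"
    return str(value)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open, with an optional name."""

    chrom: str
    start: int
    end: int
    name: str = MISSING
    strand: str = MISSING  # '+', '-', or '.' (unstranded)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript isoform: sorted non-overlapping exons and a derived TSS.

    The TSS is the genomic position of the first transcribed base: the start
    of the first exon on the plus strand, ``end - 1`` of the last exon on the
    minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end) half-open pairs, sorted

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple  # of TranscriptRecord
    biotype: str | None = None

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat copy (RepeatMasker fragment) with its name/family/class.

    ``element_id`` groups fragments of one insertion (the RepeatMasker ID
    column); ``ambiguous`` flags records whose class or family carries a
    trailing '?' in the annotation.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    family: str
    klass: str
    element_id: int | None = None
    divergence: float | None = None
    ambiguous: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty repeat interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def level(self, level: str) -> str:
        """The identifier of this record at hierarchy level name|family|klass."""
        if level == "name":
            return self.name
        if level == "family":
            return self.family
        if level == "klass":
            return self.klass
        raise ValueError(f"unknown repeat level {level!r}")


class ExpressionMatrix:
    """Gene-by-sample nonnegative expression (FPKM-like) plus a stage design.

    Parameters
    ----------
    values : DataFrame
        Genes in rows, samples in columns; nonnegative.
    design : mapping sample -> stage label
        Every sample column must be present.
    stage_order : ordered stage labels
        Defaults to order of first appearance in ``design``.
    """

    def __init__(self, values: pd.DataFrame, design: dict, stage_order=None):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in values.columns if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.values = values.astype(float)
        self.design = {s: design[s] for s in values.columns}
        if stage_order is None:
            stage_order = list(dict.fromkeys(self.design.values()))
        for stage in set(self.design.values()):
            if stage not in stage_order:
                raise ValueError(f"stage {stage!r} missing from stage_order")
        self.stage_order = list(stage_order)

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)

    def stage_samples(self, stage: str):
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return [s for s in self.samples if self.design[s] == stage]

    def stage_means(self) -> pd.DataFrame:
        """Arithmetic mean over the samples of each stage, genes x stages."""
        cols = {st: self.values[self.stage_samples(st)].mean(axis=1)
                for st in self.stage_order}
        return pd.DataFrame(cols)[self.stage_order]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.design, self.stage_order)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        sub = self.values[list(samples)]
        stages = [st for st in self.stage_order
                  if any(self.design[s] == st for s in samples)]
        return ExpressionMatrix(sub, self.design, stages)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list:
    """Read an Ensembl-dialect GTF into GeneRecords (0-based half-open).

    Only ``exon`` features are used; transcripts are assembled from their
    exon lines, exons sorted by start.  Output is ordered by
    (chrom, start, gene_id).
    """
    tx_exons: dict = {}
    tx_meta: dict = {}
    gene_biotype: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-numeric coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"malformed GTF line {lineno}: strand {strand!r}")
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id/transcript_id")
            key = (attr["gene_id"], attr["transcript_id"])
            tx_exons.setdefault(key, []).append((start1 - 1, end1))
            tx_meta[key] = (chrom, strand)
            if "gene_biotype" in attr:
                gene_biotype[attr["gene_id"]] = attr["gene_biotype"]

    by_gene: dict = {}
    for (gene_id, tx_id), exons in tx_exons.items():
        chrom, strand = tx_meta[(gene_id, tx_id)]
        exons = tuple(sorted(exons))
        tx = TranscriptRecord(tx_id, gene_id, chrom, strand, exons)
        by_gene.setdefault(gene_id, []).append(tx)

    genes = []
    for gene_id, txs in by_gene.items():
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: transcripts disagree on chrom/strand")
        txs = tuple(sorted(txs, key=lambda t: t.transcript_id))
        genes.append(GeneRecord(gene_id, txs[0].chrom, txs[0].strand, txs,
                                biotype=gene_biotype.get(gene_id)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for tx in g.transcripts:
                for (s, e) in tx.exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx.transcript_id}";'
                    if g.biotype:
                        attrs += f' gene_biotype "{g.biotype}";'
                    fh.write("\t".join([g.chrom, "teprom", "exon", str(s + 1), str(e),
                                        ".", g.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _split_class_family(cf: str):
    if "/" in cf:
        klass, family = cf.split("/", 1)
    else:
        klass = family = cf
    ambiguous = "?" in klass or "?" in family
    return klass, family, ambiguous


def read_repeatmasker(path) -> list:
    """Read a UCSC/RepeatMasker ``.out`` file (three header lines, then data).

    'C' strands become '-'; 1-based closed coordinates become 0-based
    half-open; the ``class/family`` field is split at the slash; records with
    '?' in class or family are retained with ``ambiguous=True``.
    """
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) < 11:
            raise ValueError(f"malformed RepeatMasker line {lineno}: {len(tok)} columns")
        try:
            begin1, end1 = int(tok[5]), int(tok[6])
            divergence = float(tok[1])
        except ValueError as exc:
            raise ValueError(f"malformed RepeatMasker line {lineno}: non-numeric field") from exc
        strand_sym = tok[8]
        if strand_sym == "+":
            strand = "+"
        elif strand_sym in ("C", "-"):
            strand = "-"
        else:
            raise ValueError(f"malformed RepeatMasker line {lineno}: unknown strand {strand_sym!r}")
        klass, family, ambiguous = _split_class_family(tok[10])
        element_id = int(tok[14]) if len(tok) > 14 and tok[14].isdigit() else None
        records.append(RepeatRecord(
            chrom=tok[4], start=begin1 - 1, end=end1, strand=strand,
            name=tok[9], family=family, klass=klass,
            element_id=element_id, divergence=divergence, ambiguous=ambiguous))
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return records


def write_repeatmasker(records, path) -> None:
    """Write RepeatRecords back to the ``.out`` dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        fh.write("   SW   perc perc perc  query     position in query           matching repeat\n")
        fh.write("score   div. del. ins.  sequence  begin end (left)   repeat  class/family  begin end (left)  ID\n")
        fh.write("\n")
        for i, r in enumerate(records):
            strand = "+" if r.strand == "+" else "C"
            cf = r.klass if r.klass == r.family else f"{r.klass}/{r.family}"
            div = 0.0 if r.divergence is None else r.divergence
            eid = r.element_id if r.element_id is not None else i + 1
            fh.write(f"  100 {div:6.1f}  0.0  0.0  {r.chrom} {r.start + 1} {r.end} (0) "
                     f"{strand} {r.name} {cf} 1 {r.end - r.start} (0) {eid}\n")


def join_fragments(records) -> list:
    """Merge fragments sharing (chrom, element_id) into one spanning record.

    Records without an element_id pass through unchanged.  The merged record
    spans min(start)..max(end) and keeps the first fragment's annotation.
    """
    out, groups = [], {}
    for r in records:
        if r.element_id is None:
            out.append(r)
        else:
            groups.setdefault((r.chrom, r.element_id), []).append(r)
    for frags in groups.values():
        first = min(frags, key=lambda r: r.start)
        out.append(RepeatRecord(
            chrom=first.chrom, start=min(r.start for r in frags),
            end=max(r.end for r in frags), strand=first.strand,
            name=first.name, family=first.family, klass=first.klass,
            element_id=first.element_id, divergence=first.divergence,
            ambiguous=first.ambiguous))
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path_matrix, path_design) -> ExpressionMatrix:
    """Read a gene-by-sample TSV plus a sample->stage design TSV.

    The design file has two columns (sample, stage; header optional); stage
    order is the order of first appearance in the design file.
    """
    values = pd.read_csv(path_matrix, sep="\t", index_col=0)
    design, stage_order = {}, []
    with open(path_design) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed design line {lineno}")
            sample, stage = parts[0], parts[1]
            if lineno == 1 and sample.lower() in ("sample", "sample_id"):
                continue
            design[sample] = stage
            if stage not in stage_order:
                stage_order.append(stage)
    return ExpressionMatrix(values, design, stage_order)


def write_expression(expr: ExpressionMatrix, path_matrix, path_design) -> None:
    write_tsv(expr.values, path_matrix, index_label="gene_id")
    with open(path_design, "w") as fh:
        fh.write("sample\tstage\n")
        for s in expr.samples:
            fh.write(f"{s}\t{expr.design[s]}\n")


# ---------------------------------------------------------------------------
# BED / FASTA / GMT / MEME
# ---------------------------------------------------------------------------

def read_bed(path) -> list:
    """Read BED3/BED6 into Intervals; missing name/strand become '.'."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split("\t")
            if len(tok) < 3:
                raise ValueError(f"malformed BED line {lineno}")
            try:
                start, end = int(tok[1]), int(tok[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-numeric coordinates") from exc
            name = tok[3] if len(tok) > 3 else MISSING
            strand = tok[5] if len(tok) > 5 else MISSING
            if strand not in ("+", "-", MISSING):
                raise ValueError(f"malformed BED line {lineno}: strand {strand!r}")
            out.append(Interval(tok[0], start, end, name=name, strand=strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    return out


def write_bed(intervals, path) -> None:
    """Write Interval-like or RepeatRecord objects as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "name", MISSING)
            strand = getattr(iv, "strand", MISSING)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_fasta(path) -> dict:
    """Read FASTA into an ordered {id: uppercase sequence} dict."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gmt(path) -> dict:
    """Read GMT gene sets: {set name: (description, tuple of gene ids)}."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            tok = line.split("\t")
            if len(tok) < 3:
                raise ValueError(f"malformed GMT line {lineno}")
            sets[tok[0]] = (tok[1], tuple(tok[2:]))
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_meme(path) -> list:
    """Parse MEME minimal motif format into Pwm objects.

    Note: probabilities are read verbatim from the letter-probability matrix
    (no reconstruction through integer site counts, which loses precision).
    """
    from .motif_scan import Pwm

    background = np.full(4, 0.25)
    pwms, motif_id, alt_names, rows = [], None, (), []
    expect_bg = False

    def flush():
        nonlocal motif_id, rows, alt_names
        if motif_id is not None:
            if not rows:
                raise ValueError(f"motif {motif_id}: empty probability matrix")
            pwms.append(Pwm(motif_id=motif_id, tf_names=tuple(alt_names),
                            matrix=np.array(rows, dtype=float),
                            background=background.copy()))
        motif_id, rows, alt_names = None, [], ()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expect_bg and line and line[0] in "ACGT":
                tok = line.split()
                freqs = {tok[i]: float(tok[i + 1]) for i in range(0, len(tok), 2)}
                background = np.array([freqs.get(b, 0.25) for b in "ACGT"])
                expect_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                flush()
                tok = line.split()
                motif_id = tok[1]
                alt_names = tuple(tok[2:])
            elif line.startswith("letter-probability matrix"):
                continue
            elif motif_id is not None and line and (line[0].isdigit() or line[0] == "0" or line[0] == "."):
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {motif_id}: matrix row with {len(vals)} columns")
                rows.append(vals)
    flush()
    return pwms


def write_meme(pwms, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6g}" for b, f in zip("ACGT", bg)) + "\n\n")
        for p in pwms:
            names = (" " + " ".join(p.tf_names)) if p.tf_names else ""
            fh.write(f"MOTIF {p.motif_id}{names}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p.matrix)} nsites= 20 E= 0\n")
            for row in p.matrix:
                # full precision: probability rows must still sum to 1 on re-read
                fh.write(" " + " ".join(f"{x:.17g}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# generic TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a DataFrame as TSV: '.' for missing, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", na_rep=MISSING, float_format="%.6g",
              index_label=index_label)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING])
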