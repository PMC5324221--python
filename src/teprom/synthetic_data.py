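"""Synthetic genome/annotation/expression bundles with known ground truth.

The generator emulates the statistical structure of pre-implantation
expression data: genes with stage archetypes (maternal decay, transient
2-cell induction, late activation, flat), repeat families placed as Poisson
processes with configurable strand rules, and planted per-copy,
orientation-gated, distance-decaying effects on the fold-change between a
target stage pair.  Effects are additive in log2 fold-change (multiplicative
in expression ratio): a copy at nearest-TSS distance d inside the effect
window contributes beta * exp(-d / decay_scale) when its orientation is
admissible.  Everything is driven by one integer seed; regenerating with the
same config reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (ExpressionMatrix, GeneRecord, RepeatRecord,
                         TranscriptRecord, write_bed, write_expression,
                         write_fasta, write_gtf, write_meme,
                         write_repeatmasker)
from .motif_scan import pwm_from_consensus
from .promoter_model import IntervalIndex, distance_to_tss, make_promoters

__all__ = ["RepeatFamilyConfig", "MotifPlant", "SimConfig", "SimBundle",
           "SimTruth", "default_config", "generate_bundle", "generate"]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class RepeatFamilyConfig:
    name: str
    family: str
    klass: str
    copy_rate: float                    # expected copies per bp
    length_mean: float = 200.0
    length_sd: float = 40.0
    strand_rule: str = "uniform"        # 'uniform' | 'gene_same_biased'
    strand_bias_rho: float = 0.8        # P(same strand as nearest gene)
    beta: float = 0.0                   # log2-FC per admissible copy
    orientation: str = "both"           # 'both' | 'same_only'
    decay_scale: float | None = None    # bp; None = no distance decay
    avoid_tss_bp: int = 0               # keep copies at least this far from any TSS


@dataclass
class MotifPlant:
    motif_id: str
    consensus: str
    host_name: str                      # repeat family name whose consensus carries it
    copies: int = 3
    tf_name: str = ""


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    gene_length: int = 1000
    min_spacing: int = 4000
    stages: tuple = ("oocyte", "zygote", "early2C", "mid2C", "late2C", "blastocyst")
    samples_per_stage: int = 4
    families: tuple = ()
    effect_window: tuple = (2000, 0)    # (upstream, downstream) around the TSS
    effect_stage: str = "late2C"        # effects multiply this stage and later
    baseline_log_mu: float = float(np.log(30.0))
    baseline_log_sigma: float = 1.0
    noise_sd: float = 0.8               # per-sample noise SD, log2 units
    archetypes: dict = field(default_factory=lambda: {
        "maternal_decay": (4.0, 3.0, 1.5, 0.6, 0.25, 0.05),
        "transient_2C": (0.1, 0.2, 2.0, 4.0, 1.0, 0.1),
        "late_activation": (0.05, 0.05, 0.1, 0.3, 2.0, 4.0),
        "flat": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    })
    archetype_fractions: dict = field(default_factory=lambda: {
        "maternal_decay": 0.35, "transient_2C": 0.15,
        "late_activation": 0.25, "flat": 0.25,
    })
    background_names: int = 0           # extra low-copy repeat names (lognormal counts)
    background_lognorm: tuple = (2.0, 1.0)
    blastocyst_lineages: int = 0        # planted sample subtypes in the last stage
    lineage_marker_frac: float = 0.05
    lineage_boost: float = 8.0
    motif_plants: tuple = ()
    emit_sequence: bool = False


@dataclass
class SimTruth:
    """Planted ground truth: per-family effect parameters and the per-gene
    exposures actually generated (counts and decay-weighted sums, split by
    orientation, within the effect window)."""

    seed: int
    families: dict                      # name -> dict of planted parameters
    per_gene: pd.DataFrame              # archetype, counts, exposures, total effect
    consensus: dict = field(default_factory=dict)  # family name -> consensus sequence

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "families": self.families,
            "consensus": self.consensus,
            "per_gene": self.per_gene.reset_index()
                            .rename(columns={"index": "gene_id"})
                            .to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimBundle:
    config: SimConfig
    genes: list
    repeats: list
    expr: ExpressionMatrix
    truth: SimTruth
    pwms: list
    contig_lengths: dict
    genome: dict | None = None
    sample_lineage: dict = field(default_factory=dict)


def default_config(seed: int = 0) -> SimConfig:
    """The stock simulation: one 10 Mb chromosome, 2000 genes, 6 stages x 4
    samples, and three repeat families playing the canonical roles —

    * ``B1sim`` (SINE/Alu-like): abundant, orientation-indifferent weak
      per-copy effect (+0.3 log2 units) with a slow distance decay;
    * ``MT2sim`` (LTR/ERVL-like): sparse, same-strand-only strong effect
      (+1.2) with sharp decay, copies biased to the nearest gene's strand;
    * ``L1sim`` (LINE-like): no effect, depleted near TSSs.
    """
    families = (
        RepeatFamilyConfig("B1sim", "Alu", "SINE", copy_rate=1.0e-3,
                           length_mean=150, length_sd=30, beta=0.3,
                           orientation="both", decay_scale=50_000.0),
        RepeatFamilyConfig("MT2sim", "ERVL", "LTR", copy_rate=1.0e-4,
                           length_mean=400, length_sd=80,
                           strand_rule="gene_same_biased", strand_bias_rho=0.8,
                           beta=1.2, orientation="same_only",
                           decay_scale=1000.0),
        RepeatFamilyConfig("L1sim", "L1", "LINE", copy_rate=3.0e-4,
                           length_mean=800, length_sd=200, beta=0.0,
                           avoid_tss_bp=1200),
    )
    plants = (MotifPlant("OBOXsim", "TAATCC", host_name="MT2sim", copies=3,
                         tf_name="Obox3sim"),)
    return SimConfig(seed=seed, families=families, motif_plants=plants)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_genes(cfg: SimConfig, rng) -> tuple:
    margin = max(cfg.min_spacing, 10_000)
    genes = []
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[0] += cfg.n_genes - sum(per_chrom)
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        span = cfg.chrom_length - 2 * margin - n * cfg.min_spacing
        if span <= 0:
            raise ValueError("infeasible spacing: n_genes * min_spacing exceeds genome")
        offsets = np.sort(rng.uniform(0, span, size=n))
        tss = (margin + offsets + np.arange(n) * cfg.min_spacing).astype(int)
        strands = rng.choice(["+", "-"], size=n)
        for pos, strand in zip(tss, strands):
            gid += 1
            gene_id = f"g{gid:05d}"
            if strand == "+":
                exon = (int(pos), int(pos) + cfg.gene_length)
            else:
                exon = (int(pos) - cfg.gene_length + 1, int(pos) + 1)
            tx = TranscriptRecord(f"{gene_id}.t1", gene_id, chrom, strand, (exon,))
            genes.append(GeneRecord(gene_id, chrom, strand, (tx,)))
    return genes


def _nearest_gene(tss_sorted: np.ndarray, starts: np.ndarray):
    """Index of the nearest TSS for each start, plus the distance to it."""
    i = np.searchsorted(tss_sorted, starts)
    left = np.clip(i - 1, 0, len(tss_sorted) - 1)
    right = np.clip(i, 0, len(tss_sorted) - 1)
    d_left = np.abs(starts - tss_sorted[left])
    d_right = np.abs(starts - tss_sorted[right])
    nearest = np.where(d_left <= d_right, left, right)
    return nearest, np.minimum(d_left, d_right)


def _place_family(fam: RepeatFamilyConfig, chrom: str, length: int,
                  tss_sorted: np.ndarray, strands_sorted: np.ndarray, rng,
                  eid_start: int) -> list:
    n = int(rng.poisson(fam.copy_rate * length))
    if n == 0:
        return []
    lengths = np.maximum(30, np.round(rng.normal(fam.length_mean, fam.length_sd,
                                                 size=n))).astype(int)
    starts = np.floor(rng.random(n) * np.maximum(1, length - lengths)).astype(int)
    if fam.avoid_tss_bp and len(tss_sorted):
        for _ in range(200):  # rejection rounds for the TSS-avoidance rule
            _, near = _nearest_gene(tss_sorted, starts)
            bad = near < fam.avoid_tss_bp
            if not bad.any():
                break
            starts[bad] = np.floor(rng.random(int(bad.sum()))
                                   * np.maximum(1, length - lengths[bad])).astype(int)
    if fam.strand_rule == "gene_same_biased" and len(tss_sorted):
        nearest, _ = _nearest_gene(tss_sorted, starts)
        gene_plus = strands_sorted[nearest] == "+"
        same = rng.random(n) < fam.strand_bias_rho
        plus = gene_plus == same
    else:
        plus = rng.random(n) < 0.5
    divergences = np.round(rng.uniform(5, 25, size=n), 1)
    return [RepeatRecord(chrom=chrom, start=int(s), end=int(s + ln),
                         strand="+" if p else "-", name=fam.name,
                         family=fam.family, klass=fam.klass,
                         element_id=eid_start + i + 1, divergence=float(dv))
            for i, (s, ln, p, dv) in enumerate(zip(starts, lengths, plus, divergences))]


def _family_consensus(fam: RepeatFamilyConfig, plants, rng) -> str:
    """Random consensus of the family's mean length with planted motif copies."""
    L = max(int(fam.length_mean), 30)
    seq = "".join(rng.choice(list("ACGT"), size=L))
    for plant in plants:
        if plant.host_name != fam.name:
            continue
        motif = plant.consensus.upper()
        gap = max(1, (L - len(motif)) // max(plant.copies, 1))
        for c in range(plant.copies):
            pos = min(c * gap + 5, L - len(motif))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
    return seq


def generate_bundle(config: SimConfig) -> SimBundle:
    """Generate the full in-memory bundle (annotation, repeats, expression,
    motifs, truth, optional genome sequence)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    contig_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}

    genes = _place_genes(cfg, rng)
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {c: np.array([g.transcripts[0].tss for g in gs])
                  for c, gs in by_chrom.items()}
    strand_arrays = {c: np.array([g.strand for g in gs]) for c, gs in by_chrom.items()}

    repeats = []
    eid = 0
    for fam in cfg.families:
        for chrom, length in contig_lengths.items():
            recs = _place_family(fam, chrom, length, tss_arrays.get(chrom, np.empty(0)),
                                 strand_arrays.get(chrom, np.empty(0)), rng, eid)
            eid += len(recs)
            repeats.extend(recs)
    for j in range(cfg.background_names):
        mu, sigma = cfg.background_lognorm
        count = max(1, int(round(rng.lognormal(mu, sigma))))
        for _ in range(count):
            chrom = f"chr{1 + int(rng.integers(cfg.n_chromosomes))}"
            clen = int(rng.integers(50, 300))
            start = int(rng.integers(0, cfg.chrom_length - clen))
            eid += 1
            repeats.append(RepeatRecord(
                chrom=chrom, start=start, end=start + clen,
                strand="+" if rng.random() < 0.5 else "-",
                name=f"BGrep{j:04d}", family="BGfam", klass="DNA",
                element_id=eid, divergence=float(np.round(rng.uniform(5, 25), 1))))
    repeats.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))

    # --- planted exposures within the effect window -----------------------
    tss_map = {g.gene_id: g.transcripts[0].tss for g in genes}
    windows = make_promoters(genes, tss_map, cfg.effect_window, contig_lengths)
    fam_by_name = {f.name: f for f in cfg.families}
    effect_repeats = [r for r in repeats if r.name in fam_by_name]
    ridx = IntervalIndex.from_records(effect_repeats)

    gene_ids = [g.gene_id for g in genes]
    per_gene: dict = {gid: {} for gid in gene_ids}
    effects = pd.Series(0.0, index=gene_ids)
    for w in windows:
        rows = per_gene[w.gene_id]
        for fam in cfg.families:
            rows.setdefault(f"{fam.name}.count_same", 0)
            rows.setdefault(f"{fam.name}.count_opposite", 0)
            rows.setdefault(f"{fam.name}.exposure_same", 0.0)
            rows.setdefault(f"{fam.name}.exposure_opposite", 0.0)
        for r in ridx.query(w.chrom, w.start, w.end):
            fam = fam_by_name[r.name]
            d = abs(distance_to_tss(r, w))
            w_d = float(np.exp(-d / fam.decay_scale)) if fam.decay_scale else 1.0
            orient = "same" if r.strand == w.strand else "opposite"
            rows[f"{fam.name}.count_{orient}"] += 1
            rows[f"{fam.name}.exposure_{orient}"] += w_d
            admissible = fam.orientation == "both" or orient == "same"
            if admissible and fam.beta:
                effects[w.gene_id] += fam.beta * w_d
    truth_df = pd.DataFrame.from_dict(per_gene, orient="index").fillna(0.0)
    truth_df = truth_df.reindex(sorted(truth_df.columns), axis=1)

    # --- expression -------------------------------------------------------
    arch_names = list(cfg.archetypes)
    fracs = np.array([cfg.archetype_fractions[a] for a in arch_names], dtype=float)
    fracs = fracs / fracs.sum()
    archetype = rng.choice(arch_names, size=len(gene_ids), p=fracs)
    baseline = rng.lognormal(cfg.baseline_log_mu, cfg.baseline_log_sigma,
                             size=len(gene_ids))
    effect_idx = list(cfg.stages).index(cfg.effect_stage)
    profiles = np.array([cfg.archetypes[a] for a in archetype],
                        dtype=float).reshape(len(gene_ids), len(cfg.stages))

    samples, design = [], {}
    for stage in cfg.stages:
        for i in range(cfg.samples_per_stage):
            s = f"{stage}_r{i + 1}"
            samples.append(s)
            design[s] = stage
    mat = np.empty((len(gene_ids), len(samples)))
    eff = effects.to_numpy()
    for si, s in enumerate(samples):
        sti = list(cfg.stages).index(design[s])
        mean = baseline * profiles[:, sti]
        if sti >= effect_idx:
            mean = mean * np.exp2(eff)
        noise = np.exp2(rng.normal(0.0, cfg.noise_sd, size=len(gene_ids)))
        mat[:, si] = mean * noise

    sample_lineage = {}
    if cfg.blastocyst_lineages > 0:
        last = cfg.stages[-1]
        blasto = [s for s in samples if design[s] == last]
        n_mark = max(1, int(cfg.lineage_marker_frac * len(gene_ids)))
        marker_sets = [rng.choice(len(gene_ids), size=n_mark, replace=False)
                       for _ in range(cfg.blastocyst_lineages)]
        for i, s in enumerate(blasto):
            lin = i % cfg.blastocyst_lineages
            sample_lineage[s] = lin + 1
            col = samples.index(s)
            mat[marker_sets[lin], col] *= cfg.lineage_boost

    expr = ExpressionMatrix(pd.DataFrame(mat, index=gene_ids, columns=samples),
                            design, list(cfg.stages))

    # --- motifs / sequence ------------------------------------------------
    consensus = {fam.name: _family_consensus(fam, cfg.motif_plants, rng)
                 for fam in cfg.families}
    pwms = [pwm_from_consensus(p.consensus, p.motif_id,
                               tf_names=(p.tf_name,) if p.tf_name else ())
            for p in cfg.motif_plants]

    genome = None
    if cfg.emit_sequence:
        genome = {}
        for chrom, length in contig_lengths.items():
            arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
            genome[chrom] = arr
        for r in repeats:
            cons = consensus.get(r.name)
            if cons is None:
                continue
            rlen = r.end - r.start
            piece = (cons * (rlen // len(cons) + 1))[:rlen]
            if r.strand == "-":
                piece = piece.translate(_COMP)[::-1]
            genome[r.chrom][r.start:r.end] = np.frombuffer(piece.encode(), dtype="S1")
        genome = {c: arr.tobytes().decode() for c, arr in genome.items()}

    truth_df["archetype"] = archetype
    truth_df["effect"] = eff
    fam_truth = {f.name: dict(beta=f.beta, orientation=f.orientation,
                              decay_scale=f.decay_scale, strand_rule=f.strand_rule,
                              strand_bias_rho=f.strand_bias_rho,
                              copy_rate=f.copy_rate, family=f.family, klass=f.klass)
                 for f in cfg.families}
    truth = SimTruth(seed=cfg.seed, families=fam_truth, per_gene=truth_df,
                     consensus=consensus)
    return SimBundle(cfg, genes, repeats, expr, truth, pwms, contig_lengths,
                     genome, sample_lineage)


def truth_design(bundle: SimBundle) -> tuple:
    """The correctly specified recovery design for the planted model.

    Returns (X, true_betas): X has one column per family x orientation with
    the generator's decay-weighted exposures; true_betas maps each column to
    the coefficient the planted model implies (beta for admissible
    orientations, 0 otherwise).
    """
    cols = [c for c in bundle.truth.per_gene.columns if ".exposure_" in c]
    X = bundle.truth.per_gene[cols].astype(float)
    true_betas = {}
    for col in cols:
        fam_name, kind = col.split(".exposure_")
        fam = bundle.truth.families[fam_name]
        admissible = fam["orientation"] == "both" or kind == "same"
        true_betas[col] = fam["beta"] if admissible else 0.0
    return X, true_betas


def generate(config: SimConfig, outdir) -> dict:
    """Generate and write the file bundle; returns {kind: path}.

    Files: genes.gtf, repeats.out, repeats.bed, expression.tsv, design.tsv,
    motifs.meme, truth.json, and genome.fasta when sequence emission is on.
    Same config (and seed) twice gives byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    paths = {
        "genes": outdir / "genes.gtf",
        "repeats_out": outdir / "repeats.out",
        "repeats_bed": outdir / "repeats.bed",
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "motifs": outdir / "motifs.meme",
        "truth": outdir / "truth.json",
    }
    write_gtf(bundle.genes, paths["genes"])
    write_repeatmasker(bundle.repeats, paths["repeats_out"])
    write_bed(bundle.repeats, paths["repeats_bed"])
    write_expression(bundle.expr, paths["expression"], paths["design"])
    write_meme(bundle.pwms, paths["motifs"])
    paths["truth"].write_text(bundle.truth.to_json())
    if bundle.genome is not None:
        paths["genome"] = outdir / "genome.fasta"
        write_fasta(bundle.genome, paths["genome"])
    with open(outdir / "contigs.tsv", "w") as fh:
        for chrom, ln in bundle.contig_lengths.items():
            fh.write(f"{chrom}\t{ln}\n")
    paths["contigs"] = outdir / "contigs.tsv"
    return {k: str(v) for k, v in paths.items()}
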