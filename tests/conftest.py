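import numpy as np
import pandas as pd
import pytest

from teprom import synthetic_data as sim
from teprom.io_formats import ExpressionMatrix

TINY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t501\t600\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr1\ttest\texon\t1301\t1400\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";
chr1\ttest\texon\t1101\t1200\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";
chr1\ttest\texon\t1151\t1250\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t2";
"""

RM_HEADER = (
    "   SW   perc perc perc  query     position in query           matching repeat\n"
    "score   div. del. ins.  sequence  begin end (left)   repeat  class/family  begin end (left)  ID\n"
    "\n"
)

TINY_RM = RM_HEADER + """\
  463 10.5  0.0  0.0  chr1 1001 1100 (0) C B1_Mus2 SINE/Alu 1 100 (0) 1
  312 12.0  0.0  0.0  chr1 2001 2150 (0) + MT2_Mm LTR/ERVL 1 150 (0) 2
  199  8.0  0.0  0.0  chr1 3001 3050 (0) + Ambig1 Unknown? 1 50 (0) 3
  255  9.9  0.0  0.0  chr2 501 700 (0) C L1Md_A LINE/L1 1 200 (0) 4
"""


@pytest.fixture()
def tiny_gtf(tmp_path):
    p = tmp_path / "tiny.gtf"
    p.write_text(TINY_GTF)
    return p


@pytest.fixture()
def tiny_rm(tmp_path):
    p = tmp_path / "tiny.out"
    p.write_text(TINY_RM)
    return p


@pytest.fixture()
def small_expr():
    """3 genes x 4 samples over 2 stages, values chosen for hand arithmetic."""
    values = pd.DataFrame(
        [[1.0, 3.0, 6.0, 8.0],
         [10.0, 10.0, 2.0, 2.0],
         [0.0, 0.0, 4.0, 4.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"])
    design = {"s1": "early", "s2": "early", "s3": "late", "s4": "late"}
    return ExpressionMatrix(values, design, ["early", "late"])


def small_sim_config(seed=0, **overrides):
    """A scaled-down default simulation for fast end-to-end tests."""
    cfg = sim.default_config(seed=seed)
    cfg.n_genes = 400
    cfg.chrom_length = 2_000_000
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size default-config bundle shared across tests."""
    return sim.generate_bundle(sim.default_config(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    return sim.generate_bundle(small_sim_config(seed=11))


def brute_force_overlaps(intervals, qstart, qend):
    """Exhaustive overlap scan oracle: any shared base, half-open."""
    return [payload for (s, e, payload) in intervals if s < qend and e > qstart]
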