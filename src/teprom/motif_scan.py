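"""PWM log-odds scanning of promoter and repeat-consensus sequences, plus
the group-wise ANOVA of maximal scores across fold-change-ranked gene groups.

A PWM of length L is scored against every L-window of the sequence on both
strands; the per-gene statistic is the maximal log-odds (bits), which avoids
an arbitrary site cutoff.  Site counting at "similarity" tau counts windows
scoring at least tau times the maximal achievable log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_fdr

__all__ = ["Pwm", "MotifScanResult", "log_odds", "scan_sequence",
           "count_consensus_sites", "group_motif_anova", "prioritize_tfs",
           "pwm_from_consensus"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix (L x ACGT) with background and pseudocount.

    The stored matrix holds raw probabilities; pseudocount regularization is
    applied in the log-odds transform:
    score(i, b) = log2((p(i,b) + pc * bg_b) / ((1 + pc) * bg_b)).
    """

    motif_id: str
    matrix: np.ndarray
    tf_names: tuple = ()
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: matrix must be L x 4 with L >= 1")
        norm = (m + self.pseudocount * self.background) / (1 + self.pseudocount)
        if not np.allclose(norm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: rows do not sum to 1 after "
                             "pseudocount normalization")
        object.__setattr__(self, "matrix", m)

    def __len__(self):
        return self.matrix.shape[0]


@dataclass
class MotifScanResult:
    gene_id: str | None
    motif_id: str
    max_score: float            # bits; NaN when no scorable window
    best_position: int | None
    best_strand: str | None
    scores_fwd: np.ndarray = None
    scores_rev: np.ndarray = None

    def n_sites(self, tau: float) -> int:
        """Windows (both strands, overlaps allowed) scoring >= tau * the
        maximal achievable score of the PWM."""
        threshold = tau * self._max_achievable
        n = 0
        for arr in (self.scores_fwd, self.scores_rev):
            if arr is not None and len(arr):
                n += int(np.sum(arr[~np.isnan(arr)] >= threshold - 1e-12))
        return n


def log_odds(pwm: Pwm) -> np.ndarray:
    """Log-odds score matrix in bits (L x 4)."""
    bg = pwm.background
    with np.errstate(divide="ignore"):  # -inf for p=0 cells at pseudocount 0
        return np.log2((pwm.matrix + pwm.pseudocount * bg) / ((1 + pwm.pseudocount) * bg))


def max_achievable_score(pwm: Pwm) -> float:
    return float(log_odds(pwm).max(axis=1).sum())


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, -1) for c in seq.upper()), dtype=np.int64,
                       count=len(seq))


def _window_scores(codes: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N (code -1) are NaN."""
    L = S.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    out = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    safe = codes.copy()
    nmask = codes < 0
    safe[nmask] = 0
    for j in range(L):
        out += S[j, safe[j:j + n_win]]
        bad |= nmask[j:j + n_win]
    out[bad] = np.nan
    return out


def scan_sequence(seq: str, pwm: Pwm, both_strands: bool = True,
                  gene_id: str | None = None) -> MotifScanResult:
    """Maximal log-odds of a PWM over all windows of a sequence.

    The reverse strand is scored by scanning the reverse complement; the
    reported best position is always in the input sequence's coordinates
    (start of the window).  Sequences shorter than the motif, or with every
    window obscured by N, yield a missing (NaN) result.
    """
    codes = _encode(seq)
    S = log_odds(pwm)
    fwd = _window_scores(codes, S)
    rev = np.empty(0)
    if both_strands:
        rc = np.array([_COMP[c] if c >= 0 else -1 for c in codes[::-1]], dtype=np.int64)
        rev = _window_scores(rc, S)

    best_score, best_pos, best_strand = np.nan, None, None
    if len(fwd) and not np.all(np.isnan(fwd)):
        i = int(np.nanargmax(fwd))
        best_score, best_pos, best_strand = float(fwd[i]), i, "+"
    if len(rev) and not np.all(np.isnan(rev)):
        i = int(np.nanargmax(rev))
        if np.isnan(best_score) or rev[i] > best_score:
            # window i on the RC starts at len(seq) - L - i on the input
            best_score = float(rev[i])
            best_pos = len(seq) - len(pwm) - i
            best_strand = "-"
    res = MotifScanResult(gene_id, pwm.motif_id, best_score, best_pos,
                          best_strand, fwd, rev)
    res._max_achievable = max_achievable_score(pwm)
    return res


def count_consensus_sites(seq: str, pwm: Pwm, tau: float = 0.9,
                          both_strands: bool = True,
                          similarity: str = "score") -> int:
    """Number of windows of a (consensus) sequence at similarity >= tau;
    overlapping windows all count.

    similarity='score' (default): window log-odds >= tau * the maximal
    achievable log-odds.  similarity='identity': fraction of window
    positions matching the PWM's consensus letter >= tau.
    """
    if similarity == "score":
        res = scan_sequence(seq, pwm, both_strands=both_strands)
        if np.isnan(res.max_score) and not len(res.scores_fwd):
            return 0
        return res.n_sites(tau)
    if similarity != "identity":
        raise ValueError(f"unknown similarity mode {similarity!r}")
    consensus = pwm.matrix.argmax(axis=1)
    codes = _encode(seq)
    L = len(pwm)
    n = 0
    strands = [codes]
    if both_strands:
        strands.append(np.array([_COMP[c] if c >= 0 else -1
                                 for c in codes[::-1]], dtype=np.int64))
    for arr in strands:
        for i in range(len(arr) - L + 1):
            win = arr[i:i + L]
            if (win < 0).any():
                continue
            if (win == consensus).mean() >= tau - 1e-12:
                n += 1
    return n


def scan_promoters(sequences: dict, pwms) -> pd.DataFrame:
    """Max score of every PWM over every gene's (proximal) promoter sequence.

    ``sequences``: {gene_id: str}.  Returns genes x motifs DataFrame of max
    scores (NaN = unscorable).
    """
    data = {}
    for pwm in pwms:
        data[pwm.motif_id] = {g: scan_sequence(s, pwm).max_score
                              for g, s in sequences.items()}
    return pd.DataFrame(data).sort_index()


def group_motif_anova(scores: pd.DataFrame, groups,
                      rank_transform: bool = False) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of per-gene max scores across gene groups.

    ``groups`` is a GeneClusters (typically rank bins).  Per motif: F, p,
    BH FDR over motifs, per-group mean scores, and a monotone-trend statistic
    (Spearman rho of group order vs group means).  Motifs are ranked by FDR,
    then by |trend| descending.  ``rank_transform`` replaces scores by their
    global ranks first (a Kruskal-Wallis-flavoured robustification).
    """
    if rank_transform:
        scores = scores.rank(axis=0)
    labels = groups.labels
    order = groups.label_order()
    if len(order) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for motif in scores.columns:
        samples = []
        means = {}
        for lab in order:
            vals = scores.loc[[g for g in groups.members(lab) if g in scores.index], motif]
            vals = vals.dropna().to_numpy()
            samples.append(vals)
            means[f"mean.G{lab}"] = float(vals.mean()) if len(vals) else np.nan
        if any(len(s) < 2 for s in samples):
            rows.append(dict(motif=motif, F=np.nan, p=np.nan, trend=np.nan, **means))
            continue
        pooled = np.concatenate(samples)
        if pooled.std() == 0:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*samples)
            if np.isnan(F):
                F, p = 0.0, 1.0
        mean_vec = [means[f"mean.G{lab}"] for lab in order]
        if np.std(mean_vec) == 0:
            trend = 0.0
        else:
            trend = float(stats.spearmanr(np.arange(len(order)), mean_vec).statistic)
        rows.append(dict(motif=motif, F=float(F), p=float(p), trend=trend, **means))
    out = pd.DataFrame(rows)
    if not len(out):
        return pd.DataFrame(columns=["motif", "F", "p", "trend", "fdr"])
    out["fdr"] = bh_fdr(out["p"])
    out = out.sort_values(["fdr", "p"], kind="mergesort")
    out = out.iloc[np.lexsort((-out["trend"].abs().fillna(0), out["fdr"].fillna(1)))]
    return out.reset_index(drop=True)


def prioritize_tfs(anova: pd.DataFrame, pwms, tf_fc: pd.Series) -> pd.DataFrame:
    """Join motif ANOVA results to the fold-changes of the motifs' own TF
    genes and flag concordance.

    A TF is concordant when the sign of its own fold-change over the stage
    pair matches the sign of the motif's group trend.  Output is sorted by
    (concordant flag desc, FDR asc); TFs absent from the expression table
    are retained with a missing flag.
    """
    by_id = {p.motif_id: p for p in pwms}
    rows = []
    for _, rec in anova.iterrows():
        pwm = by_id.get(rec["motif"])
        tf_names = pwm.tf_names if pwm is not None else ()
        if not tf_names:
            tf_names = (rec["motif"],)
        for tf in tf_names:
            fc_val = float(tf_fc[tf]) if tf in tf_fc.index else np.nan
            concordant = (np.nan if np.isnan(fc_val) or np.isnan(rec["trend"])
                          else float(np.sign(fc_val) == np.sign(rec["trend"])
                                     and rec["trend"] != 0))
            rows.append(dict(motif=rec["motif"], tf=tf, fdr=rec["fdr"],
                             trend=rec["trend"], tf_fc=fc_val,
                             concordant=concordant))
    out = pd.DataFrame(rows, columns=["motif", "tf", "fdr", "trend", "tf_fc",
                                      "concordant"])
    if len(out):
        out = out.sort_values(["concordant", "fdr"], ascending=[False, True],
                              na_position="last").reset_index(drop=True)
    return out


def pwm_from_consensus(consensus: str, motif_id: str, tf_names=(),
                       match_p: float = 0.97) -> Pwm:
    """A near-deterministic PWM for a consensus string (off-letters share
    the remaining probability)."""
    off = (1 - match_p) / 3
    m = np.full((len(consensus), 4), off)
    for i, c in enumerate(consensus.upper()):
        m[i, _CODE[c]] = match_p
    return Pwm(motif_id=motif_id, matrix=m, tf_names=tuple(tf_names))
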