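import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teprom import motif_scan as ms
from teprom.expression_dynamics import FoldChangeTable, GeneClusters, rank_bins

RC = str.maketrans("ACGT", "TGCA")


def _uniform_pwm(L=4, pc=0.0):
    return ms.Pwm("U", np.full((L, 4), 0.25), pseudocount=pc)


def _det_pwm(consensus, pc=0.0):
    m = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus):
        m[i, "ACGT".index(c)] = 1.0
    return ms.Pwm(consensus, m, pseudocount=pc)


def brute_force_max(seq, pwm):
    """Exhaustive per-window log-odds oracle over both strands."""
    S = ms.log_odds(pwm)
    L = len(pwm)
    best = np.nan
    for strand_seq in (seq, seq.translate(RC)[::-1]):
        for i in range(len(strand_seq) - L + 1):
            win = strand_seq[i:i + L]
            if "N" in win:
                continue
            score = sum(S[j, "ACGT".index(win[j])] for j in range(L))
            if np.isnan(best) or score > best:
                best = score
    return best


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        S = ms.log_odds(_uniform_pwm())
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_deterministic_dimer_max_score_four_bits(self):
        pwm = _det_pwm("AC")
        assert ms.max_achievable_score(pwm) == pytest.approx(4.0)

    def test_monotone_in_probability(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.dirichlet(np.ones(4), size=5)
            pwm = ms.Pwm("r", m, pseudocount=0.01)
            S = ms.log_odds(pwm)
            order = np.argsort(m, axis=1)
            Ssorted = np.take_along_axis(S, order, axis=1)
            assert (np.diff(Ssorted, axis=1) >= -1e-12).all()


class TestScanSequence:
    def test_strand_symmetry_of_planted_motif(self):
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), size=100))
        motif = "TTAATCC"
        pwm = ms.pwm_from_consensus(motif, "m")
        fwd_seq = bg[:40] + motif + bg[40:]
        rev_seq = bg[:40] + motif.translate(RC)[::-1] + bg[40:]
        r_fwd = ms.scan_sequence(fwd_seq, pwm)
        r_rev = ms.scan_sequence(rev_seq, pwm)
        assert r_fwd.max_score == pytest.approx(r_rev.max_score)
        assert r_rev.best_strand == "-"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                     size=200))
            m = rng.dirichlet(np.ones(4), size=int(rng.integers(3, 9)))
            pwm = ms.Pwm(f"r{trial}", m, pseudocount=0.01)
            got = ms.scan_sequence(seq, pwm).max_score
            expected = brute_force_max(seq, pwm)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        pwm = ms.Pwm("r", rng.dirichlet(np.ones(4), size=6), pseudocount=0.01)
        a = ms.scan_sequence(seq, pwm)
        b = ms.scan_sequence(seq.translate(RC)[::-1], pwm)
        assert a.max_score == pytest.approx(b.max_score)
        assert a.n_sites(0.8) == b.n_sites(0.8)

    def test_too_short_sequence_is_missing(self):
        res = ms.scan_sequence("ACG", _det_pwm("ACGTA"))
        assert np.isnan(res.max_score)

    def test_n_sites_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = ms.pwm_from_consensus("TAATCC", "m")
        res = ms.scan_sequence(seq, pwm)
        taus = [0.2, 0.5, 0.8, 1.0]
        counts = [res.n_sites(t) for t in taus]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_tau_one_counts_only_perfect_consensus(self):
        motif = "TAATCC"
        pwm = _det_pwm(motif, pc=0.01)
        seq = "G" * 20 + motif + "G" * 20 + motif + "G" * 10 + "TAATCG" + "G" * 10
        assert ms.count_consensus_sites(seq, pwm, tau=1.0) == 2


class TestCountConsensusSites:
    def test_three_planted_exact_motifs(self):
        motif = "TAATCC"
        pwm = ms.pwm_from_consensus(motif, "m")
        spacer = "GGGGGGGGGG"
        seq = spacer + motif + spacer + motif + spacer + motif + spacer
        assert ms.count_consensus_sites(seq, pwm, tau=1.0) == 3

    def test_zero_length_motif_rejected(self):
        with pytest.raises(ValueError):
            ms.Pwm("bad", np.zeros((0, 4)))

    def test_fixture_matches_brute_force(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        pwm = ms.pwm_from_consensus("TTAACC", "m")
        S = ms.log_odds(pwm)
        threshold = 0.9 * ms.max_achievable_score(pwm)
        expected = 0
        for strand_seq in (seq, seq.translate(RC)[::-1]):
            for i in range(len(strand_seq) - 6 + 1):
                win = strand_seq[i:i + 6]
                score = sum(S[j, "ACGT".index(win[j])] for j in range(6))
                if score >= threshold - 1e-12:
                    expected += 1
        assert ms.count_consensus_sites(seq, pwm, tau=0.9) == expected


class TestGroupAnova:
    def _groups(self, sizes):
        ids, labels = [], []
        for b, n in enumerate(sizes, start=1):
            for i in range(n):
                ids.append(f"g{b}_{i:03d}")
                labels.append(b)
        return GeneClusters(pd.Series(labels, index=ids), "rank_bin", group_size=max(sizes))

    def test_zero_between_group_variance_gives_f0(self):
        groups = self._groups([5, 5])
        scores = pd.DataFrame({"m": 1.0}, index=groups.labels.index)
        res = ms.group_motif_anova(scores, groups)
        assert res.iloc[0]["F"] == 0.0
        assert res.iloc[0]["p"] == 1.0

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(6)
        groups = self._groups([12, 15])
        vals = rng.normal(size=27)
        scores = pd.DataFrame({"m": vals}, index=groups.labels.index)
        res = ms.group_motif_anova(scores, groups)
        a, b = vals[:12], vals[12:]
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.iloc[0]["F"] == pytest.approx(t ** 2)

    def test_planted_group_specific_enrichment_detected(self):
        rng = np.random.default_rng(7)
        detected = 0
        n_rounds = 100
        for _ in range(n_rounds):
            groups = self._groups([50] * 5)
            base = rng.normal(0, 1, size=250)
            base[:50] += 1.0  # group 1 carries the motif signal
            scores = pd.DataFrame({"sig": base,
                                   "null": rng.normal(0, 1, size=250)},
                                  index=groups.labels.index)
            res = ms.group_motif_anova(scores, groups).set_index("motif")
            if res.loc["sig", "fdr"] < 0.05:
                detected += 1
        assert detected >= 95

    def test_empty_input_gives_empty_output(self):
        groups = self._groups([3, 3])
        scores = pd.DataFrame(index=groups.labels.index)
        res = ms.group_motif_anova(scores, groups)
        assert len(res) == 0


class TestPrioritizeTfs:
    def _anova(self):
        return pd.DataFrame([
            dict(motif="m1", F=30.0, p=1e-6, trend=-0.9, fdr=2e-6),
            dict(motif="m2", F=1.0, p=0.5, trend=0.2, fdr=0.5),
        ])

    def test_concordant_tf_tops_list(self):
        pwms = [ms.pwm_from_consensus("TAAT", "m1", tf_names=("TFup",)),
                ms.pwm_from_consensus("GGGC", "m2", tf_names=("TFflat",))]
        # motif m1 trend is negative (enriched in high-FC group 1); its TF
        # is itself upregulated -> concordant
        tf_fc = pd.Series({"TFup": -2.5, "TFflat": 0.1})
        out = ms.prioritize_tfs(self._anova(), pwms, tf_fc)
        assert out.iloc[0]["tf"] == "TFup"
        assert out.iloc[0]["concordant"] == 1.0

    def test_missing_tf_retained_with_missing_flag(self):
        pwms = [ms.pwm_from_consensus("TAAT", "m1", tf_names=("Ghost",))]
        out = ms.prioritize_tfs(self._anova().iloc[:1], pwms, pd.Series(dtype=float))
        assert out.iloc[0]["tf"] == "Ghost"
        assert np.isnan(out.iloc[0]["concordant"])

    def test_empty_anova_gives_empty_output(self):
        out = ms.prioritize_tfs(pd.DataFrame(columns=["motif", "fdr", "trend"]),
                                [], pd.Series(dtype=float))
        assert len(out) == 0


class TestAlternativeModes:
    def test_identity_similarity_counts_positional_matches(self):
        motif = "TAATCC"
        pwm = ms.pwm_from_consensus(motif, "m")
        near = "TAATCG"  # 5/6 = 0.83 identity
        seq = "G" * 10 + motif + "G" * 10 + near + "G" * 10
        assert ms.count_consensus_sites(seq, pwm, tau=1.0, similarity="identity") == 1
        assert ms.count_consensus_sites(seq, pwm, tau=0.8, similarity="identity") == 2

    def test_rank_transform_preserves_detection(self):
        rng = np.random.default_rng(20)
        ids = [f"g{i:03d}" for i in range(100)]
        groups = GeneClusters(pd.Series([1] * 50 + [2] * 50, index=ids),
                              "rank_bin", group_size=50)
        vals = rng.normal(size=100)
        vals[:50] += 2.0
        scores = pd.DataFrame({"m": vals}, index=ids)
        raw = ms.group_motif_anova(scores, groups)
        ranked = ms.group_motif_anova(scores, groups, rank_transform=True)
        assert raw.iloc[0]["p"] < 1e-6 and ranked.iloc[0]["p"] < 1e-6
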