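"""Agreement and sleep-architecture metrics against hand-computed oracles
and independent library implementations."""

import numpy as np
import pytest
from scipy import stats as sstats
from sklearn.metrics import cohen_kappa_score

from cardiosleep.evaluation import (ConfusionMatrix, accuracy,
                                    class_distribution, cohens_kappa,
                                    confusion, longitudinal_trends,
                                    paired_metric_test, sleep_metrics,
                                    variance_consistency_test)
from cardiosleep.types import Hypnogram, Stage

W, L, D, R, A, P = (int(Stage.WAKE), int(Stage.N1N2), int(Stage.N3),
                    int(Stage.REM), int(Stage.ARTIFACT), int(Stage.PAD))


def embed(two_by_two):
    m = np.zeros((4, 4), dtype=int)
    m[:2, :2] = two_by_two
    return ConfusionMatrix(m)


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        t = np.array([W, L, D, R, L, D])
        cm = confusion(t, t)
        assert np.array_equal(cm.counts, np.diag([1, 2, 2, 1]))

    def test_artifact_epochs_excluded(self):
        t = np.array([W, D, A, R])
        p = np.array([W, L, W, R])
        cm = confusion(t, p)
        assert cm.total == 3
        assert cm.counts[D, L] == 1
        assert cm.counts[W, W] == 1 and cm.counts[R, R] == 1

    def test_pad_epochs_excluded(self):
        t = np.array([W, L, P, P])
        p = np.array([W, L, W, W])
        assert confusion(t, p).total == 2

    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        cm = confusion(rng.integers(0, 4, 500), rng.integers(0, 4, 500))
        rp = cm.row_percent()
        assert np.allclose(rp.sum(axis=1), 100.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([W]), np.array([W, L]))


class TestKappaAccuracy:
    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
        assert accuracy(cm) == 100.0
        assert cohens_kappa(cm) == 1.0

    def test_marginal_independence_gives_zero_kappa(self):
        cm = embed([[25, 25], [25, 25]])
        assert accuracy(cm) == 50.0
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_kappa(self):
        """[[40,10],[20,30]]: p_o = 0.7, p_e = 0.5, kappa = 0.4."""
        cm = embed([[40, 10], [20, 30]])
        assert accuracy(cm) == pytest.approx(70.0)
        assert cohens_kappa(cm) == pytest.approx(0.4)

    def test_matches_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(5)
        t = rng.integers(0, 4, 2000)
        p = np.where(rng.random(2000) < 0.6, t, rng.integers(0, 4, 2000))
        cm = confusion(t, p)
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(t, p),
                                                 abs=1e-12)

    def test_kappa_invariant_under_class_permutation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, (4, 4))
        k0 = cohens_kappa(ConfusionMatrix(counts))
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(4)
            k = cohens_kappa(ConfusionMatrix(counts[np.ix_(perm, perm)]))
            assert k == pytest.approx(k0, abs=1e-12)

    def test_observed_agreement_reconstructed_from_kappa(self):
        """p_o = kappa + p_e * (1 - kappa) inverts the kappa formula."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 40, (4, 4))
        cm = ConfusionMatrix(counts)
        k = cohens_kappa(cm)
        n = cm.total
        p_e = (cm.counts.sum(axis=1) / n) @ (cm.counts.sum(axis=0) / n)
        p_o = np.trace(cm.counts) / n
        assert k + p_e * (1 - k) == pytest.approx(p_o, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((4, 4), int)))
        with pytest.raises(ValueError):
            cohens_kappa(ConfusionMatrix(np.zeros((4, 4), int)))

    def test_degenerate_single_class(self):
        cm = ConfusionMatrix(np.diag([10, 0, 0, 0]))
        assert cohens_kappa(cm) == 1.0


class TestSleepMetrics:
    def test_hand_counted_example(self):
        """10 epochs [W,W,L,L,D,D,R,L,W,W]: TIB 5, TST 3, SE 60, SOL 1."""
        hyp = Hypnogram(np.array([W, W, L, L, D, D, R, L, W, W]))
        m = sleep_metrics(hyp)
        assert m.tib_min == 5.0
        assert m.tst_min == 3.0
        assert m.se_pct == pytest.approx(60.0)
        assert m.sol_min == 1.0
        assert m.pct_n1n2 == pytest.approx(50.0)
        assert m.pct_n3 == pytest.approx(100 / 3)
        assert m.pct_rem == pytest.approx(100 / 6)

    def test_all_wake_night(self):
        m = sleep_metrics(Hypnogram(np.full(10, W)))
        assert m.tst_min == 0.0 and m.se_pct == 0.0
        assert m.sol_min is None and m.pct_n3 is None

    def test_artifact_counts_toward_tib_not_tst(self):
        m = sleep_metrics(Hypnogram(np.array([W, A, D])))
        assert m.tib_min == 1.5
        assert m.tst_min == 0.5

    def test_pad_excluded_entirely(self):
        m = sleep_metrics(Hypnogram(np.array([W, L, P, P])))
        assert m.tib_min == 1.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        m = sleep_metrics(Hypnogram(rng.integers(0, 4, 400)))
        assert m.pct_n1n2 + m.pct_n3 + m.pct_rem == pytest.approx(100.0,
                                                                  abs=0.1)


class TestPairedTests:
    def test_identical_conditions_degenerate(self):
        r = paired_metric_test(np.array([60.0, 65, 70]),
                               np.array([60.0, 65, 70]))
        assert r.degenerate and r.t_stat == 0.0 and r.p_value == 1.0

    def test_constant_shift_degenerate(self):
        r = paired_metric_test(np.array([60.0, 65, 70]),
                               np.array([70.0, 75, 80]))
        assert r.degenerate

    def test_matches_closed_form(self):
        """before [60,70,65,75] -> after [66,74,72,80]: d has mean 5.5 and
        sd sqrt(5/3), so t = 5.5 / (sd/2) = 8.5206..."""
        before = np.array([60.0, 70, 65, 75])
        after = np.array([66.0, 74, 72, 80])
        r = paired_metric_test(before, after)
        t_hand = 5.5 / (np.sqrt(5.0 / 3.0) / 2.0)
        assert r.t_stat == pytest.approx(t_hand, abs=1e-10)
        assert r.p_value == pytest.approx(2 * sstats.t.sf(t_hand, df=3),
                                          abs=1e-12)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            paired_metric_test(np.array([1.0, 2]), np.array([2.0, 3]))


class TestVarianceConsistency:
    def test_equal_conditions_degenerate(self):
        acc = np.array([60.0, 70, 80, 90])
        r = variance_consistency_test(acc, acc)
        assert r.degenerate and r.p_value == 1.0

    def test_reduced_spread_gives_negative_t(self):
        a = np.array([60.0, 80, 60, 80])   # spread +/-10
        b = np.array([68.0, 72, 68, 72])   # spread +/-2, same mean
        r = variance_consistency_test(a, b)
        assert r.t_stat < 0

    def test_mean_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(70, 10, 8)
        b = rng.normal(70, 3, 8)
        r1 = variance_consistency_test(a, b)
        r2 = variance_consistency_test(a, b + 13.5)
        assert r1.t_stat == pytest.approx(r2.t_stat, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-9)


class TestTrends:
    def _nights(self):
        rng = np.random.default_rng(4)
        nights = []
        for p in range(3):
            for label in ("B1", "I1"):
                hyp = Hypnogram(rng.integers(0, 4, 120))
                nights.append((f"P{p}", label, hyp, hyp))
        return nights

    def test_identity_predictions_match_expert_table(self):
        table = longitudinal_trends(self._nights())
        piv = table.pivot_table(index=["metric", "night_label"],
                                columns="source", values="mean")
        assert np.allclose(piv["expert"], piv["model"])

    def test_single_participant_sem_missing(self):
        nights = self._nights()[:1]
        table = longitudinal_trends(nights)
        assert (table["n"] == 1).all()
        assert table["sem"].isna().all()

    def test_missing_model_rows_skipped(self):
        nights = [(p, l, h, None) for p, l, h, _ in self._nights()]
        table = longitudinal_trends(nights)
        assert set(table["source"]) == {"expert"}


class TestClassDistribution:
    def test_percentages_from_counts(self):
        pct = class_distribution([30, 50, 20])
        assert np.allclose(pct, [30.0, 50.0, 20.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_distribution([0, 0])
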