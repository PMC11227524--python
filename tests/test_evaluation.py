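import numpy as np
import pytest

from hjdpose.evaluation import (BalanceError, EvaluationReport, FoldPlan,
                                FoldResult, anova_oneway, balance_downsample,
                                chance_level, chance_level_mc, confusion,
                                evaluate_loso, moving_average, plan_loso,
                                run_fold, temporal_accuracy)
from hjdpose.features import WindowSpec
from hjdpose.io import STAGES, MocapRecording, StageAnnotation


def fake_windows(rng, subjects, per_stage):
    """Synthetic labelled feature windows keyed by subject."""
    out = {}
    for s in subjects:
        ys, xs = [], []
        for lbl in range(5):
            n = per_stage[s][lbl] if isinstance(per_stage, dict) else per_stage
            ys.append(np.full(n, lbl))
            xs.append(rng.normal(lbl, 0.1, size=(n, 6)))
        out[s] = (np.concatenate(xs), np.concatenate(ys))
    return out


def uniform_durations(subjects, seconds):
    return {s: {g: float(seconds) for g in STAGES} for s in subjects}


class StubClassifier:
    """Deterministic stub: optionally always-correct or constant output."""

    def __init__(self, mode="echo", constant=0):
        self.mode = mode
        self.constant = constant

    def fit(self, X, y):
        self._lookup = {tuple(np.round(x, 9)): lbl for x, lbl in zip(X, y)}
        self._train_X = X.copy()
        return self

    def predict(self, X):
        if self.mode == "constant":
            return np.full(len(X), self.constant)
        # 'echo' mode: nearest training point's label (features encode labels)
        return np.array([int(round(x.mean())) for x in X]).clip(0, 4)


class TestPlanLoso:
    def test_five_subjects_five_folds(self):
        plans = plan_loso(uniform_durations("ABCDE", 30))
        assert len(plans) == 5
        for p in plans:
            assert p.test_subject not in p.train_subjects
            assert len(p.train_subjects) == 4

    def test_fractional_minimum_floored_to_18s(self):
        durations = uniform_durations(["S1", "S2", "S3", "S4", "S5"], 120)
        durations["S4"]["CR1"] = 18.94
        plans = plan_loso(durations, WindowSpec(5, 4))
        p5 = next(p for p in plans if p.test_subject == "S5")
        assert p5.balance_target_s == 18
        assert p5.samples_per_stage == 4  # starts 0,4,8,12
        # when S4 itself is held out, the other subjects set a 120 s target
        p4 = next(p for p in plans if p.test_subject == "S4")
        assert p4.balance_target_s == 120

    def test_two_subjects(self):
        plans = plan_loso(uniform_durations("AB", 30))
        assert len(plans) == 2
        assert plans[0].train_subjects == ("B",)

    def test_test_subject_in_train_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan("A", ("A", "B"), 10, 2, 0)


class TestBalance:
    def test_already_balanced_preserved(self, rng):
        windows = fake_windows(rng, "AB", 4)
        plan = FoldPlan("A", ("B",), 30, 4, seed=1)
        Xb, yb = balance_downsample(windows, plan)
        assert np.array_equal(np.sort(Xb.sum(axis=1)), np.sort(windows["B"][0].sum(axis=1)))

    def test_uneven_counts_downsampled_flat(self, rng):
        per = {"A": dict(enumerate([10, 20, 30, 40, 50])), "B": dict(enumerate([10] * 5))}
        windows = fake_windows(rng, "AB", per)
        plan = FoldPlan("B", ("A",), 30, 10, seed=1)
        _, yb = balance_downsample(windows, plan)
        assert np.array_equal(np.bincount(yb), [10] * 5)

    def test_seed_determinism(self, rng):
        windows = fake_windows(rng, "AB", 8)
        plan = FoldPlan("A", ("B",), 30, 5, seed=42)
        X1, _ = balance_downsample(windows, plan)
        X2, _ = balance_downsample(windows, plan)
        assert np.array_equal(X1, X2)
        other = FoldPlan("A", ("B",), 30, 5, seed=43)
        X3, y3 = balance_downsample(windows, other)
        assert np.bincount(y3).tolist() == [5] * 5
        assert not np.array_equal(X1, X3)

    def test_insufficient_windows_named(self, rng):
        per = {"A": dict(enumerate([9] * 5)), "B": dict(enumerate([9, 3, 9, 9, 9]))}
        windows = fake_windows(rng, "AB", per)
        plan = FoldPlan("A", ("B",), 30, 5, seed=0)
        with pytest.raises(BalanceError, match="B stage B2"):
            balance_downsample(windows, plan)


class TestRunFold:
    def test_perfect_stub_scores_100(self, rng):
        windows = fake_windows(rng, "AB", 6)
        plan = FoldPlan("A", ("B",), 30, 6, seed=0)
        res = run_fold(plan, windows, lambda seed: StubClassifier("echo"))
        assert res.accuracy_pct == 100.0

    def test_constant_stub_on_balanced_labels_is_20pct(self, rng):
        windows = fake_windows(rng, "AB", 10)
        plan = FoldPlan("A", ("B",), 30, 10, seed=0)
        res = run_fold(plan, windows, lambda seed: StubClassifier("constant", 3))
        assert res.accuracy_pct == pytest.approx(20.0)

    def test_training_never_sees_test_windows(self, rng):
        windows = fake_windows(rng, "ABC", 5)
        plan = FoldPlan("A", ("B", "C"), 30, 5, seed=0)
        clf = StubClassifier("echo")
        run_fold(plan, windows, lambda seed: clf)
        test_rows = {tuple(np.round(x, 9)) for x in windows["A"][0]}
        train_rows = {tuple(np.round(x, 9)) for x in clf._train_X}
        assert not test_rows & train_rows

    def test_report_mean_equals_fold_mean(self, rng):
        windows = fake_windows(rng, "ABC", 8)  # 8 >= the 7-window target below
        rep = evaluate_loso(windows, uniform_durations("ABC", 30),
                            lambda seed: StubClassifier("echo"))
        assert rep.mean_accuracy_pct == pytest.approx(np.mean(rep.accuracies), abs=1e-12)


class TestTemporalAccuracy:
    def _tiny(self):
        pos = np.zeros((3000, 12, 3))
        pos[:, 2, 0] = -40.0  # LHip
        pos[:, 3, 0] = 40.0   # RHip
        pos[:, 0, 1] = 300.0  # Head
        pos[:, 10, :] = (10.0, -150.0, 30.0)
        rec = MocapRecording("T", pos, 100.0)
        ann = StageAnnotation(
            ((0, 6, "B1"), (6, 12, "B2"), (12, 18, "CR1"), (18, 24, "CR2"), (24, 30, "DC"))
        )
        return rec, ann

    class _Always:
        def __init__(self, lbl):
            self.lbl = lbl

        def predict(self, X):
            return np.full(len(X), self.lbl)

    def test_flat_curve_structure(self):
        rec, ann = self._tiny()
        times, correct, labels = temporal_accuracy(
            self._Always(0), rec, ann, ("LFoot",), width=5.0, stride=1.0
        )
        # stub predicting stage 0 is right exactly inside B1
        assert np.array_equal(correct == 1.0, labels == 0)
        # window count: floor((6-5)/1)+1 = 2 windows per 6 s stage
        assert len(times) == 10
        assert np.all(np.diff(times) >= 0)

    def test_hand_enumerated_windows(self):
        rec, ann = self._tiny()
        times, correct, labels = temporal_accuracy(
            self._Always(2), rec, ann, ("LFoot",), width=5.0, stride=1.0
        )
        expected_starts = [0, 1, 6, 7, 12, 13, 18, 19, 24, 25]
        assert [round(t) for t in times] == expected_starts
        assert correct.sum() == 2  # only the two CR1 windows


class TestMovingAverage:
    def test_constant_curve_unchanged(self):
        v = np.full(17, 0.7)
        np.testing.assert_allclose(moving_average(v, 5), v)

    def test_span_one_identity(self, rng):
        v = rng.random(20)
        np.testing.assert_array_equal(moving_average(v, 1), v)

    def test_matches_direct_windowed_mean(self, rng):
        v = rng.random(30)
        span = 7
        got = moving_average(v, span)
        for i in range(30):
            lo = max(i - (span - 1) // 2, 0)
            hi = min(i + span // 2 + 1, 30)
            assert got[i] == pytest.approx(v[lo:hi].mean())


class TestConfusion:
    def test_perfect_diagonal(self):
        y = np.repeat(np.arange(5), 3)
        m = confusion(y, y)
        assert np.array_equal(m, np.diag([3.0] * 5))

    def test_constant_predictor_single_column(self):
        y = np.repeat(np.arange(5), 2)
        m = confusion(np.ones_like(y), y)
        assert m[:, 1].sum() == 10 and m.sum() == 10

    def test_matches_direct_tally(self, rng):
        yt = rng.integers(0, 5, 100)
        yp = rng.integers(0, 5, 100)
        m = confusion(yp, yt)
        for i in range(5):
            for j in range(5):
                assert m[i, j] == np.sum((yt == i) & (yp == j))
        rows = confusion(yp, yt, normalize=True).sum(axis=1)
        np.testing.assert_allclose(rows[np.bincount(yt, minlength=5) > 0], 1.0)


class TestAnova:
    def test_identical_groups_zero_f(self):
        g = [1.0, 2.0, 3.0]
        F, df1, df2, p = anova_oneway([g, g, g])
        assert F == pytest.approx(0.0)
        assert (df1, df2) == (2, 6)

    def test_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2.0], [4.0, 6.0], [9.0, 10.0]]
        means = [np.mean(g) for g in groups]
        grand = np.mean([x for g in groups for x in g])
        ss_between = sum(2 * (m - grand) ** 2 for m in means)
        ss_within = sum((x - m) ** 2 for g, m in zip(groups, means) for x in g)
        expected_F = (ss_between / 2) / (ss_within / 3)
        F, df1, df2, p = anova_oneway(groups)
        assert F == pytest.approx(expected_F, rel=1e-12)
        assert (df1, df2) == (2, 3)
        assert 0 <= p <= 1

    def test_shift_invariance(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        F1, *_ = anova_oneway(groups)
        F2, *_ = anova_oneway([g + 100.0 for g in groups])
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ZeroDivisionError):
            anova_oneway([[2.0, 2.0], [2.0, 2.0]])


def test_chance_level_closed_form_and_mc():
    assert chance_level(5) == 20.0
    mc = chance_level_mc(5, n_draws=100_000, seed=11)
    assert abs(mc - 20.0) <= 0.5
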