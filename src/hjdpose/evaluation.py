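"""Leave-one-subject-out evaluation with stage-balanced training sets.

Each fold holds out every window of one subject.  Training windows from
the remaining subjects are balanced by downsampling every (subject, stage)
cell to the window count realisable in the shortest stage across the
training subjects (floored to whole seconds), so labels are exactly flat.
Fold accuracy is the percentage of correctly classified held-out windows.

Also provides the sliding-window temporal accuracy curve (one stage swept
at a fine stride), centered moving averages, confusion matrices, one-way
ANOVA for method comparison, and the five-class chance-level anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import SphericalBinning, WindowSpec, bin_indices, compute_hjd, make_windows
from .io import MocapRecording, StageAnnotation, STAGES

__all__ = [
    "FoldPlan",
    "FoldResult",
    "EvaluationReport",
    "BalanceError",
    "plan_loso",
    "balance_downsample",
    "run_fold",
    "evaluate_loso",
    "temporal_accuracy",
    "moving_average",
    "confusion",
    "anova_oneway",
    "chance_level",
    "chance_level_mc",
]


class BalanceError(ValueError):
    """A (subject, stage) cell has too few windows to balance."""


@dataclass(frozen=True)
class FoldPlan:
    test_subject: str
    train_subjects: tuple[str, ...]
    balance_target_s: int
    samples_per_stage: int
    seed: int

    def __post_init__(self):
        if self.test_subject in self.train_subjects:
            raise ValueError("test subject must not appear in training")


@dataclass
class FoldResult:
    plan: FoldPlan
    accuracy_pct: float
    y_true: np.ndarray
    y_pred: np.ndarray


@dataclass
class EvaluationReport:
    fold_results: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy_pct for f in self.fold_results])

    @property
    def mean_accuracy_pct(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy_pct(self) -> float:
        """Standard deviation of the per-fold accuracies."""
        return float(self.accuracies.std(ddof=1)) if len(self.fold_results) > 1 else 0.0

    def pooled_confusion(self, normalize: bool = False) -> np.ndarray:
        yt = np.concatenate([f.y_true for f in self.fold_results])
        yp = np.concatenate([f.y_pred for f in self.fold_results])
        return confusion(yp, yt, normalize=normalize)


def plan_loso(
    stage_durations: dict[str, dict[str, float]],
    spec: WindowSpec | None = None,
    master_seed: int = 0,
) -> list[FoldPlan]:
    """One fold per subject, with the balance target recomputed per fold.

    ``stage_durations[subject][stage]`` gives available seconds per stage.
    The per-fold balance target is the minimum stage duration among the
    training subjects, floored to whole seconds; ``samples_per_stage`` is
    the number of sliding windows that fit in that many seconds.
    """
    spec = spec or WindowSpec()
    subjects = list(stage_durations)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    seeds = np.random.SeedSequence(master_seed).generate_state(len(subjects))
    plans = []
    for i, test in enumerate(subjects):
        train = tuple(s for s in subjects if s != test)
        target = math.floor(min(d for s in train for d in stage_durations[s].values()))
        if target < spec.width:
            raise ValueError(f"balance target {target}s shorter than window width")
        n = math.floor((target - spec.width) / spec.stride) + 1
        plans.append(FoldPlan(test, train, target, n, int(seeds[i]) % (2**31)))
    return plans


def balance_downsample(
    windows: dict[str, tuple[np.ndarray, np.ndarray]], plan: FoldPlan
):
    """Uniformly subsample each training (subject, stage) to the fold target.

    ``windows`` maps subject id to ``(X, y)``.  Returns concatenated
    ``(X_bal, y_bal)`` with exactly ``samples_per_stage`` windows per
    (subject, stage); the draw is seeded by the fold plan.
    """
    rng = np.random.default_rng(plan.seed)
    xs, ys = [], []
    for subj in plan.train_subjects:
        X, y = windows[subj][0], windows[subj][1]
        for lbl in range(len(STAGES)):
            idx = np.flatnonzero(y == lbl)
            if idx.size < plan.samples_per_stage:
                raise BalanceError(
                    f"subject {subj} stage {STAGES[lbl]}: {idx.size} windows "
                    f"< target {plan.samples_per_stage}"
                )
            keep = np.sort(rng.choice(idx, size=plan.samples_per_stage, replace=False))
            xs.append(X[keep])
            ys.append(y[keep])
    return np.concatenate(xs), np.concatenate(ys)


def run_fold(plan: FoldPlan, windows, make_classifier) -> FoldResult:
    """Train on the balanced training windows, test on every held-out window.

    ``make_classifier(seed)`` must return an unfitted estimator; it receives
    the fold seed so per-fold initialisation is reproducible.
    """
    Xtr, ytr = balance_downsample(windows, plan)
    Xte, yte = windows[plan.test_subject][0], windows[plan.test_subject][1]
    clf = make_classifier(plan.seed)
    clf.fit(Xtr.reshape(len(Xtr), -1), ytr)
    pred = clf.predict(Xte.reshape(len(Xte), -1))
    acc = 100.0 * float(np.mean(pred == yte))
    return FoldResult(plan, acc, yte.copy(), np.asarray(pred))


def evaluate_loso(windows, stage_durations, make_classifier,
                  spec: WindowSpec | None = None, master_seed: int = 0) -> EvaluationReport:
    """Full leave-one-subject-out evaluation; one fold per subject."""
    report = EvaluationReport()
    for plan in plan_loso(stage_durations, spec, master_seed):
        report.fold_results.append(run_fold(plan, windows, make_classifier))
    return report


def temporal_accuracy(
    model,
    rec: MocapRecording,
    ann: StageAnnotation,
    joints: tuple[str, ...],
    scheme: SphericalBinning | None = None,
    width: float = 5.0,
    stride: float = 0.5,
):
    """Per-window correctness of a trained model swept across a recording.

    Returns ``(times, correct, labels)`` for every labelled window at the
    given (typically fine) stride; the five-stage "ascending steps" plot is
    ``labels + correct`` against ``times``.
    """
    scheme = scheme or SphericalBinning()
    bins = bin_indices(rec, scheme)
    ws = [w for w in make_windows(rec, ann, WindowSpec(width, stride)) if w.label is not None]
    X = np.empty((len(ws), len(joints) * scheme.n_bins))
    for i, w in enumerate(ws):
        X[i] = np.concatenate(
            [compute_hjd(rec, j, (w.start, w.width), scheme, _bins=bins).hist for j in joints]
        )
    y = np.array([w.label for w in ws])
    times = np.array([w.start for w in ws])
    pred = model.predict(X)
    return times, (pred == y).astype(float), y


def moving_average(curve: np.ndarray, span: int) -> np.ndarray:
    """Centered moving mean with edge truncation (span 1 is the identity)."""
    if span < 1:
        raise ValueError("span must be >= 1")
    v = np.asarray(curve, dtype=float)
    if span == 1:
        return v.copy()
    n = v.size
    half_lo = (span - 1) // 2
    half_hi = span // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def confusion(preds, labels, n_classes: int = 5, normalize: bool = False) -> np.ndarray:
    """Confusion matrix ``[true, predicted]`` over the stage labels."""
    m = _sk_confusion(labels, preds, labels=np.arange(n_classes)).astype(float)
    if normalize:
        rows = m.sum(axis=1, keepdims=True)
        m = np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)
    return m


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns ``(F, df1, df2, p)``.

    Raises on the degenerate all-constant, equal-means case where F is 0/0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if all(g.std() == 0 for g in groups) and len({float(g.mean()) for g in groups}) == 1:
        raise ZeroDivisionError("F undefined: zero variance within and between groups")
    F, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    return float(F), df1, df2, float(p)


def chance_level(n_classes: int = 5) -> float:
    """Expected accuracy (%) of uniform random guessing on balanced labels."""
    return 100.0 / n_classes


def chance_level_mc(n_classes: int = 5, n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the chance level on a balanced label set."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n_draws)
    guesses = rng.integers(0, n_classes, size=n_draws)
    return 100.0 * float(np.mean(labels == guesses))
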