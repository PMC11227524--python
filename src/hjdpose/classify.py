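"""Stage classifiers over HJD features, as scikit-learn estimators.

Seven architectures are provided, mirroring the comparison this package
supports: two classic baselines (kNN, LDA, delegating to scikit-learn) and
five neural models trained with Adam on the package's own autodiff engine —
a fully connected network, 1D and 2D convolutional networks, and 1D and 2D
capsule networks whose class capsules are formed by dynamic routing and
trained with a margin loss on capsule norms.

1D models consume the concatenated per-joint histogram vector; 2D models
consume the joints x bins matrix (flattened in X, re-shaped internally via
``n_joints``), letting convolution mix information across body parts.
All estimators are deterministic given their ``seed``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .nn.autodiff import Adam, Tensor
from .nn.capsule import margin_loss_t, routing_t, squash_t

__all__ = [
    "TrainingError",
    "KNNStageClassifier",
    "LDAStageClassifier",
    "FCNetClassifier",
    "Conv1DClassifier",
    "Conv2DClassifier",
    "CapsNet1DClassifier",
    "CapsNet2DClassifier",
    "build_model",
    "ARCHITECTURES",
]


class TrainingError(RuntimeError):
    """Optimization diverged (non-finite loss)."""


# ---------------------------------------------------------------------------
# Classic baselines
# ---------------------------------------------------------------------------

class KNNStageClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour stage classifier (Euclidean, majority vote).

    ``n_neighbors`` may be an integer or ``"cv"``, in which case k is chosen
    from ``cv_grid`` by stratified cross-validation within the training set
    (ties resolved toward the smaller k).  Prediction ties resolve to the
    lowest label.
    """

    def __init__(self, n_neighbors=5, cv_grid=(1, 3, 5, 7, 9), cv_folds=3):
        self.n_neighbors = n_neighbors
        self.cv_grid = cv_grid
        self.cv_folds = cv_folds

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        k = self.n_neighbors
        if k == "cv":
            k = self._select_k(X, y)
        if k > X.shape[0]:
            raise ValueError(f"k={k} exceeds {X.shape[0]} training points")
        self.k_ = int(k)
        self._knn = KNeighborsClassifier(n_neighbors=self.k_, metric="euclidean")
        self._knn.fit(X, y)
        self.classes_ = self._knn.classes_
        return self

    def _select_k(self, X, y):
        _, counts = np.unique(y, return_counts=True)
        n_folds = min(self.cv_folds, counts.min())
        grid = [k for k in self.cv_grid if k <= X.shape[0] * (n_folds - 1) / max(n_folds, 1)]
        if n_folds < 2 or not grid:
            return min(5, X.shape[0])
        cv = StratifiedKFold(n_splits=n_folds)
        best_k, best_acc = grid[0], -1.0
        for k in grid:
            accs = []
            for tr, te in cv.split(X, y):
                m = KNeighborsClassifier(n_neighbors=min(k, len(tr))).fit(X[tr], y[tr])
                accs.append(m.score(X[te], y[te]))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_k, best_acc = k, acc
        return best_k

    def predict(self, X):
        check_is_fitted(self, "k_")
        X = check_array(X)
        # argmax over predict_proba resolves ties toward the lowest label
        proba = self._knn.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class LDAStageClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis with optional shrinkage regularization."""

    def __init__(self, shrinkage=None):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("LDA requires at least 2 classes")
        if self.shrinkage is None:
            self._lda = LinearDiscriminantAnalysis(solver="svd")
        else:
            self._lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage)
        self._lda.fit(X, y)
        self.classes_ = self._lda.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._lda.predict(check_array(X))

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        return self._lda.decision_function(check_array(X))


# ---------------------------------------------------------------------------
# Neural classifiers
# ---------------------------------------------------------------------------

def _he(rng, *shape):
    fan_in = int(np.prod(shape[1:])) or 1
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class _NeuralBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict loop: mini-batch Adam with seeded init & shuffle."""

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], len(self.classes_), rng)
        opt = Adam(self._params, lr=self.lr)
        n = X.shape[0]
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for i0 in range(0, n, self.batch_size):
                idx = order[i0 : i0 + self.batch_size]
                opt.zero_grad()
                loss = self._loss(X[idx], y_idx[idx])
                if not np.isfinite(loss.data):
                    raise TrainingError("training loss is not finite")
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(idx))
            history.append(sum(losses) / n)
        self.history_ = history
        return self

    def predict(self, X):
        check_is_fitted(self, "history_")
        X = check_array(X)
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def decision_function(self, X):
        check_is_fitted(self, "history_")
        X = check_array(X)
        scores = []
        for i0 in range(0, X.shape[0], 256):
            scores.append(self._scores(X[i0 : i0 + 256]))
        return np.concatenate(scores, axis=0)


class FCNetClassifier(_NeuralBase):
    """Fully connected network on the concatenated HJD vector."""

    def __init__(self, hidden=(128, 64), epochs=100, lr=1e-3, batch_size=32, seed=0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, d, n_classes, rng):
        dims = [d, *self.hidden, n_classes]
        self._W = [Tensor(_he(rng, dims[i + 1], dims[i]).T, requires_grad=True)
                   for i in range(len(dims) - 1)]
        self._b = [Tensor(np.zeros(dims[i + 1]), requires_grad=True)
                   for i in range(len(dims) - 1)]
        self._params = self._W + self._b

    def _logits(self, Xb):
        h = Tensor(Xb)
        for i, (W, b) in enumerate(zip(self._W, self._b)):
            h = h @ W + b
            if i < len(self._W) - 1:
                h = h.relu()
        return h

    def _loss(self, Xb, yb):
        return self._logits(Xb).cross_entropy(yb)

    def _scores(self, Xb):
        return self._logits(Xb).data


class Conv1DClassifier(_NeuralBase):
    """1D CNN over the concatenated HJD vector (conv-pool stem + dense head)."""

    def __init__(self, filters=(32, 64), kernel=3, dense=64,
                 epochs=100, lr=1e-3, batch_size=32, seed=0):
        self.filters = filters
        self.kernel = kernel
        self.dense = dense
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, d, n_classes, rng):
        f1, f2 = self.filters
        k = self.kernel
        self._w1 = Tensor(_he(rng, f1, 1, k), requires_grad=True)
        self._b1 = Tensor(np.zeros((f1, 1)), requires_grad=True)
        self._w2 = Tensor(_he(rng, f2, f1, k), requires_grad=True)
        self._b2 = Tensor(np.zeros((f2, 1)), requires_grad=True)
        L = (d - k + 1) // 2
        L = (L - k + 1) // 2
        if L < 1:
            raise ValueError(f"input length {d} too short for this stem")
        self._flat = f2 * L
        self._Wd = Tensor(_he(rng, self.dense, self._flat).T, requires_grad=True)
        self._bd = Tensor(np.zeros(self.dense), requires_grad=True)
        self._Wo = Tensor(_he(rng, n_classes, self.dense).T, requires_grad=True)
        self._bo = Tensor(np.zeros(n_classes), requires_grad=True)
        self._params = [self._w1, self._b1, self._w2, self._b2,
                        self._Wd, self._bd, self._Wo, self._bo]

    def _logits(self, Xb):
        B = Xb.shape[0]
        h = Tensor(Xb[:, None, :])
        h = (h.conv1d(self._w1) + self._b1).relu().maxpool1d(2)
        h = (h.conv1d(self._w2) + self._b2).relu().maxpool1d(2)
        h = h.reshape(B, self._flat)
        h = (h @ self._Wd + self._bd).relu()
        return h @ self._Wo + self._bo

    def _loss(self, Xb, yb):
        return self._logits(Xb).cross_entropy(yb)

    def _scores(self, Xb):
        return self._logits(Xb).data


class Conv2DClassifier(_NeuralBase):
    """2D CNN over the joints x bins HJD matrix.

    Kernel heights adapt to the (small) joint axis; requires ``n_joints >= 2``
    so that convolution can mix information across body parts.
    """

    def __init__(self, n_joints=2, filters=(32, 64), kernel=3, dense=64,
                 epochs=100, lr=1e-3, batch_size=32, seed=0):
        self.n_joints = n_joints
        self.filters = filters
        self.kernel = kernel
        self.dense = dense
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, d, n_classes, rng):
        J = self.n_joints
        if J < 2:
            raise ValueError("2D architectures require at least 2 joints")
        if d % J:
            raise ValueError(f"feature length {d} not divisible by n_joints={J}")
        W = d // J
        f1, f2 = self.filters
        k = self.kernel
        kh1 = min(k, J)
        self._w1 = Tensor(_he(rng, f1, 1, kh1, k), requires_grad=True)
        self._b1 = Tensor(np.zeros((f1, 1, 1)), requires_grad=True)
        H = J - kh1 + 1
        Wl = W - k + 1
        ph1 = min(2, H)
        H, Wl = H // ph1, Wl // 2
        kh2 = min(k, H)
        self._w2 = Tensor(_he(rng, f2, f1, kh2, k), requires_grad=True)
        self._b2 = Tensor(np.zeros((f2, 1, 1)), requires_grad=True)
        H = H - kh2 + 1
        Wl = Wl - k + 1
        ph2 = min(2, H)
        H, Wl = H // ph2, Wl // 2
        if H < 1 or Wl < 1:
            raise ValueError("input too small for this stem")
        self._pool1, self._pool2 = (ph1, 2), (ph2, 2)
        self._shape = (J, W)
        self._flat = f2 * H * Wl
        self._Wd = Tensor(_he(rng, self.dense, self._flat).T, requires_grad=True)
        self._bd = Tensor(np.zeros(self.dense), requires_grad=True)
        self._Wo = Tensor(_he(rng, n_classes, self.dense).T, requires_grad=True)
        self._bo = Tensor(np.zeros(n_classes), requires_grad=True)
        self._params = [self._w1, self._b1, self._w2, self._b2,
                        self._Wd, self._bd, self._Wo, self._bo]

    def _logits(self, Xb):
        B = Xb.shape[0]
        h = Tensor(Xb.reshape(B, 1, *self._shape))
        h = (h.conv2d(self._w1) + self._b1).relu().maxpool2d(self._pool1)
        h = (h.conv2d(self._w2) + self._b2).relu().maxpool2d(self._pool2)
        h = h.reshape(B, self._flat)
        h = (h @ self._Wd + self._bd).relu()
        return h @ self._Wo + self._bo

    def _loss(self, Xb, yb):
        return self._logits(Xb).cross_entropy(yb)

    def _scores(self, Xb):
        return self._logits(Xb).data


class _CapsBase(_NeuralBase):
    """Shared capsule head: primary capsules -> routed class capsules.

    Class scores are capsule norms; training minimises the margin loss.
    Pooling is deliberately absent from the stem — dynamic routing takes its
    place as the aggregation mechanism.
    """

    def _caps_head_build(self, n_caps, n_classes, rng):
        self._Wr = Tensor(
            rng.normal(0.0, 0.1, size=(n_caps, n_classes, self.caps_dim, self.class_caps_dim)),
            requires_grad=True,
        )

    def _route(self, primary):  # primary: Tensor (B, N, caps_dim)
        u = squash_t(primary, axis=-1)
        u_hat = Tensor.caps_predict(u, self._Wr)
        return routing_t(u_hat, iters=self.routing_iters)

    def _loss(self, Xb, yb):
        v = self._class_caps(Xb)
        return margin_loss_t(v, yb, self.m_plus, self.m_minus, self.lam)

    def _scores(self, Xb):
        v = self._class_caps(Xb)
        return np.sqrt((v.data**2).sum(axis=-1))


class CapsNet1DClassifier(_CapsBase):
    """1D capsule network: conv stem, strided primary-capsule conv, routing."""

    def __init__(self, filters=(32, 64), kernel=3, caps_channels=8, caps_dim=8,
                 class_caps_dim=16, primary_stride=4, routing_iters=3,
                 m_plus=0.9, m_minus=0.1, lam=0.5,
                 epochs=100, lr=1e-3, batch_size=32, seed=0):
        self.filters = filters
        self.kernel = kernel
        self.caps_channels = caps_channels
        self.caps_dim = caps_dim
        self.class_caps_dim = class_caps_dim
        self.primary_stride = primary_stride
        self.routing_iters = routing_iters
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lam = lam
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, d, n_classes, rng):
        f1, f2 = self.filters
        k, s = self.kernel, self.primary_stride
        cpc = self.caps_channels * self.caps_dim
        self._w1 = Tensor(_he(rng, f1, 1, k), requires_grad=True)
        self._b1 = Tensor(np.zeros((f1, 1)), requires_grad=True)
        self._w2 = Tensor(_he(rng, f2, f1, k), requires_grad=True)
        self._b2 = Tensor(np.zeros((f2, 1)), requires_grad=True)
        self._wp = Tensor(_he(rng, cpc, f2, k), requires_grad=True)
        self._bp = Tensor(np.zeros((cpc, 1)), requires_grad=True)
        L = d - k + 1
        L = L - k + 1
        Lp = (L - k) // s + 1
        if Lp < 1:
            raise ValueError(f"input length {d} too short for this stem")
        self._n_caps = self.caps_channels * Lp
        self._caps_head_build(self._n_caps, n_classes, rng)
        self._params = [self._w1, self._b1, self._w2, self._b2,
                        self._wp, self._bp, self._Wr]

    def _class_caps(self, Xb):
        B = Xb.shape[0]
        h = Tensor(Xb[:, None, :])
        h = (h.conv1d(self._w1) + self._b1).relu()
        h = (h.conv1d(self._w2) + self._b2).relu()
        h = h.conv1d(self._wp, stride=self.primary_stride) + self._bp
        # (B, caps_channels*caps_dim, Lp) -> (B, caps_channels, caps_dim, Lp)
        B_, C, Lp = h.shape
        h = h.reshape(B_, self.caps_channels, self.caps_dim, Lp)
        h = h.transpose((0, 1, 3, 2)).reshape(B_, self._n_caps, self.caps_dim)
        return self._route(h)


class CapsNet2DClassifier(_CapsBase):
    """2D capsule network over the joints x bins matrix."""

    def __init__(self, n_joints=2, filters=(32, 64), kernel=3, caps_channels=8,
                 caps_dim=8, class_caps_dim=16, primary_stride=3, routing_iters=3,
                 m_plus=0.9, m_minus=0.1, lam=0.5,
                 epochs=100, lr=1e-3, batch_size=32, seed=0):
        self.n_joints = n_joints
        self.filters = filters
        self.kernel = kernel
        self.caps_channels = caps_channels
        self.caps_dim = caps_dim
        self.class_caps_dim = class_caps_dim
        self.primary_stride = primary_stride
        self.routing_iters = routing_iters
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lam = lam
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, d, n_classes, rng):
        J = self.n_joints
        if J < 2:
            raise ValueError("2D architectures require at least 2 joints")
        if d % J:
            raise ValueError(f"feature length {d} not divisible by n_joints={J}")
        W = d // J
        f1, f2 = self.filters
        k, s = self.kernel, self.primary_stride
        cpc = self.caps_channels * self.caps_dim
        kh1 = min(k, J)
        self._w1 = Tensor(_he(rng, f1, 1, kh1, k), requires_grad=True)
        self._b1 = Tensor(np.zeros((f1, 1, 1)), requires_grad=True)
        H, Wl = J - kh1 + 1, W - k + 1
        kh2 = min(k, H)
        self._w2 = Tensor(_he(rng, f2, f1, kh2, k), requires_grad=True)
        self._b2 = Tensor(np.zeros((f2, 1, 1)), requires_grad=True)
        H, Wl = H - kh2 + 1, Wl - k + 1
        khp = min(k, H)
        self._wp = Tensor(_he(rng, cpc, f2, khp, k), requires_grad=True)
        self._bp = Tensor(np.zeros((cpc, 1, 1)), requires_grad=True)
        Hp = H - khp + 1
        Wp = (Wl - k) // s + 1
        if Hp < 1 or Wp < 1:
            raise ValueError("input too small for this stem")
        self._shape = (J, W)
        self._prim_hw = (Hp, Wp)
        self._n_caps = self.caps_channels * Hp * Wp
        self._caps_head_build(self._n_caps, n_classes, rng)
        self._params = [self._w1, self._b1, self._w2, self._b2,
                        self._wp, self._bp, self._Wr]

    def _class_caps(self, Xb):
        B = Xb.shape[0]
        h = Tensor(Xb.reshape(B, 1, *self._shape))
        h = (h.conv2d(self._w1) + self._b1).relu()
        h = (h.conv2d(self._w2) + self._b2).relu()
        h = h.conv2d(self._wp, stride=(1, self.primary_stride)) + self._bp
        Hp, Wp = self._prim_hw
        h = h.reshape(B, self.caps_channels, self.caps_dim, Hp * Wp)
        h = h.transpose((0, 1, 3, 2)).reshape(B, self._n_caps, self.caps_dim)
        return self._route(h)


#: Architecture registry; 2D entries require an ``n_joints`` keyword.
ARCHITECTURES = {
    "kNN": KNNStageClassifier,
    "LDA": LDAStageClassifier,
    "FCNet": FCNetClassifier,
    "Conv1D": Conv1DClassifier,
    "Conv2D": Conv2DClassifier,
    "CapsNet1D": CapsNet1DClassifier,
    "CapsNet2D": CapsNet2DClassifier,
}

TWO_D_ARCHS = ("Conv2D", "CapsNet2D")
DEEP_ARCHS = ("FCNet", "Conv1D", "Conv2D", "CapsNet1D", "CapsNet2D")


def build_model(arch: str, input_shape: tuple[int, int], **cfg):
    """Instantiate an architecture for a (n_joints, n_bins) input shape.

    1D architectures flatten the shape; 2D architectures keep it and refuse
    single-joint inputs.
    """
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}; choose from {list(ARCHITECTURES)}")
    n_joints, _ = input_shape
    if arch in TWO_D_ARCHS:
        if n_joints < 2:
            raise ValueError(f"{arch} requires >= 2 joints, got {n_joints}")
        cfg.setdefault("n_joints", n_joints)
    return ARCHITECTURES[arch](**cfg)
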