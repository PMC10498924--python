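"""The M1-M7 outcome model family.

Every model follows the same contract: ``fit(X, y)`` then
``predict_proba(X)`` returning class-1 probabilities in [0, 1]; hard labels
are 1 exactly when the probability is >= 0.5. M1/M2 wrap scikit-learn
estimators; M3/M4 are fully connected networks and M5-M7 a downscaled
3D CNN with mobile-inverted-bottleneck blocks and squeeze-excitation,
trained with the in-package autograd engine (no GPU framework available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .nn import Adam, Conv3d, Dense, Dropout, MBConv3d, Module, Tensor, bce_with_logits

logger = logging.getLogger(__name__)

PROBABILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model family member."""

    model_id: str                      # "M1" .. "M7"
    input_kind: str = "tabular"        # "tabular" or "image"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_id not in {f"M{i}" for i in range(1, 8)}:
            raise ValueError(f"unknown model id {self.model_id!r}")


class OutcomeModel:
    """Uniform train/predict-probability contract."""

    def fit(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_proba(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= PROBABILITY_THRESHOLD).astype(int)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


class M1Logistic(OutcomeModel):
    """Logistic regression (expects standardized inputs)."""

    def __init__(self, reg_strength: float = 1.0, max_iter: int = 1000, seed: int = 0):
        self.clf = LogisticRegression(C=reg_strength, max_iter=max_iter,
                                      random_state=seed)

    def fit(self, X, y):
        self.clf.fit(np.asarray(X, dtype=np.float64), _check_labels(y))
        return self

    def predict_proba(self, X):
        return self.clf.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]

    @property
    def coef_(self):
        return self.clf.coef_[0]


class M2Forest(OutcomeModel):
    def __init__(self, n_estimators: int = 300, max_features="sqrt", seed: int = 0):
        self.clf = RandomForestClassifier(n_estimators=n_estimators,
                                          max_features=max_features,
                                          random_state=seed)

    def fit(self, X, y):
        self.clf.fit(np.asarray(X, dtype=np.float64), _check_labels(y))
        return self

    def predict_proba(self, X):
        return self.clf.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]


class _FcnnNet(Module):
    def __init__(self, n_in: int, hidden: tuple[int, ...], dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = []
        prev = n_in
        for width in hidden:
            self.layers.append(self._child(Dense(prev, width, rng)))
            prev = width
        self.dropout = self._child(Dropout(dropout, rng))
        self.head = self._child(Dense(prev, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h).relu()
        h = self.dropout(h)
        return self.head(h)


def _focal_loss(logits: Tensor, y: np.ndarray, gamma: float = 2.0) -> Tensor:
    p = logits.sigmoid()
    eps = 1e-7
    y = np.asarray(y, dtype=np.float64).reshape(logits.shape)
    pos = (p + eps).log() * ((1.0 - p) ** gamma) * y
    neg = (1.0 - p + eps).log() * (p ** gamma) * (1.0 - y)
    return -(pos + neg).mean()


class M3Fcnn(OutcomeModel):
    """Fully connected network on tabular inputs."""

    interactions = False

    def __init__(self, hidden: tuple[int, ...] = (16,), dropout: float = 0.1,
                 loss: str = "bce", epochs: int = 400, lr: float = 1e-2,
                 seed: int = 0):
        if loss not in ("bce", "focal"):
            raise ValueError(f"unknown loss {loss!r}")
        self.hidden, self.dropout, self.loss = hidden, dropout, loss
        self.epochs, self.lr, self.seed = epochs, lr, seed
        self.net: _FcnnNet | None = None

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if not self.interactions:
            return X
        iu = np.triu_indices(X.shape[1], k=1)
        pairs = X[:, iu[0]] * X[:, iu[1]]
        return np.concatenate([X, pairs], axis=1)

    def fit(self, X, y):
        y = _check_labels(y)
        feats = self._features(X)
        rng = np.random.default_rng(self.seed)
        self.net = _FcnnNet(feats.shape[1], self.hidden, self.dropout, rng)
        opt = Adam(self.net.parameters(), lr=self.lr)
        self.net.train()
        for _epoch in range(self.epochs):
            logits = self.net(Tensor(feats))
            if self.loss == "bce":
                loss = bce_with_logits(logits, y.reshape(-1, 1))
            else:
                loss = _focal_loss(logits, y.reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss diverged at epoch {_epoch}: {loss.data}")
            self.net.zero_grad()
            loss.backward()
            opt.step()
        self.net.eval()
        return self

    def predict_proba(self, X):
        if self.net is None:
            raise RuntimeError("model is not fitted")
        self.net.eval()
        logits = self.net(Tensor(self._features(X)))
        return logits.sigmoid().data.ravel()


class M4FcnnInteractions(M3Fcnn):
    """FCNN whose input is augmented with all pairwise feature products."""

    interactions = True


@dataclass(frozen=True)
class CnnSpec:
    """Width/depth/dropout knobs of the downscaled 3D CNN."""

    in_channels: int = 2
    stem_width: int = 8
    block_width: int = 16
    head_width: int = 32
    n_blocks: int = 1
    expand: int = 2
    dropout: float = 0.2
    loss: str = "bce"
    epochs: int = 30
    batch_size: int = 16
    lr: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if self.in_channels not in (2, 3, 4):
            raise ValueError("CNN input must stack 2-4 channels")
        if self.loss not in ("bce", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")


class _CnnNet(Module):
    def __init__(self, spec: CnnSpec, rng: np.random.Generator):
        super().__init__()
        self.stem = self._child(Conv3d(spec.in_channels, spec.stem_width, 3, rng,
                                       stride=2, padding=1))
        blocks = [MBConv3d(spec.stem_width, spec.block_width, rng,
                           expand=spec.expand, stride=2)]
        for _ in range(spec.n_blocks - 1):
            blocks.append(MBConv3d(spec.block_width, spec.block_width, rng,
                                   expand=spec.expand, stride=1))
        self.blocks = [self._child(b) for b in blocks]
        self.head_conv = self._child(Conv3d(spec.block_width, spec.head_width, 1, rng))
        self.dropout = self._child(Dropout(spec.dropout, rng))
        self.head = self._child(Dense(spec.head_width, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem(x).swish()
        for block in self.blocks:
            h = block(h)
        h = self.head_conv(h).swish()
        h = h.mean(axis=(2, 3, 4))
        h = self.dropout(h)
        return self.head(h)


class CnnModel(OutcomeModel):
    """Downscaled EfficientNet-style 3D CNN (M5: PET+CT; M6: +GTVp; M7: +GTVn).

    Inputs are channel-stacked preprocessed volumes of shape (N, C, D, H, W)
    with PET and CT scaled to [0, 1] and optional binary mask channels.
    """

    def __init__(self, spec: CnnSpec = CnnSpec()):
        self.spec = spec
        self.net: _CnnNet | None = None

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 5:
            raise ValueError("CNN input must be (N, C, D, H, W)")
        if X.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} channels, got {X.shape[1]}")
        return X

    def fit(self, X, y):
        X = self._check_input(X)
        y = _check_labels(y)
        rng = np.random.default_rng(self.spec.seed)
        self.net = _CnnNet(self.spec, rng)
        opt = Adam(self.net.parameters(), lr=self.spec.lr)
        self.net.train()
        n = X.shape[0]
        for epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                logits = self.net(Tensor(X[idx]))
                if self.spec.loss == "bce":
                    loss = bce_with_logits(logits, y[idx].reshape(-1, 1))
                else:
                    loss = _focal_loss(logits, y[idx].reshape(-1, 1))
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"CNN loss diverged at epoch {epoch}: {loss.data}")
                self.net.zero_grad()
                loss.backward()
                opt.step()
        self.net.eval()
        return self

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Probability Tensor for one (or more) inputs; used for saliency."""
        if self.net is None:
            raise RuntimeError("model is not fitted")
        self.net.eval()
        return self.net(x).sigmoid()

    def predict_proba(self, X):
        X = self._check_input(X)
        if self.net is None:
            raise RuntimeError("model is not fitted")
        self.net.eval()
        out = []
        for start in range(0, X.shape[0], self.spec.batch_size):
            logits = self.net(Tensor(X[start:start + self.spec.batch_size]))
            out.append(logits.sigmoid().data.ravel())
        return np.concatenate(out)


_MODEL_CLASSES = {
    "M1": M1Logistic, "M2": M2Forest, "M3": M3Fcnn, "M4": M4FcnnInteractions,
}


def make_model(spec: ModelSpec) -> OutcomeModel:
    """Instantiate a model from its declarative spec."""
    if spec.model_id in _MODEL_CLASSES:
        return _MODEL_CLASSES[spec.model_id](**spec.hyperparameters)
    channels = {"M5": 2, "M6": 3, "M7": 4}[spec.model_id]
    params = dict(spec.hyperparameters)
    params.setdefault("in_channels", channels)
    return CnnModel(CnnSpec(**params))


def weighted_score(val_auc: float, val_mcc: float, val_f1_c1: float,
                   val_f1_c0: float, train_f1_c1: float,
                   weights=None) -> float:
    """Weighted mean of the five tuning components (equal weights default)."""
    components = np.array([val_auc, val_mcc, val_f1_c1, val_f1_c0, train_f1_c1],
                          dtype=np.float64)
    if np.any((components < 0) | (components > 1)):
        raise ValueError("score components must lie in [0, 1]")
    if weights is None:
        weights = np.full(5, 0.2)
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (5,):
            raise ValueError("need exactly five weights")
        total = weights.sum()
        if not np.isclose(total, 1.0):
            warnings.warn("weights do not sum to 1; normalizing", stacklevel=2)
            weights = weights / total
    return float(components @ weights)
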