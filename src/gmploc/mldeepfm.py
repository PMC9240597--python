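"""Multi-label DeepFM classifier with a thresholded exponential
ranking loss.

Two components are trained in parallel on the same dense feature
vector x (the flattened 20x20 PSSM composition by default) and their
K-dimensional outputs are summed:

    y_hat = y_FM + y_Deep

* FM component: a factorization machine layer computes the first-order
  term sum_i w_i x_i and, per latent factor f, the pooled second-order
  term 0.5 * [(sum_i V_if x_i)^2 - sum_i V_if^2 x_i^2]; the dense head
  maps the concatenation [linear, pooled_1..k] together with a
  first-order bypass of the raw features (so each label has its own
  first-order weights, as in a multi-output FM) to K scores. Summing
  the emission alone reproduces the classic FM value
  sum_i w_i x_i + sum_{i<j} <v_i, v_j> x_i x_j exactly.
* Deep component: a ReLU multilayer perceptron (default widths
  256/128/64/32 with dropout) whose final linear layer emits K raw
  scores with no activation, so scores can be negative.

Training minimizes, per sample with relevant label set R and
irrelevant set I and threshold y0:

    log( 1 + sum_{k in I, r in R} e^{s_k - s_r}
           + sum_{k in I} e^{s_k - y0} + sum_{r in R} e^{y0 - s_r} )

summed over the batch. The leading 1 (``plus_one``) bounds the loss
below by 0; the literal form without it is available. Predicted label
sets are {k : s_k > y0}, falling back to the top-scoring label when
empty (every protein has at least one location).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "LossConfig", "ClassifierConfig", "MLDeepFM", "FMLayer",
    "fm_interaction", "fm_forward", "deep_forward", "predict_scores",
    "decide_labels", "multilabel_loss", "train_mldeepfm",
    "save_model", "load_model",
]

_NEG_INF = -np.inf


@dataclass
class LossConfig:
    y0: float = 0.0
    plus_one: bool = True
    reduction: str = "sum"   # "sum" (as printed) or "mean"

    def __post_init__(self):
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


@dataclass
class ClassifierConfig:
    n_features: int
    n_labels: int = 14
    k_lat: int = 8
    hidden: tuple[int, ...] = (256, 128, 64, 32)
    dropout: float = 0.5
    include_fm: bool = True
    include_deep: bool = True
    epochs: int = 1000
    batch_size: int = 512
    learning_rate: float = 1e-4
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if not (self.include_fm or self.include_deep):
            raise ValueError("at least one of the FM and Deep components is required")


class FMLayer(nn.Layer):
    """Emits [first-order scalar, per-factor pooled pairwise terms]."""

    def __init__(self, n: int, k_lat: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 0.1, size=n)
        self.V = rng.normal(0.0, 0.1, size=(n, k_lat))
        self.dw = np.zeros_like(self.w)
        self.dV = np.zeros_like(self.V)

    def params(self):
        return [self.w, self.V]

    def grads(self):
        return [self.dw, self.dV]

    def forward(self, x, train=False):
        self._x = x
        self._s = x @ self.V                       # (B, k)
        linear = x @ self.w                        # (B,)
        pooled = 0.5 * (self._s ** 2 - (x ** 2) @ (self.V ** 2))
        return np.concatenate([linear[:, None], pooled], axis=1)

    def backward(self, grad_out):
        x, s, V = self._x, self._s, self.V
        d_lin = grad_out[:, 0]                     # (B,)
        d_pool = grad_out[:, 1:]                   # (B, k)
        self.dw[...] = x.T @ d_lin
        ds = d_pool * s
        self.dV[...] = x.T @ ds - ((x ** 2).T @ d_pool) * V
        dx = d_lin[:, None] * self.w[None, :]
        dx += ds @ V.T
        dx -= x * (d_pool @ (V ** 2).T)
        return dx


def fm_interaction(x: np.ndarray, w: np.ndarray, V: np.ndarray) -> float:
    """Classic FM value via the O(n*k) pooled identity."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    V = np.asarray(V, dtype=float)
    if x.shape != w.shape or V.shape[0] != x.shape[0]:
        raise ValueError("shape mismatch between x, w and V")
    s = x @ V
    pairwise = 0.5 * float((s ** 2 - (x ** 2) @ (V ** 2)).sum())
    return float(w @ x) + pairwise


class MLDeepFM:
    """Parallel FM + Deep components whose score vectors are summed."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n, K = config.n_features, config.n_labels
        # head input = [FM-layer emission, raw features]: the bypass gives
        # each label its own first-order weights (multi-output FM)
        self.fm_layer = FMLayer(n, config.k_lat, rng) if config.include_fm else None
        self.fm_head = (nn.Dense(1 + config.k_lat + n, K, rng)
                        if config.include_fm else None)
        if config.include_deep:
            layers: list[nn.Layer] = []
            widths = (n,) + tuple(config.hidden)
            for a, b in zip(widths[:-1], widths[1:]):
                layers += [nn.Dense(a, b, rng), nn.ReLU()]
                if config.dropout > 0:
                    layers.append(nn.Dropout(config.dropout, rng))
            layers.append(nn.Dense(widths[-1], K, rng))  # linear head, no activation
            self.deep = nn.Sequential(*layers)
        else:
            self.deep = None

    # -- forward -----------------------------------------------------
    def fm_scores(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.fm_layer is None:
            return np.zeros((x.shape[0], self.config.n_labels))
        emission = self.fm_layer.forward(x, train)
        return self.fm_head.forward(np.concatenate([emission, x], axis=1), train)

    def deep_scores(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.deep is None:
            return np.zeros((x.shape[0], self.config.n_labels))
        return self.deep.forward(x, train=train)

    def scores(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.fm_scores(x, train) + self.deep_scores(x, train)

    # -- backward ----------------------------------------------------
    def backward(self, d_scores: np.ndarray) -> None:
        if self.fm_layer is not None:
            d_head_in = self.fm_head.backward(d_scores)
            self.fm_layer.backward(d_head_in[:, :1 + self.config.k_lat])
        if self.deep is not None:
            self.deep.backward(d_scores)

    def params(self):
        out = []
        if self.fm_layer is not None:
            out += self.fm_layer.params() + self.fm_head.params()
        if self.deep is not None:
            out += self.deep.params()
        return out

    def grads(self):
        out = []
        if self.fm_layer is not None:
            out += self.fm_layer.grads() + self.fm_head.grads()
        if self.deep is not None:
            out += self.deep.grads()
        return out


def fm_forward(x: np.ndarray, model: MLDeepFM) -> np.ndarray:
    return model.fm_scores(np.atleast_2d(np.asarray(x, dtype=float)))


def deep_forward(x: np.ndarray, model: MLDeepFM) -> np.ndarray:
    return model.deep_scores(np.atleast_2d(np.asarray(x, dtype=float)))


def predict_scores(x: np.ndarray, model: MLDeepFM) -> np.ndarray:
    return model.scores(x)


def decide_labels(scores: np.ndarray, y0: float = 0.0) -> np.ndarray:
    """Binary decisions {k : s_k > y0}; empty rows fall back to the
    top-scoring label (lowest index on ties)."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    pred = (s > y0).astype(int)
    empty = pred.sum(axis=1) == 0
    if empty.any():
        top = s[empty].argmax(axis=1)  # argmax takes the lowest index on ties
        pred[np.flatnonzero(empty), top] = 1
    return pred if np.asarray(scores).ndim > 1 else pred[0]


def _row_logsumexp(a: np.ndarray) -> np.ndarray:
    """logsumexp over the last axis; rows of all -inf give -inf."""
    m = a.max(axis=-1)
    safe_m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = safe_m + np.log(np.exp(a - safe_m[..., None]).sum(axis=-1))
    return np.where(np.isfinite(m), out, _NEG_INF)


def _loss_terms(scores: np.ndarray, labels: np.ndarray, cfg: LossConfig):
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.atleast_2d(np.asarray(labels, dtype=int))
    if s.shape != y.shape:
        raise ValueError("scores and labels shapes differ")
    if (y.sum(axis=1) == 0).any():
        raise ValueError("every sample must have at least one relevant label")
    lse_i = _row_logsumexp(np.where(y == 0, s, _NEG_INF))     # log sum_I e^{s}
    lse_nr = _row_logsumexp(np.where(y == 1, -s, _NEG_INF))   # log sum_R e^{-s}
    parts = [lse_i + lse_nr, lse_i - cfg.y0, cfg.y0 + lse_nr]
    if cfg.plus_one:
        parts.append(np.zeros_like(lse_i))
    per_sample = _row_logsumexp(np.stack(parts, axis=-1))
    return s, y, lse_i, lse_nr, per_sample


def multilabel_loss(scores: np.ndarray, labels: np.ndarray,
                    cfg: LossConfig | None = None) -> float:
    """Thresholded exponential ranking loss, reduced over the batch."""
    cfg = cfg or LossConfig()
    *_, per_sample = _loss_terms(scores, labels, cfg)
    total = float(per_sample.sum())
    return total / per_sample.shape[0] if cfg.reduction == "mean" else total


def multilabel_loss_grad(scores: np.ndarray, labels: np.ndarray,
                         cfg: LossConfig | None = None) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to the scores."""
    cfg = cfg or LossConfig()
    s, y, lse_i, lse_nr, per_sample = _loss_terms(scores, labels, cfg)
    M = per_sample[:, None]
    with np.errstate(over="ignore"):
        g_irr = np.exp(s + lse_nr[:, None] - M) + np.exp(s - cfg.y0 - M)
        g_rel = -(np.exp(lse_i[:, None] - s - M) + np.exp(cfg.y0 - s - M))
    grad = np.where(y == 0, g_irr, g_rel)
    total = float(per_sample.sum())
    if cfg.reduction == "mean":
        return total / s.shape[0], grad / s.shape[0]
    return total, grad


def train_mldeepfm(features: np.ndarray, labels: np.ndarray,
                   config: ClassifierConfig) -> tuple[MLDeepFM, list[float]]:
    """Joint Adam training of both components on the ranking loss.

    Returns the model and a per-epoch loss trace (mean per-sample
    loss, evaluated on the training batches as seen)."""
    X = np.asarray(features, dtype=float)
    Y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty (N, n) matrix")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and labels disagree on N")
    model = MLDeepFM(config)
    opt = nn.Adam(model.params(), model.grads(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    batch = min(config.batch_size, n)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            scores = model.scores(X[idx], train=True)
            loss, grad = multilabel_loss_grad(scores, Y[idx], config.loss)
            epoch_loss += loss if config.loss.reduction == "sum" else loss * len(idx)
            model.backward(grad)
            opt.step()
        trace.append(epoch_loss / n)
    return model, trace


def save_model(model: MLDeepFM, path: str | Path,
               label_names: list[str] | None = None,
               loss_trace: list[float] | None = None) -> None:
    """NPZ checkpoint of all parameter arrays with a JSON sidecar
    (architecture, seed, label vocabulary)."""
    path = Path(path)
    np.savez(path, *[np.asarray(p) for p in model.params()])
    cfg = asdict(model.config)
    cfg["hidden"] = list(model.config.hidden)
    sidecar = {"config": cfg}
    if label_names is not None:
        sidecar["label_names"] = list(label_names)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if loss_trace is not None:
        trace_path = path.with_suffix(".loss.csv")
        trace_path.write_text("epoch,loss\n" + "\n".join(
            f"{i},{v}" for i, v in enumerate(loss_trace)) + "\n")


def load_model(path: str | Path) -> tuple[MLDeepFM, list[str] | None]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["config"])
    cfg_d["hidden"] = tuple(cfg_d["hidden"])
    cfg_d["loss"] = LossConfig(**cfg_d["loss"])
    model = MLDeepFM(ClassifierConfig(**cfg_d))
    arrays = np.load(path)
    for p, key in zip(model.params(), arrays.files, strict=True):
        p[...] = arrays[key]
    return model, sidecar.get("label_names")
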