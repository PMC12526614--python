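"""Binary instability classifiers: an LSTM sequence network and an RBF-SVM.

The LSTM cell follows the standard gated recurrence: input, forget and output
gates squashed to (0, 1) by sigmoids, a tanh input node in (-1, 1), the cell
state C_t = F_t*C_{t-1} + X_t*Ctilde_t and hidden state H_t = Y_t*tanh(C_t)
(so |H_t| < 1 componentwise). The final hidden state feeds a fully connected
layer to two logits and a softmax giving P(KI). Forward pass, backpropagation
through time and the Adam optimizer are implemented directly on numpy arrays;
gradients are verified against numerical differentiation in the test suite.

The SVM is a soft-margin classifier with the Gaussian radial basis kernel
k(u1, u2) = exp(-gamma * ||u1 - u2||^2) on flattened (T*F,) sequences, trained
by Sequential Minimal Optimization (scikit-learn's libsvm backend, KKT
tolerance 1e-3). gamma defaults to the variance-scaled 1/(T*F*var), C to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from sklearn.svm import SVC

from .errors import FeatureSetMismatchError, ParameterError
from .features import LabeledDataset

DEFAULT_N_STEPS = 20


@dataclass
class TrainConfig:
    """Training hyperparameters (small-data defaults, fully logged)."""

    hidden: int = 32
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    split_fraction: float = 0.8
    seed: int = 0
    class_weight: bool = False
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError(
                f"split_fraction {self.split_fraction} outside (0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic


@dataclass
class LSTMParams:
    """All weights of the network, one array per gate / node / output layer.

    Shapes: W_u* (m, h) input-to-gate, W_h* (h, h) hidden-to-gate, b_* (h,);
    W_fc (h, 2), b_fc (2,) for the fully connected output layer.
    """

    W_ui: np.ndarray
    W_hi: np.ndarray
    b_i: np.ndarray
    W_uf: np.ndarray
    W_hf: np.ndarray
    b_f: np.ndarray
    W_uo: np.ndarray
    W_ho: np.ndarray
    b_o: np.ndarray
    W_uc: np.ndarray
    W_hc: np.ndarray
    b_c: np.ndarray
    W_fc: np.ndarray
    b_fc: np.ndarray

    @property
    def m(self) -> int:
        return self.W_ui.shape[0]

    @property
    def h(self) -> int:
        return self.W_ui.shape[1]

    def names(self) -> list[str]:
        return [f.name for f in dc_fields(self)]

    @classmethod
    def init(cls, m: int, h: int, rng: np.random.Generator) -> "LSTMParams":
        ku, kh = 1.0 / np.sqrt(m), 1.0 / np.sqrt(h)
        def wu(): return rng.uniform(-ku, ku, size=(m, h))
        def wh(): return rng.uniform(-kh, kh, size=(h, h))
        zeros = lambda n=h: np.zeros(n)
        return cls(
            W_ui=wu(), W_hi=wh(), b_i=zeros(),
            W_uf=wu(), W_hf=wh(), b_f=np.ones(h),  # open forget gate at init
            W_uo=wu(), W_ho=wh(), b_o=zeros(),
            W_uc=wu(), W_hc=wh(), b_c=zeros(),
            W_fc=rng.uniform(-kh, kh, size=(h, 2)), b_fc=np.zeros(2))

    @classmethod
    def zeros(cls, m: int, h: int) -> "LSTMParams":
        z = lambda *s: np.zeros(s)
        return cls(W_ui=z(m, h), W_hi=z(h, h), b_i=z(h),
                   W_uf=z(m, h), W_hf=z(h, h), b_f=z(h),
                   W_uo=z(m, h), W_ho=z(h, h), b_o=z(h),
                   W_uc=z(m, h), W_hc=z(h, h), b_c=z(h),
                   W_fc=z(h, 2), b_fc=z(2))


@dataclass
class LSTMState:
    """Hidden state H in (-1, 1) componentwise and cell state C."""

    H: np.ndarray
    C: np.ndarray


def lstm_cell_step(U_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM cell update for a batch row (k, m) and state (k, h)."""
    U_t = np.atleast_2d(np.asarray(U_t, dtype=float))
    H, C = np.atleast_2d(state.H), np.atleast_2d(state.C)
    if U_t.shape[1] != params.m:
        raise ParameterError(f"input width {U_t.shape[1]} != params.m {params.m}")
    i = _sigmoid(U_t @ params.W_ui + H @ params.W_hi + params.b_i)
    f = _sigmoid(U_t @ params.W_uf + H @ params.W_hf + params.b_f)
    o = _sigmoid(U_t @ params.W_uo + H @ params.W_ho + params.b_o)
    g = np.tanh(U_t @ params.W_uc + H @ params.W_hc + params.b_c)
    C_new = f * C + i * g
    H_new = o * np.tanh(C_new)
    return LSTMState(H=H_new, C=C_new)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_full(X: np.ndarray, params: LSTMParams):
    """Unrolled forward over (k, T, m) with per-step caches for BPTT."""
    k, T, m = X.shape
    H = np.zeros((k, params.h))
    C = np.zeros((k, params.h))
    caches = []
    for t in range(T):
        U = X[:, t, :]
        i = _sigmoid(U @ params.W_ui + H @ params.W_hi + params.b_i)
        f = _sigmoid(U @ params.W_uf + H @ params.W_hf + params.b_f)
        o = _sigmoid(U @ params.W_uo + H @ params.W_ho + params.b_o)
        g = np.tanh(U @ params.W_uc + H @ params.W_hc + params.b_c)
        C_new = f * C + i * g
        tC = np.tanh(C_new)
        H_new = o * tC
        caches.append((U, H, C, i, f, o, g, tC))
        H, C = H_new, C_new
    logits = H @ params.W_fc + params.b_fc
    return logits, _softmax(logits), H, caches


def lstm_forward(sequence: np.ndarray, params: LSTMParams,
                 n_steps: int = DEFAULT_N_STEPS) -> tuple[np.ndarray, np.ndarray]:
    """Full unroll from zero state; returns (P(KI), logits).

    Accepts one (T, m) sequence or a batch (k, T, m); T must equal
    ``n_steps`` (20, the fixed cycle length).
    """
    X = np.asarray(sequence, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1] != n_steps:
        raise ParameterError(f"sequence length {X.shape[1]} != required {n_steps}")
    logits, probs, _, _ = _forward_full(X, params)
    score = probs[:, 1]
    if single:
        return float(score[0]), logits[0]
    return score, logits


def _loss_and_grads(params: LSTMParams, X: np.ndarray, y: np.ndarray,
                    sample_weight: np.ndarray | None = None):
    """Weighted softmax cross-entropy and analytic gradients via BPTT."""
    k = X.shape[0]
    w = np.ones(k) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    wsum = w.sum()
    logits, probs, H_T, caches = _forward_full(X, params)
    p_true = probs[np.arange(k), y]
    loss = float(-(w * np.log(np.maximum(p_true, 1e-300))).sum() / wsum)

    grads = LSTMParams.zeros(params.m, params.h)
    dlogits = probs.copy()
    dlogits[np.arange(k), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    grads.W_fc += H_T.T @ dlogits
    grads.b_fc += dlogits.sum(axis=0)
    dH = dlogits @ params.W_fc.T
    dC = np.zeros_like(dH)
    for U, H_prev, C_prev, i, f, o, g, tC in reversed(caches):
        do = dH * tC
        dC = dC + dH * o * (1.0 - tC * tC)
        di = dC * g
        dg = dC * i
        df = dC * C_prev
        dC_prev = dC * f
        da_i = di * i * (1.0 - i)
        da_f = df * f * (1.0 - f)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g * g)
        grads.W_ui += U.T @ da_i; grads.W_hi += H_prev.T @ da_i; grads.b_i += da_i.sum(0)
        grads.W_uf += U.T @ da_f; grads.W_hf += H_prev.T @ da_f; grads.b_f += da_f.sum(0)
        grads.W_uo += U.T @ da_o; grads.W_ho += H_prev.T @ da_o; grads.b_o += da_o.sum(0)
        grads.W_uc += U.T @ da_g; grads.W_hc += H_prev.T @ da_g; grads.b_c += da_g.sum(0)
        dH = (da_i @ params.W_hi.T + da_f @ params.W_hf.T
              + da_o @ params.W_ho.T + da_g @ params.W_hc.T)
        dC = dC_prev
    return loss, grads


class _Adam:
    def __init__(self, params: LSTMParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(getattr(params, n)) for n in params.names()}
        self.v = {n: np.zeros_like(getattr(params, n)) for n in params.names()}

    def step(self, params: LSTMParams, grads: LSTMParams) -> None:
        self.t += 1
        for n in params.names():
            g = getattr(grads, n)
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1 ** self.t)
            vhat = self.v[n] / (1 - self.b2 ** self.t)
            getattr(params, n)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class LSTMClassifier:
    """A trained LSTM with its loss trace and the feature ids it expects."""

    params: LSTMParams
    feature_ids: tuple[int, ...]
    n_steps: int
    loss_trace: np.ndarray
    config: TrainConfig


def _class_weights(y: np.ndarray) -> np.ndarray:
    n = y.size
    n_pos = int(y.sum())
    w = np.where(y == 1, n / (2.0 * max(n_pos, 1)), n / (2.0 * max(n - n_pos, 1)))
    return w


def train_lstm(train: LabeledDataset, cfg: TrainConfig | None = None) -> LSTMClassifier:
    """Mini-batch Adam on softmax cross-entropy; deterministic given cfg.seed."""
    cfg = cfg or TrainConfig()
    y = train.y
    if np.unique(y).size < 2:
        raise ParameterError("training data contains a single class")
    X = train.X
    k, T, m = X.shape
    rng = np.random.default_rng(cfg.seed)
    params = LSTMParams.init(m, cfg.hidden, rng)
    opt = _Adam(params, cfg.learning_rate)
    weights = _class_weights(y) if cfg.class_weight else None
    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(k)
        losses = []
        for start in range(0, k, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            wb = None if weights is None else weights[idx]
            loss, grads = _loss_and_grads(params, X[idx], y[idx], wb)
            opt.step(params, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return LSTMClassifier(params=params, feature_ids=tuple(train.feature_ids),
                          n_steps=T, loss_trace=np.asarray(trace), config=cfg)


@dataclass
class SVMModel:
    """RBF-kernel SVM on flattened sequences; wraps the fitted SMO solution."""

    svc: SVC
    feature_ids: tuple[int, ...]
    n_steps: int
    gamma: float
    C: float
    config: TrainConfig

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        return self.svc.dual_coef_

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])


def train_svm(train: LabeledDataset, cfg: TrainConfig | None = None) -> SVMModel:
    """Soft-margin RBF SVM via SMO to KKT tolerance 1e-3."""
    cfg = cfg or TrainConfig()
    y = train.y
    if np.unique(y).size < 2:
        raise ParameterError("training data contains a single class")
    Xf = train.X.reshape(train.n, -1)
    svc = SVC(C=cfg.svm_c, kernel="rbf", gamma=cfg.svm_gamma, tol=1e-3,
              class_weight="balanced" if cfg.class_weight else None)
    svc.fit(Xf, y)
    gamma = svc._gamma if hasattr(svc, "_gamma") else (
        1.0 / (Xf.shape[1] * Xf.var()) if cfg.svm_gamma == "scale" else float(cfg.svm_gamma))
    return SVMModel(svc=svc, feature_ids=tuple(train.feature_ids),
                    n_steps=train.X.shape[1], gamma=float(gamma),
                    C=float(cfg.svm_c), config=cfg)


def predict(model, data: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Scores in [0, 1] (P(KI) for LSTM, logistic-linked margin for SVM)
    and hard labels (score >= 0.5 / margin >= 0)."""
    if tuple(data.feature_ids) != tuple(model.feature_ids):
        raise FeatureSetMismatchError(
            f"model expects feature ids {model.feature_ids}, "
            f"data has {data.feature_ids}")
    if isinstance(model, LSTMClassifier):
        scores, _ = lstm_forward(data.X, model.params, n_steps=model.n_steps)
        return np.asarray(scores), (np.asarray(scores) >= 0.5).astype(int)
    if isinstance(model, SVMModel):
        margins = model.svc.decision_function(data.X.reshape(data.n, -1))
        return _sigmoid(margins), (margins >= 0).astype(int)
    raise ParameterError(f"unknown model type {type(model).__name__}")
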