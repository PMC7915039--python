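"""Per-subject secure-grasp detectors and their evaluation.

Two detectors are implemented:

* a feedforward network with one hidden layer of 10 tanh units and a
  logistic output, trained on the binary cross-entropy with Moller's
  scaled conjugate gradient (SCG) — conjugate directions, a
  finite-difference Hessian-vector product, and a Levenberg-Marquardt
  scaling parameter in place of a line search — with early stopping on
  the validation split;
* an analytical force-equilibrium rule for precision pinch: secure iff
  the index and thumb force voltages are within 10 % of each other and
  both exceed 10 % of full-scale output.  The rule has no analogue for
  tri-pod or whole-hand grips, where thumb opposition is too weak for
  voltage cancellation.

Evaluation reports cross-entropy, percent classification error and the
two mean-squared errors (continuous and rounded output) per data split,
plus per-grip true-positive rates on the test rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .labeling import LabeledDataset, SPLITS
from .synth import Grip, V_MAX

__all__ = [
    "TrainConfig",
    "AnnModel",
    "EvaluationReport",
    "train_ann",
    "predict",
    "round_output",
    "analytical_pinch_detect",
    "evaluate",
    "cross_entropy",
]

_EPS = 1e-12  # clamp for log() stability; outputs are reported unclamped


@dataclass
class TrainConfig:
    """SCG training hyperparameters (Moller defaults)."""

    n_hidden: int = 10
    max_iter: int = 1000
    max_val_fail: int = 6      # consecutive validation increases tolerated
    sigma: float = 5e-5        # finite-difference step scale
    lambda0: float = 5e-7      # initial LM scaling parameter
    init: str = "uniform"      # "uniform" in [-init_scale, init_scale]
    init_scale: float = 0.5
    seed: int = 0
    grad_tol: float = 1e-8


@dataclass
class AnnModel:
    """Weights, input scaling and training trace of the grasp detector."""

    W1: np.ndarray           # (n_hidden, n_inputs)
    b1: np.ndarray           # (n_hidden,)
    W2: np.ndarray           # (n_hidden,)
    b2: float
    x_lo: np.ndarray         # per-channel affine map to [-1, 1]
    x_hi: np.ndarray
    config: TrainConfig
    trace: dict[str, list[float]] = field(default_factory=dict)
    stop_iteration: int = 0
    stop_reason: str = ""

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = self.x_hi - self.x_lo
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.x_lo) / span - 1.0

    def to_json(self) -> str:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2,
            "x_lo": self.x_lo.tolist(), "x_hi": self.x_hi.tolist(),
            "config": vars(self.config), "trace": self.trace,
            "stop_iteration": self.stop_iteration,
            "stop_reason": self.stop_reason,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AnnModel":
        d = json.loads(text)
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=float(d["b2"]),
            x_lo=np.array(d["x_lo"]), x_hi=np.array(d["x_hi"]),
            config=TrainConfig(**d["config"]), trace=d["trace"],
            stop_iteration=d["stop_iteration"],
            stop_reason=d["stop_reason"])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cross_entropy(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy in nats."""
    p = np.clip(y_hat, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _forward(w: np.ndarray, shapes, Xs: np.ndarray):
    W1, b1, W2, b2 = _unpack(w, shapes)
    H = np.tanh(Xs @ W1.T + b1)
    y_hat = _sigmoid(H @ W2 + b2)
    return y_hat, H


def _unpack(w: np.ndarray, shapes):
    h, d = shapes
    i = 0
    W1 = w[i:i + h * d].reshape(h, d); i += h * d
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + h]; i += h
    b2 = w[i]
    return W1, b1, W2, b2


def _loss_grad(w, shapes, Xs, y):
    """Cross-entropy and its analytic gradient (backpropagation)."""
    h, d = shapes
    W1, b1, W2, b2 = _unpack(w, shapes)
    H = np.tanh(Xs @ W1.T + b1)
    z = H @ W2 + b2
    y_hat = _sigmoid(z)
    loss = cross_entropy(y_hat, y)
    n = len(y)
    dz = (y_hat - y) / n                      # logistic + BCE shortcut
    gW2 = H.T @ dz
    gb2 = dz.sum()
    dH = np.outer(dz, W2) * (1.0 - H * H)
    gW1 = dH.T @ Xs
    gb1 = dH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
    return loss, grad


def ann_loss(w, shapes, Xs, y) -> float:
    y_hat, _ = _forward(w, shapes, Xs)
    return cross_entropy(y_hat, y)


def ann_grad(w, shapes, Xs, y) -> np.ndarray:
    return _loss_grad(w, shapes, Xs, y)[1]


def _scg(loss, grad, w0, max_iter, sigma0, lambda0, grad_tol, callback):
    """Moller's scaled conjugate gradient.

    ``callback(it, w, f, success)`` is invoked once per iteration and may
    return True to request a stop (used for early stopping).  Weight
    updates happen only on "successful" iterations (positive comparison
    parameter), so the objective trace is non-increasing.
    """
    w = w0.copy()
    f = loss(w)
    g = grad(w)
    r = -g
    p = r.copy()
    lam, lam_bar = lambda0, 0.0
    success = True
    n = len(w)
    s = np.zeros_like(w)
    delta = 1.0
    for it in range(1, max_iter + 1):
        p2 = float(p @ p)
        if success:
            pnorm = np.sqrt(p2)
            if pnorm < 1e-300:
                return w, f, it, "zero search direction"
            sk = sigma0 / pnorm
            s = (grad(w + sk * p) - g) / sk
            delta = float(p @ s)
        delta_k = delta + (lam - lam_bar) * p2
        if delta_k <= 0:       # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta_k / p2)
            delta_k = -delta_k + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new = loss(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite loss during SCG training")
        comparison = 2.0 * delta_k * (f - f_new) / mu**2
        if comparison >= 0:
            w = w + alpha * p
            f = f_new
            g = grad(w)
            r_new = -g
            lam_bar = 0.0
            success = True
            if it % n == 0:
                p = r_new.copy()        # periodic restart
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta_k * (1.0 - comparison) / p2
        if callback(it, w, f, success):
            return w, f, it, "early stop"
        if success and float(np.abs(r).max()) < grad_tol:
            return w, f, it, "gradient tolerance"
    return w, f, max_iter, "max iterations"


def train_ann(
    dataset: LabeledDataset,
    config: TrainConfig | None = None,
) -> AnnModel:
    """Train the secure-grasp network on a labeled dataset.

    Minimises the training-split cross-entropy with SCG and stops early
    after ``max_val_fail`` consecutive validation-CE increases, returning
    the best-validation weights.  The per-iteration CE on all three
    splits is recorded in the model trace.
    """
    config = config or TrainConfig()
    masks = {s: dataset.rows(split=s) for s in SPLITS}
    X_tr = dataset.features[masks["train"]]
    y_tr = dataset.labels[masks["train"]].astype(float)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")

    x_lo = X_tr.min(axis=0)
    x_hi = X_tr.max(axis=0)
    span = np.where(x_hi - x_lo > 0, x_hi - x_lo, 1.0)

    def scaled(X):
        return 2.0 * (X - x_lo) / span - 1.0

    Xs = {s: scaled(dataset.features[masks[s]]) for s in SPLITS}
    ys = {s: dataset.labels[masks[s]].astype(float) for s in SPLITS}

    h, d = config.n_hidden, X_tr.shape[1]
    shapes = (h, d)
    n_par = h * d + h + h + 1
    rng = np.random.default_rng(config.seed)
    if config.init == "uniform":
        w0 = rng.uniform(-config.init_scale, config.init_scale, n_par)
    elif config.init == "layer_scaled":
        w0 = rng.uniform(-1.0, 1.0, n_par)
        W1, b1, W2, b2 = _unpack(w0, shapes)
        W1 *= 1.0 / np.sqrt(d)
        W2 *= 1.0 / np.sqrt(h)
    else:
        raise ValueError(f"unknown init {config.init!r}")

    trace: dict[str, list[float]] = {s: [] for s in SPLITS}
    trace["success"] = []
    state = {"best_val": np.inf, "best_w": w0.copy(), "best_it": 0,
             "fails": 0}

    def callback(it, w, f_train, success):
        ce_val = (ann_loss(w, shapes, Xs["val"], ys["val"])
                  if len(ys["val"]) else np.inf)
        ce_test = (ann_loss(w, shapes, Xs["test"], ys["test"])
                   if len(ys["test"]) else np.nan)
        trace["train"].append(f_train)
        trace["val"].append(ce_val)
        trace["test"].append(ce_test)
        trace["success"].append(float(success))
        if len(ys["val"]) == 0:
            state["best_w"] = w.copy()
            state["best_it"] = it
            return False
        if not success:        # weights unchanged; don't age the counter
            return False
        if ce_val < state["best_val"] - 1e-15:
            state["best_val"] = ce_val
            state["best_w"] = w.copy()
            state["best_it"] = it
            state["fails"] = 0
        else:
            state["fails"] += 1
        return state["fails"] >= config.max_val_fail

    _, _, stop_it, reason = _scg(
        lambda w: ann_loss(w, shapes, Xs["train"], ys["train"]),
        lambda w: ann_grad(w, shapes, Xs["train"], ys["train"]),
        w0, config.max_iter, config.sigma, config.lambda0,
        config.grad_tol, callback)

    W1, b1, W2, b2 = _unpack(state["best_w"], shapes)
    return AnnModel(
        W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=float(b2),
        x_lo=x_lo, x_hi=x_hi, config=config, trace=trace,
        stop_iteration=state["best_it"] or stop_it, stop_reason=reason)


def predict(model: AnnModel, features: np.ndarray) -> np.ndarray | float:
    """Continuous secure-grasp output in [0, 1] for one frame or a batch."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    H = np.tanh(model.scale(X) @ model.W1.T + model.b1)
    y_hat = _sigmoid(H @ model.W2 + model.b2)
    return float(y_hat[0]) if single else y_hat


def round_output(y_hat):
    """Discretise the continuous output: 1 iff y_hat > 0.5.

    Exactly 0.5 maps to 0 (insecure), the conservative choice for
    feedback triggering.
    """
    return (np.asarray(y_hat) > 0.5).astype(int)


def analytical_pinch_detect(
    frame: np.ndarray,
    rel_tol: float = 0.10,
    floor: float = 0.10,
    v_max: float = V_MAX,
) -> np.ndarray | int:
    """Force-equilibrium secure-grasp test on the index/thumb pair.

    Returns 1 iff both force voltages exceed ``floor * v_max`` and agree
    within ``rel_tol`` of the larger of the two.  Accepts one frame
    (10-vector) or a batch (N, 10); force channels are columns 0 (thumb)
    and 1 (index).
    """
    X = np.asarray(frame, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    v_thumb, v_index = X[:, 0], X[:, 1]
    nonzero = (v_thumb > floor * v_max) & (v_index > floor * v_max)
    balanced = (np.abs(v_index - v_thumb)
                <= rel_tol * np.maximum(v_index, v_thumb))
    out = (nonzero & balanced).astype(int)
    return int(out[0]) if single else out


@dataclass
class EvaluationReport:
    """Detector performance in the layout of the study's summary tables."""

    per_split: dict[str, dict[str, float]]   # CE, PE %, MSEs per split
    tp_ann: dict[str, float | None]          # per-grip TP %, test rows
    tp_analytical: dict[str, float | None]   # equilibrium rule, same rows
    flags: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = [{"split": s, **vals} for s, vals in self.per_split.items()]
        return pd.DataFrame(rows)


def evaluate(
    model: AnnModel,
    dataset: LabeledDataset,
    grip_strata: tuple = (Grip.PINCH, Grip.TRIPOD, Grip.WHOLE_HAND),
) -> EvaluationReport:
    """Compute CE / percent error / MSEs per split and per-grip TP rates.

    True-positive rate per grip = share of secure test frames of that
    grip that the detector also calls secure.  The analytical
    equilibrium rule is scored on the same test rows; strata with no
    secure test frames are reported as None and flagged.
    """
    per_split: dict[str, dict[str, float]] = {}
    for s in SPLITS:
        m = dataset.rows(split=s)
        if m.sum() == 0:
            continue
        y = dataset.labels[m].astype(float)
        y_hat = predict(model, dataset.features[m])
        y_round = round_output(y_hat)
        per_split[s] = {
            "cross_entropy": cross_entropy(y_hat, y),
            "percent_error": float(np.mean(y_round != y) * 100.0),
            "mse_continuous": float(np.mean((y_hat - y) ** 2)),
            "mse_rounded": float(np.mean((y_round - y) ** 2)),
        }

    flags: list[str] = []
    tp_ann: dict[str, float | None] = {}
    tp_analytical: dict[str, float | None] = {}
    for grip in grip_strata:
        grip = Grip(grip)
        m = dataset.rows(split="test", grip=grip)
        secure = m & (dataset.labels == 1)
        n_sec = int(secure.sum())
        if n_sec == 0:
            tp_ann[grip.value] = None
            tp_analytical[grip.value] = None
            flags.append(f"no secure test frames for grip {grip.value}")
            continue
        X = dataset.features[secure]
        tp_ann[grip.value] = float(
            np.mean(round_output(predict(model, X))) * 100.0)
        tp_analytical[grip.value] = float(
            np.mean(analytical_pinch_detect(X)) * 100.0)
    return EvaluationReport(per_split=per_split, tp_ann=tp_ann,
                            tp_analytical=tp_analytical, flags=flags)
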