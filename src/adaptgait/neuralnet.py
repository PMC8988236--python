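"""From-scratch feedforward classifier with SCG batch and GD incremental training.

The intent classifier is a single-hidden-layer network, 102 inputs -> 20 tanh
hidden units -> 5 softmax outputs, trained offline with Moller's scaled
conjugate gradient (SCG) and adapted online with plain full-batch gradient
descent (learning rate 0.01, three epochs per update).  The monitored
"training error" is the mean cross-entropy of the softmax posteriors; both
break clauses (SCG plateau at 0.001 over at most 1000 epochs, GD plateau at
the same precision within its 3 epochs) act on that loss.

Weights and biases are initialized uniformly in ``(-1/sqrt(n_inputs),
+1/sqrt(n_inputs))`` — for the 102-input network that is +/-0.099.

SCG notes: the algorithm estimates curvature along the search direction from
a finite difference of gradients (sigma0 = 1e-4) and regularizes it with a
Levenberg-Marquardt scale lambda (initial 1e-6) that grows on rejected steps
and shrinks on well-modeled ones; accepted steps never increase the loss.
An epoch is one SCG iteration, accepted or not; the plateau clause compares
consecutive *accepted* losses, because a rejected step leaves the loss
unchanged by construction and merely retunes lambda.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .featureset import N_FEATURES, LabeledExample, examples_to_xy
from .signal_io import MODES

__all__ = [
    "WEIGHTS_FORMAT_VERSION",
    "NetworkShape",
    "NetworkWeights",
    "ScgConfig",
    "GdConfig",
    "InitConfig",
    "TrainingDivergedError",
    "WeightsFormatError",
    "init_weights",
    "forward_pass",
    "forward_batch",
    "predict_batch",
    "loss_and_gradient",
    "train_scg",
    "train_gd",
    "save_weights",
    "load_weights",
]

WEIGHTS_FORMAT_VERSION = "1"


class TrainingDivergedError(RuntimeError):
    """Non-finite loss or update during training."""


class WeightsFormatError(ValueError):
    """Weight file is malformed, inconsistent, or of an unsupported version."""


@dataclass(frozen=True)
class NetworkShape:
    """Layer sizes; hidden activation is fixed to tanh."""

    n_inputs: int = N_FEATURES
    n_hidden: int = 20
    n_outputs: int = len(MODES)

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all network dimensions must be >= 1")

    @property
    def n_params(self) -> int:
        return (self.n_inputs + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_outputs


@dataclass
class NetworkWeights:
    """All parameters of the two-layer network plus format metadata.

    ``input_mean``/``input_scale`` hold the per-feature standardization
    fitted from the SCG training set (identity until then); they travel with
    the weights so online prediction and gradient-descent adaptation see the
    same conditioned inputs that batch training saw.
    """

    shape: NetworkShape
    w_hidden: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    w_output: np.ndarray  # (n_hidden, n_outputs)
    b_output: np.ndarray  # (n_outputs,)
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    version: str = WEIGHTS_FORMAT_VERSION

    def __post_init__(self) -> None:
        self.w_hidden = np.asarray(self.w_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_output = np.asarray(self.w_output, dtype=float)
        self.b_output = np.asarray(self.b_output, dtype=float)
        s = self.shape
        if self.input_mean is None:
            self.input_mean = np.zeros(s.n_inputs)
        if self.input_scale is None:
            self.input_scale = np.ones(s.n_inputs)
        self.input_mean = np.asarray(self.input_mean, dtype=float)
        self.input_scale = np.asarray(self.input_scale, dtype=float)
        expected = {
            "w_hidden": (s.n_inputs, s.n_hidden),
            "b_hidden": (s.n_hidden,),
            "w_output": (s.n_hidden, s.n_outputs),
            "b_output": (s.n_outputs,),
            "input_mean": (s.n_inputs,),
            "input_scale": (s.n_inputs,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise WeightsFormatError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise WeightsFormatError(f"{name} contains non-finite values")
        if np.any(self.input_scale <= 0):
            raise WeightsFormatError("input_scale must be strictly positive")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_mean) / self.input_scale

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            shape=self.shape,
            w_hidden=self.w_hidden.copy(),
            b_hidden=self.b_hidden.copy(),
            w_output=self.w_output.copy(),
            b_output=self.b_output.copy(),
            input_mean=self.input_mean.copy(),
            input_scale=self.input_scale.copy(),
            version=self.version,
        )

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.w_hidden.ravel(), self.b_hidden, self.w_output.ravel(), self.b_output]
        )

    @classmethod
    def from_flat(cls, flat: np.ndarray, shape: NetworkShape,
                  version: str = WEIGHTS_FORMAT_VERSION) -> "NetworkWeights":
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (shape.n_params,):
            raise WeightsFormatError(f"flat vector length {flat.size} != {shape.n_params}")
        i = 0
        w1 = flat[i:i + shape.n_inputs * shape.n_hidden].reshape(shape.n_inputs, shape.n_hidden)
        i += w1.size
        b1 = flat[i:i + shape.n_hidden]
        i += b1.size
        w2 = flat[i:i + shape.n_hidden * shape.n_outputs].reshape(shape.n_hidden, shape.n_outputs)
        i += w2.size
        b2 = flat[i:i + shape.n_outputs]
        return cls(shape=shape, w_hidden=w1.copy(), b_hidden=b1.copy(),
                   w_output=w2.copy(), b_output=b2.copy(), version=version)


@dataclass(frozen=True)
class ScgConfig:
    max_epochs: int = 1000
    plateau_precision: float = 1e-3
    plateau_patience: int = 5
    sigma0: float = 1e-4
    lambda0: float = 1e-6
    lambda_max: float = 1e15
    grad_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.plateau_precision <= 0:
            raise ValueError("plateau_precision must be positive")


@dataclass(frozen=True)
class GdConfig:
    learning_rate: float = 0.01
    epochs: int = 3
    plateau_precision: float = 1e-3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class InitConfig:
    """Symmetric uniform initialization with half-width 1/sqrt(n_inputs)."""

    seed: int = 0

    @staticmethod
    def bound(shape: NetworkShape) -> float:
        return 1.0 / math.sqrt(shape.n_inputs)


def init_weights(shape: NetworkShape, cfg: InitConfig) -> NetworkWeights:
    """Draw every weight and bias uniformly from (-b, +b), b = 1/sqrt(n_inputs)."""
    rng = np.random.default_rng(cfg.seed)
    b = InitConfig.bound(shape)
    return NetworkWeights(
        shape=shape,
        w_hidden=rng.uniform(-b, b, size=(shape.n_inputs, shape.n_hidden)),
        b_hidden=rng.uniform(-b, b, size=shape.n_hidden),
        w_output=rng.uniform(-b, b, size=(shape.n_hidden, shape.n_outputs)),
        b_output=rng.uniform(-b, b, size=shape.n_outputs),
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Class posteriors for a batch, shape ``(n, n_outputs)``; rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.shape.n_inputs:
        raise WeightsFormatError(
            f"input has shape {X.shape}, expected (n, {weights.shape.n_inputs})"
        )
    h = np.tanh(weights.standardize(X) @ weights.w_hidden + weights.b_hidden)
    return _softmax(h @ weights.w_output + weights.b_output)


def forward_pass(weights: NetworkWeights, features: np.ndarray) -> tuple[np.ndarray, int]:
    """Posterior scores and argmax class for one feature vector.

    Scores sum to 1; ties break toward the lowest class index.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (weights.shape.n_inputs,):
        raise WeightsFormatError(
            f"feature vector has shape {features.shape}, expected ({weights.shape.n_inputs},)"
        )
    scores = forward_batch(weights, features[None, :])[0]
    return scores, int(np.argmax(scores))


def predict_batch(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Argmax class per row (lowest-index tie-break)."""
    return np.argmax(forward_batch(weights, X), axis=1)


def _as_xy(data, shape: NetworkShape) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        X, y = data
    elif len(data) == 0 or isinstance(data[0], LabeledExample):
        X, y = examples_to_xy(data)
        if X.shape[1] != shape.n_inputs:
            X = np.empty((0, shape.n_inputs)) if X.shape[0] == 0 else X
    else:
        raise TypeError("expected (X, y) arrays or a sequence of LabeledExample")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != shape.n_inputs:
        raise WeightsFormatError(f"design matrix shape {X.shape} incompatible with {shape}")
    if y.shape != (X.shape[0],) or (y.size and (y.min() < 0 or y.max() >= shape.n_outputs)):
        raise ValueError("labels must be integers in [0, n_outputs)")
    return X, y


def loss_and_gradient(
    weights: NetworkWeights, X, y: np.ndarray | None = None
) -> tuple[float, NetworkWeights]:
    """Mean cross-entropy and its analytic gradient (same structure as weights).

    ``X``/``y`` may be a design matrix and integer labels, or ``X`` alone may
    be a sequence of LabeledExample.
    """
    if y is None:
        X, y = _as_xy(X, weights.shape)
    else:
        X, y = _as_xy((X, y), weights.shape)
    n = X.shape[0]
    if n == 0:
        raise ValueError("batch must be non-empty")
    X = weights.standardize(X)
    h = np.tanh(X @ weights.w_hidden + weights.b_hidden)
    p = _softmax(h @ weights.w_output + weights.b_output)
    eps = np.finfo(float).tiny
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))

    dz = p.copy()
    dz[np.arange(n), y] -= 1.0
    dz /= n
    g_w2 = h.T @ dz
    g_b2 = dz.sum(axis=0)
    dh = dz @ weights.w_output.T
    da = dh * (1.0 - h * h)
    g_w1 = X.T @ da
    g_b1 = da.sum(axis=0)
    grad = NetworkWeights(
        shape=weights.shape, w_hidden=g_w1, b_hidden=g_b1,
        w_output=g_w2, b_output=g_b2, version=weights.version,
    )
    return loss, grad


def _loss_only(flat: np.ndarray, shape: NetworkShape, X: np.ndarray, y: np.ndarray) -> float:
    w = NetworkWeights.from_flat(flat, shape)
    h = np.tanh(X @ w.w_hidden + w.b_hidden)
    p = _softmax(h @ w.w_output + w.b_output)
    eps = np.finfo(float).tiny
    return float(-np.mean(np.log(p[np.arange(X.shape[0]), y] + eps)))


def _grad_flat(flat: np.ndarray, shape: NetworkShape, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    w = NetworkWeights.from_flat(flat, shape)
    loss, grad = loss_and_gradient(w, X, y)
    return loss, grad.flatten()


def train_scg(
    train_set,
    shape: NetworkShape | None = None,
    scg_cfg: ScgConfig | None = None,
    init_cfg: InitConfig | None = None,
    initial_weights: NetworkWeights | None = None,
) -> tuple[NetworkWeights, list[float]]:
    """Batch-train with Moller's scaled conjugate gradient.

    ``train_set`` is either a sequence of LabeledExample or an ``(X, y)``
    tuple.  Returns the trained weights and the loss history (entry 0 is the
    pre-training loss; one entry per epoch thereafter).  Training stops at
    ``max_epochs``, on the plateau clause — ``plateau_patience`` consecutive
    accepted epochs each improving by less than ``plateau_precision``,
    checked from the second accepted epoch (a single sub-threshold epoch is
    common mid-run for conjugate-gradient methods and is not yet a plateau)
    — or when the gradient vanishes.
    """
    shape = shape or NetworkShape()
    scg_cfg = scg_cfg or ScgConfig()
    init_cfg = init_cfg or InitConfig()
    X, y = _as_xy(train_set, shape)
    if X.shape[0] == 0:
        raise ValueError("training set must be non-empty")

    # condition the inputs: per-feature z-scoring fitted on the training set,
    # carried with the weights so prediction/adaptation see the same scale
    if initial_weights is not None:
        w = initial_weights.flatten()
        input_mean = initial_weights.input_mean.copy()
        input_scale = initial_weights.input_scale.copy()
    else:
        w = init_weights(shape, init_cfg).flatten()
        input_mean = X.mean(axis=0)
        input_scale = X.std(axis=0)
        input_scale[input_scale < 1e-8] = 1.0
    X = (X - input_mean) / input_scale

    loss, g = _grad_flat(w, shape, X, y)
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite loss at initialization")
    history = [loss]
    r = -g
    p = r.copy()
    success = True
    lam = scg_cfg.lambda0
    lam_bar = 0.0
    last_accepted = loss
    n_accepted = 0
    plateau_run = 0
    delta = 0.0

    for epoch in range(1, scg_cfg.max_epochs + 1):
        p2 = float(p @ p)
        p_norm = math.sqrt(p2)
        if p_norm < scg_cfg.grad_tol:
            break
        if success:
            sigma = scg_cfg.sigma0 / p_norm
            _, g_fwd = _grad_flat(w + sigma * p, shape, X, y)
            s = (g_fwd - (-r)) / sigma  # E'(w + sigma p) - E'(w), E'(w) = -r
            delta = float(p @ s)
        # delta persists across rejected steps, accumulating the lambda
        # increments so that repeated rejections shrink the step size
        delta = delta + (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new = _loss_only(w + alpha * p, shape, X, y)
        if not np.isfinite(loss_new):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        comparison = 2.0 * delta * (loss - loss_new) / (mu * mu) if mu != 0 else -1.0

        if comparison >= 0:  # successful step
            w = w + alpha * p
            loss = loss_new
            _, g_new = _grad_flat(w, shape, X, y)
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if epoch % w.size == 0:
                p = r_new.copy()  # periodic restart along steepest descent
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
            lam += delta * (1.0 - comparison) / p2

        history.append(loss)
        if lam > scg_cfg.lambda_max:
            # trust region collapsed to numerical noise: no step along the
            # current direction can measurably change the loss
            break
        if comparison >= 0:
            n_accepted += 1
            improvement = last_accepted - loss
            last_accepted = loss
            if n_accepted >= 2 and improvement < scg_cfg.plateau_precision:
                plateau_run += 1
                if plateau_run >= scg_cfg.plateau_patience:
                    break
            else:
                plateau_run = 0
        if float(r @ r) < scg_cfg.grad_tol ** 2:
            break

    out = NetworkWeights.from_flat(w, shape)
    out.input_mean = input_mean
    out.input_scale = input_scale
    return out, history


def train_gd(
    weights: NetworkWeights,
    examples,
    cfg: GdConfig | None = None,
) -> NetworkWeights:
    """Full-batch gradient descent from existing weights (online adaptation).

    Performs at most ``cfg.epochs`` steps at the fixed learning rate,
    stopping early if the epoch-over-epoch loss improvement falls below
    ``plateau_precision`` (checked from the second step).  An empty example
    buffer returns the input weights unchanged; a non-finite update raises
    and leaves the caller's weights untouched.
    """
    cfg = cfg or GdConfig()
    if isinstance(examples, tuple):
        X, y = _as_xy(examples, weights.shape)
    else:
        if len(examples) == 0:
            return weights.copy()
        X, y = _as_xy(examples, weights.shape)
    if X.shape[0] == 0:
        return weights.copy()

    X = weights.standardize(X)
    w = weights.flatten()
    prev_loss = None
    for step in range(1, cfg.epochs + 1):
        loss, g = _grad_flat(w, shape=weights.shape, X=X, y=y)
        w_new = w - cfg.learning_rate * g
        if not np.all(np.isfinite(w_new)):
            raise TrainingDivergedError(
                f"non-finite gradient-descent update at step {step}; weights rolled back"
            )
        new_loss = _loss_only(w_new, weights.shape, X, y)
        if not np.isfinite(new_loss):
            raise TrainingDivergedError(
                f"non-finite loss after gradient-descent step {step}; weights rolled back"
            )
        w = w_new
        if prev_loss is not None and step >= 2 and (prev_loss - new_loss) < cfg.plateau_precision:
            break
        prev_loss = new_loss
    out = NetworkWeights.from_flat(w, weights.shape, version=weights.version)
    out.input_mean = weights.input_mean.copy()
    out.input_scale = weights.input_scale.copy()
    return out


def save_weights(weights: NetworkWeights, path: str | Path) -> Path:
    """Write weights to a versioned JSON container (bit-exact round trip)."""
    path = Path(path)
    payload = {
        "format": "adaptgait-weights",
        "version": weights.version,
        "shape": {
            "n_inputs": weights.shape.n_inputs,
            "n_hidden": weights.shape.n_hidden,
            "n_outputs": weights.shape.n_outputs,
        },
        "w_hidden": weights.w_hidden.tolist(),
        "b_hidden": weights.b_hidden.tolist(),
        "w_output": weights.w_output.tolist(),
        "b_output": weights.b_output.tolist(),
        "input_mean": weights.input_mean.tolist(),
        "input_scale": weights.input_scale.tolist(),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload) + "\n")
    return path


def load_weights(path: str | Path) -> NetworkWeights:
    """Load and validate a weight container written by :func:`save_weights`."""
    raw = json.loads(Path(path).read_text())
    if raw.get("format") != "adaptgait-weights":
        raise WeightsFormatError(f"{path}: not an adaptgait weight file")
    if raw.get("version") != WEIGHTS_FORMAT_VERSION:
        raise WeightsFormatError(
            f"{path}: unsupported weights version {raw.get('version')!r}; "
            f"this build reads version {WEIGHTS_FORMAT_VERSION!r}"
        )
    try:
        shape = NetworkShape(**{k: int(v) for k, v in raw["shape"].items()})
    except (KeyError, TypeError) as exc:
        raise WeightsFormatError(f"{path}: malformed shape block ({exc})") from exc
    return NetworkWeights(
        shape=shape,
        w_hidden=np.array(raw["w_hidden"], dtype=float),
        b_hidden=np.array(raw["b_hidden"], dtype=float),
        w_output=np.array(raw["w_output"], dtype=float),
        b_output=np.array(raw["b_output"], dtype=float),
        input_mean=np.array(raw.get("input_mean", np.zeros(shape.n_inputs)), dtype=float),
        input_scale=np.array(raw.get("input_scale", np.ones(shape.n_inputs)), dtype=float),
        version=raw["version"],
    )
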