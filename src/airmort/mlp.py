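"""From-scratch multilayer perceptron with the four classic MATLAB-style trainers.

The network is the textbook feed-forward perceptron: each hidden neuron j
computes an activation value

    a_j = sum_i w_ij x_i + b_j

passes it through tansig / logsig / purelin, and a single output neuron
combines the hidden outputs the same way.  Training minimizes the mean
squared error on the training split while monitoring the validation split;
the run stops when validation MSE has failed to improve for ``patience``
consecutive epochs (or at ``max_epochs``) and the parameters from the best
validation epoch are returned.

Four optimizers are provided, mirroring the toolbox names practitioners
know:

* ``levenberg_marquardt``  — damped Gauss-Newton on the residual Jacobian,
* ``scaled_conjugate_gradient`` — Møller's SCG (no line search),
* ``powell_beale_cg`` — Polak-Ribière CG with Powell-Beale restarts,
* ``bayesian_regularization`` — Levenberg-Marquardt on the regularized
  objective beta*SSE + alpha*SSW with MacKay evidence updates of (alpha, beta).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable

import numpy as np

HIDDEN_SIZE_GRID = (5, 10, 15, 20, 25, 30, 35)
ACTIVATION_NAMES = ("tansig", "logsig", "purelin")
ALGORITHMS = (
    "levenberg_marquardt",
    "scaled_conjugate_gradient",
    "powell_beale_cg",
    "bayesian_regularization",
)


def activation(name: str, alpha):
    """Apply one of the three activation functions to an activation value."""
    alpha = np.asarray(alpha, dtype=float)
    if name == "tansig":
        return np.tanh(alpha)
    if name == "logsig":
        return 1.0 / (1.0 + np.exp(-alpha))
    if name == "purelin":
        return alpha + 0.0
    raise ValueError(f"unknown activation {name!r}")


def _activation_derivative(name: str, out: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation *output* (cheaper than via input)."""
    if name == "tansig":
        return 1.0 - out**2
    if name == "logsig":
        return out * (1.0 - out)
    if name == "purelin":
        return np.ones_like(out)
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class MLPArchitecture:
    """Network shape: inputs, one or two hidden layers, activations, trainer."""

    n_inputs: int
    hidden_sizes: tuple[int, ...] = (5,)
    hidden_activation: str = "tansig"
    output_activation: str = "purelin"
    algorithm: str = "levenberg_marquardt"

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if len(self.hidden_sizes) not in (1, 2):
            raise ValueError("only 1 or 2 hidden layers are supported")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be >= 1")
        for name in (self.hidden_activation, self.output_activation):
            if name not in ACTIVATION_NAMES:
                raise ValueError(f"unknown activation {name!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_sizes, 1)

    @property
    def layer_activations(self) -> tuple[str, ...]:
        return (*(self.hidden_activation,) * len(self.hidden_sizes), self.output_activation)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


@dataclass
class MLPParameters:
    """Fitted weights/biases, one (W, b) pair per layer; W is (fan_in, fan_out)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases layer count mismatch")
        for W, b in zip(self.weights, self.biases):
            if W.shape[1] != b.shape[0]:
                raise ValueError("weight/bias shape mismatch")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError("parameters must be finite")

    @property
    def hidden_weights(self) -> np.ndarray:
        """Input-to-first-hidden weight matrix w_ij (inputs × hidden neurons)."""
        return self.weights[0]

    @property
    def hidden_bias(self) -> np.ndarray:
        return self.biases[0]

    @property
    def output_weights(self) -> np.ndarray:
        """Last-hidden-to-output weights w_jk."""
        return self.weights[-1]

    @property
    def output_bias(self) -> np.ndarray:
        return self.biases[-1]

    def copy(self) -> "MLPParameters":
        return MLPParameters([W.copy() for W in self.weights], [b.copy() for b in self.biases])


def init_parameters(arch: MLPArchitecture, rng: np.random.Generator) -> MLPParameters:
    """Seeded uniform [-0.5, 0.5] initialization scaled by 1/sqrt(fan-in)."""
    sizes = arch.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-0.5, 0.5, size=(fan_in, fan_out)) * scale)
        biases.append(rng.uniform(-0.5, 0.5, size=fan_out) * scale)
    return MLPParameters(weights, biases)


def _forward_trace(params: MLPParameters, arch: MLPArchitecture, X: np.ndarray) -> list[np.ndarray]:
    """Layer outputs [a0=X, a1, ..., aL]; aL has shape (n, 1)."""
    a = np.asarray(X, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != arch.n_inputs:
        raise ValueError(f"expected {arch.n_inputs} inputs, got {a.shape[1]}")
    trace = [a]
    for W, b, act in zip(params.weights, params.biases, arch.layer_activations):
        a = activation(act, a @ W + b)
        trace.append(a)
    return trace


def forward(params: MLPParameters, arch: MLPArchitecture, X: np.ndarray) -> np.ndarray:
    """Network output for each row of X (scaled covariates); returns shape (n,)."""
    return _forward_trace(params, arch, X)[-1][:, 0]


# ---------------------------------------------------------------------------
# parameter vector packing and the output Jacobian


def pack(params: MLPParameters) -> np.ndarray:
    parts = []
    for W, b in zip(params.weights, params.biases):
        parts.append(W.ravel())
        parts.append(b)
    return np.concatenate(parts)


def unpack(theta: np.ndarray, arch: MLPArchitecture) -> MLPParameters:
    sizes = arch.layer_sizes
    weights, biases, pos = [], [], 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
        biases.append(theta[pos : pos + fan_out])
        pos += fan_out
    return MLPParameters(weights, biases)


def output_jacobian(
    params: MLPParameters, arch: MLPArchitecture, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample derivative of the scalar output w.r.t. every parameter.

    Returns (y, J) with y shape (n,) and J shape (n, n_parameters), columns
    ordered as in :func:`pack`.
    """
    trace = _forward_trace(params, arch, X)
    acts = arch.layer_activations
    n = trace[0].shape[0]
    # reverse pass: delta_l = dy/d(preactivation of layer l), shape (n, size_l)
    deltas: list[np.ndarray] = [None] * len(params.weights)
    deltas[-1] = _activation_derivative(acts[-1], trace[-1])
    for l in range(len(params.weights) - 2, -1, -1):
        deltas[l] = (deltas[l + 1] @ params.weights[l + 1].T) * _activation_derivative(acts[l], trace[l + 1])
    blocks = []
    for l, delta in enumerate(deltas):
        a_prev = trace[l]
        # dy/dW_l[i,j] = a_prev[:, i] * delta[:, j]
        blocks.append((a_prev[:, :, None] * delta[:, None, :]).reshape(n, -1))
        blocks.append(delta)
    return trace[-1][:, 0], np.hstack(blocks)


def _mse(params: MLPParameters, arch: MLPArchitecture, X: np.ndarray, y: np.ndarray) -> float:
    r = forward(params, arch, X) - y
    return float(r @ r / len(y))


# ---------------------------------------------------------------------------
# trainers (all operate on the packed parameter vector)


class _EarlyStopper:
    """Best-validation-iterate tracker with a consecutive-failure patience rule."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_val = np.inf
        self.best_theta: np.ndarray | None = None
        self.fails = 0

    def update(self, theta: np.ndarray, val_mse: float) -> bool:
        """Record this epoch; returns True when training should stop."""
        if val_mse < self.best_val:
            self.best_val = val_mse
            self.best_theta = theta.copy()
            self.fails = 0
        else:
            self.fails += 1
        return self.fails >= self.patience


def _train_lm(
    theta: np.ndarray,
    arch: MLPArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    val_mse: Callable[[np.ndarray], float],
    stopper: _EarlyStopper,
    max_epochs: int,
    mu0: float = 1e-3,
    mu_max: float = 1e10,
    regularized: bool = False,
) -> int:
    """Levenberg-Marquardt; with ``regularized`` it becomes Bayesian regularization."""
    n, p = len(y), len(theta)
    mu = mu0
    alpha, beta = (0.01, 1.0) if regularized else (0.0, 1.0)
    eye = np.eye(p)

    def objective(th: np.ndarray, sse: float) -> float:
        return beta * sse + alpha * float(th @ th)

    params = unpack(theta, arch)
    r = forward(params, arch, X) - y
    sse = float(r @ r)
    epoch = 0
    while epoch < max_epochs:
        yhat, J = output_jacobian(unpack(theta, arch), arch, X)
        r = yhat - y
        sse = float(r @ r)
        grad = beta * (J.T @ r) + alpha * theta
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(beta * JtJ + (alpha + mu) * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            theta_new = theta + delta
            r_new = forward(unpack(theta_new, arch), arch, X) - y
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and objective(theta_new, sse_new) < objective(theta, sse):
                theta = theta_new
                sse = sse_new
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break
        if regularized:
            # evidence approximation: effective number of parameters gamma
            H = 2.0 * beta * JtJ + 2.0 * alpha * eye
            try:
                tr_hinv = float(np.trace(np.linalg.inv(H)))
            except np.linalg.LinAlgError:
                tr_hinv = 0.0
            gamma = p - 2.0 * alpha * tr_hinv
            sw = float(theta @ theta)
            if sw > 0 and sse > 0 and 0 < gamma < n:
                alpha = max(gamma / (2.0 * sw), 1e-12)
                beta = max((n - gamma) / (2.0 * sse), 1e-12)
        epoch += 1
        if stopper.update(theta, val_mse(theta)):
            break
    return epoch


def _train_scg(
    theta: np.ndarray,
    arch: MLPArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    val_mse: Callable[[np.ndarray], float],
    stopper: _EarlyStopper,
    max_epochs: int,
) -> int:
    """Møller's scaled conjugate gradient on the training MSE."""
    n = len(y)

    def f_and_g(th: np.ndarray) -> tuple[float, np.ndarray]:
        yhat, J = output_jacobian(unpack(th, arch), arch, X)
        r = yhat - y
        return float(r @ r / n), (2.0 / n) * (J.T @ r)

    sigma0 = 5e-5
    lam, lam_bar = 5e-7, 0.0
    fw, grad = f_and_g(theta)
    r_vec = -grad
    p_vec = r_vec.copy()
    success = True
    restart_every = len(theta)
    epoch = 0
    delta = 1.0
    s = np.zeros_like(theta)
    while epoch < max_epochs:
        p_norm2 = float(p_vec @ p_vec)
        if p_norm2 < 1e-30:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_plus = f_and_g(theta + sigma * p_vec)
            s = (g_plus - (-r_vec)) / sigma
            delta = float(p_vec @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p_vec @ r_vec)
        alpha = mu / delta
        f_new = _mse(unpack(theta + alpha * p_vec, arch), arch, X, y)
        if not np.isfinite(f_new):
            break
        comp = 2.0 * delta * (fw - f_new) / (mu * mu)
        if comp >= 0:
            theta = theta + alpha * p_vec
            fw, grad = f_and_g(theta)
            r_new = -grad
            lam_bar = 0.0
            success = True
            if (epoch + 1) % restart_every == 0:
                p_vec = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r_vec)) / mu
                p_vec = r_new + beta * p_vec
            r_vec = r_new
            if comp >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            epoch += 1
            if stopper.update(theta, val_mse(theta)):
                break
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam += delta * (1.0 - comp) / p_norm2
        if lam > 1e15:
            break
    return epoch


def _train_cgb(
    theta: np.ndarray,
    arch: MLPArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    val_mse: Callable[[np.ndarray], float],
    stopper: _EarlyStopper,
    max_epochs: int,
) -> int:
    """Polak-Ribière conjugate gradient with Powell-Beale restarts.

    Restarts to steepest descent whenever successive gradients lose
    orthogonality (|g_k . g_{k-1}| >= 0.2 |g_k|^2) or the direction stops
    being a descent direction.  Uses a Wolfe line search with backtracking
    fallback.
    """
    from scipy.optimize import line_search

    n = len(y)

    def f(th: np.ndarray) -> float:
        return _mse(unpack(th, arch), arch, X, y)

    def g(th: np.ndarray) -> np.ndarray:
        yhat, J = output_jacobian(unpack(th, arch), arch, X)
        return (2.0 / n) * (J.T @ (yhat - y))

    grad = g(theta)
    direction = -grad
    epoch = 0
    while epoch < max_epochs:
        if float(grad @ grad) < 1e-24:
            break
        if float(direction @ grad) >= 0:  # not a descent direction: restart
            direction = -grad
        alpha = None
        with np.errstate(all="ignore"):
            try:
                ls = line_search(f, g, theta, direction, gfk=grad, maxiter=20)
                alpha = ls[0]
            except Exception:
                alpha = None
        if alpha is None:
            # backtracking on the Armijo condition
            alpha = 1.0
            f0 = f(theta)
            slope = float(grad @ direction)
            for _ in range(30):
                if f(theta + alpha * direction) <= f0 + 1e-4 * alpha * slope:
                    break
                alpha *= 0.5
            else:
                break
        theta_new = theta + alpha * direction
        grad_new = g(theta_new)
        if not np.isfinite(grad_new).all():
            break
        # Powell-Beale restart test
        if abs(float(grad_new @ grad)) >= 0.2 * float(grad_new @ grad_new):
            direction = -grad_new
        else:
            beta_pr = float(grad_new @ (grad_new - grad)) / max(float(grad @ grad), 1e-30)
            direction = -grad_new + max(beta_pr, 0.0) * direction
        theta, grad = theta_new, grad_new
        epoch += 1
        if stopper.update(theta, val_mse(theta)):
            break
    return epoch


_TRAINERS = {
    "levenberg_marquardt": _train_lm,
    "scaled_conjugate_gradient": _train_scg,
    "powell_beale_cg": _train_cgb,
    "bayesian_regularization": lambda *a, **k: _train_lm(*a, regularized=True, **k),
}


@dataclass
class TrainingResult:
    """One training run: fitted parameters plus its split-wise errors."""

    params: MLPParameters | None
    arch: MLPArchitecture
    mse_train: float
    mse_val: float
    epochs_run: int
    seed: int
    mse_test: float = float("nan")
    mape_all: float = float("nan")
    mape_test: float = float("nan")
    failed: bool = False


def train(
    arch: MLPArchitecture,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    max_epochs: int = 1000,
    patience: int = 6,
) -> TrainingResult:
    """Train one network on scaled data with validation-based early stopping.

    Returns the parameters from the epoch with the lowest validation MSE
    seen (including the initial parameters).  A run that produces a
    non-finite loss is reported with ``failed=True`` rather than raising.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("train and validation sets must be nonempty")

    rng = np.random.default_rng(seed)
    params0 = init_parameters(arch, rng)
    theta0 = pack(params0)

    def val_mse(th: np.ndarray) -> float:
        return _mse(unpack(th, arch), arch, X_val, y_val)

    stopper = _EarlyStopper(patience)
    stopper.update(theta0, val_mse(theta0))
    try:
        epochs = _TRAINERS[arch.algorithm](
            theta0.copy(), arch, X_train, y_train, val_mse, stopper, max_epochs
        )
    except FloatingPointError:
        return TrainingResult(None, arch, np.nan, np.nan, 0, seed, failed=True)

    theta_best = stopper.best_theta if stopper.best_theta is not None else theta0
    params = unpack(theta_best, arch)
    mse_train = _mse(params, arch, X_train, y_train)
    mse_val = _mse(params, arch, X_val, y_val)
    if not (np.isfinite(mse_train) and np.isfinite(mse_val)):
        return TrainingResult(None, arch, np.nan, np.nan, epochs, seed, failed=True)
    return TrainingResult(params, arch, mse_train, mse_val, epochs, seed)


def predict_dataset(params: MLPParameters, arch: MLPArchitecture, dataset) -> np.ndarray:
    """Predictions on the original response scale for a ModelingDataset."""
    if dataset.scaling is None:
        raise ValueError("dataset has no scaling parameters")
    y_scaled = forward(params, arch, dataset.X_scaled)
    return dataset.unscale_response(y_scaled)


# ---------------------------------------------------------------------------
# plain-text serialization of fitted weights (appendix-style tables)


def params_to_text(params: MLPParameters, arch: MLPArchitecture) -> str:
    buf = io.StringIO()
    buf.write("# airmort MLP weight tables\n")
    buf.write(
        f"arch n_inputs={arch.n_inputs} hidden={','.join(map(str, arch.hidden_sizes))} "
        f"hidden_activation={arch.hidden_activation} output_activation={arch.output_activation} "
        f"algorithm={arch.algorithm}\n"
    )
    for l, (W, b) in enumerate(zip(params.weights, params.biases), start=1):
        buf.write(f"layer {l} weights {W.shape[0]} {W.shape[1]}\n")
        for row in W:
            buf.write(" ".join(format(v, ".17g") for v in row) + "\n")
        buf.write(f"layer {l} bias {b.shape[0]}\n")
        buf.write(" ".join(format(v, ".17g") for v in b) + "\n")
    return buf.getvalue()


def params_from_text(text: str) -> tuple[MLPParameters, MLPArchitecture]:
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = dict(tok.split("=", 1) for tok in lines[0].split()[1:])
    arch = MLPArchitecture(
        n_inputs=int(header["n_inputs"]),
        hidden_sizes=tuple(int(h) for h in header["hidden"].split(",")),
        hidden_activation=header["hidden_activation"],
        output_activation=header["output_activation"],
        algorithm=header["algorithm"],
    )
    weights, biases = [], []
    i = 1
    while i < len(lines):
        kind = lines[i].split()
        if kind[2] == "weights":
            rows, cols = int(kind[3]), int(kind[4])
            W = np.array([[float(v) for v in lines[i + 1 + r].split()] for r in range(rows)])
            assert W.shape == (rows, cols)
            weights.append(W)
            i += 1 + rows
        else:
            size = int(kind[3])
            biases.append(np.array([float(v) for v in lines[i + 1].split()]))
            assert biases[-1].shape == (size,)
            i += 2
    return MLPParameters(weights, biases), arch
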