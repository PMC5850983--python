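"""Two-unit absolute-value autoencoder for unsupervised myocontrol.

One network is fitted per wrist degree of freedom.  The network reproduces
the R-channel RMS feature vector P(t) through a two-neuron hidden layer:

    a(t) = |IW . P(t)|            hidden layer, 2 x 1, no biases
    Q(t) = LW . a(t) + B          linear output layer, R x 1

and is trained to make Q(t) ~ P(t).  Because surface-EMG features are, to a
good approximation, nonnegative mixtures of a few direction-specific muscle
synergies, the two rectified hidden units of a well-fitted network carry the
activation of the DoF's two opposite movement directions — without any
kinematic labels.  The absolute value makes the activations nonnegative by
construction for arbitrary weights.

Training uses Levenberg–Marquardt (LM) on the stacked residual vector
``Q(t) - P(t)`` over all R*N residuals and all 5R free parameters (IW: 2R,
LW: 2R, B: R), with an analytic Jacobian that uses the subgradient
``sign(x)`` (``sign(0) = 0``) for the absolute value.  Fitting repeats the
training from ``n_restarts`` independent random initializations and keeps
the network whose two hidden time courses have minimum absolute Pearson
correlation: entangled solutions split a single direction across both units
(high |rho|), whereas the desired solution dedicates one unit per direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSeries

__all__ = [
    "AENParams",
    "ActivationSeries",
    "TrainConfig",
    "FitResult",
    "TrainingError",
    "forward_hidden",
    "forward_output",
    "reconstruction_sse",
    "train_lm",
    "fit_autoencoder",
    "extract_activations",
    "selection_correlation",
]


class TrainingError(RuntimeError):
    """Raised when an LM restart produces non-finite state, or all restarts fail."""


@dataclass
class AENParams:
    """Parameters of one DoF's autoencoder.

    ``iw`` is the 2 x R input weight matrix, ``lw`` the R x 2 output weight
    matrix and ``b`` the R output biases.  Hidden units carry no bias.
    """

    iw: np.ndarray
    lw: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.iw = np.asarray(self.iw, dtype=float)
        self.lw = np.asarray(self.lw, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.iw.ndim != 2 or self.iw.shape[0] != 2:
            raise ValueError("iw must have shape (2, R)")
        r = self.iw.shape[1]
        if self.lw.shape != (r, 2):
            raise ValueError(f"lw must have shape ({r}, 2)")
        if self.b.shape != (r,):
            raise ValueError(f"b must have shape ({r},)")
        for arr in (self.iw, self.lw, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.iw.shape[1]

    @property
    def n_free(self) -> int:
        """Number of free parameters, 5R."""
        return 5 * self.n_channels

    def to_dict(self) -> dict:
        return {
            "iw": self.iw.tolist(),
            "lw": self.lw.tolist(),
            "b": self.b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AENParams":
        return cls(iw=np.array(d["iw"]), lw=np.array(d["lw"]), b=np.array(d["b"]))


@dataclass
class ActivationSeries:
    """Nonnegative hidden-layer activations a1(t), a2(t) at the frame rate."""

    a1: np.ndarray
    a2: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a2 = np.asarray(self.a2, dtype=float)
        if self.a1.shape != self.a2.shape or self.a1.ndim != 1:
            raise ValueError("a1 and a2 must be 1-D arrays of equal length")
        if np.any(self.a1 < 0) or np.any(self.a2 < 0):
            raise ValueError("activations must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.a1.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        """Activations as a 2 x N array."""
        return np.vstack([self.a1, self.a2])


@dataclass
class TrainConfig:
    """Training hyperparameters for LM fitting with random restarts.

    ``lm_lambda_init/up/down`` define the damping schedule: the damping
    factor is multiplied by ``lm_lambda_up`` after a rejected step and by
    ``lm_lambda_down`` after an accepted one.  ``convergence_tol`` is the
    relative SSE decrease below which an accepted step terminates training.
    """

    n_restarts: int = 10
    max_iterations: int = 200
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 0.1
    lm_lambda_max: float = 1e12
    convergence_tol: float = 1e-8
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if min(self.lm_lambda_init, self.lm_lambda_up, self.lm_lambda_down) <= 0:
            raise ValueError("damping factors must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class FitResult:
    """Outcome of a multi-restart fit.

    ``params`` is the selected network (with any per-channel training
    normalization already folded back into the weights, so it applies
    directly to raw feature vectors).
    """

    params: AENParams
    selection_correlation: float
    sse: float
    restart_correlations: list[float]
    restart_sses: list[float]
    trace: list[float]
    seed: int
    n_failed: int = 0
    norm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Forward maps
# ---------------------------------------------------------------------------

def _check_dims(r_params: int, r_features: int) -> None:
    if r_params != r_features:
        raise ValueError(
            f"dimension mismatch: network expects R={r_params} channels, "
            f"features have R={r_features}"
        )


def forward_hidden(params: AENParams, features: FeatureSeries) -> ActivationSeries:
    """Hidden-layer activations ``a(t) = |IW . P(t)|`` (elementwise abs, no bias)."""
    _check_dims(params.n_channels, features.n_channels)
    a = np.abs(params.iw @ features.values)
    return ActivationSeries(a1=a[0], a2=a[1], frame_rate=features.frame_rate)


def extract_activations(iw: np.ndarray, features: FeatureSeries) -> ActivationSeries:
    """Control-signal extraction ``a(t) = |IW . P(t)|`` from the input weights alone.

    Identical formula to :func:`forward_hidden`; the output layer plays no
    role at run time.
    """
    iw = np.asarray(iw, dtype=float)
    if iw.ndim != 2 or iw.shape[0] != 2:
        raise ValueError("iw must have shape (2, R)")
    _check_dims(iw.shape[1], features.n_channels)
    a = np.abs(iw @ features.values)
    return ActivationSeries(a1=a[0], a2=a[1], frame_rate=features.frame_rate)


def forward_output(params: AENParams, act: ActivationSeries) -> np.ndarray:
    """Linear reconstruction ``Q(t) = LW . a(t) + B`` as an R x N array."""
    return params.lw @ act.stacked + params.b[:, None]


def reconstruction_sse(params: AENParams, features: FeatureSeries) -> float:
    """Sum of squared reconstruction errors over all channels and windows."""
    q = forward_output(params, forward_hidden(params, features))
    return float(np.sum((q - features.values) ** 2))


# ---------------------------------------------------------------------------
# Levenberg–Marquardt training
# ---------------------------------------------------------------------------

def _pack(params: AENParams) -> np.ndarray:
    return np.concatenate([params.iw.ravel(), params.lw.ravel(), params.b])


def _unpack(theta: np.ndarray, r: int) -> AENParams:
    iw = theta[: 2 * r].reshape(2, r)
    lw = theta[2 * r : 4 * r].reshape(r, 2)
    b = theta[4 * r :]
    return AENParams(iw=iw, lw=lw, b=b)


def _residuals_and_jacobian(
    theta: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked residual vector (R*N,) and its Jacobian (R*N, 5R).

    Residual ordering is channel-major: index ``r * N + t``.  The abs-value
    derivative uses the subgradient sign(x) with sign(0) = 0.
    """
    r, n = p.shape
    iw = theta[: 2 * r].reshape(2, r)
    lw = theta[2 * r : 4 * r].reshape(r, 2)
    b = theta[4 * r :]

    z = iw @ p                       # 2 x N pre-rectification
    s = np.sign(z)                   # subgradient of |.|
    a = np.abs(z)
    q = lw @ a + b[:, None]
    res = (q - p).ravel()            # (R*N,)

    # d res[r,t] / d IW[k,j] = LW[r,k] * s[k,t] * P[j,t]
    j_iw = np.einsum("rk,kt,jt->rtkj", lw, s, p).reshape(r * n, 2 * r)
    # d res[r,t] / d LW[r',k] = delta(r,r') * a[k,t]
    j_lw = np.zeros((r, n, r, 2))
    idx = np.arange(r)
    j_lw[idx, :, idx, :] = a.T
    j_lw = j_lw.reshape(r * n, 2 * r)
    # d res[r,t] / d B[r'] = delta(r,r')
    j_b = np.zeros((r, n, r))
    j_b[idx, :, idx] = 1.0
    j_b = j_b.reshape(r * n, r)

    return res, np.hstack([j_iw, j_lw, j_b])


def train_lm(
    features: FeatureSeries,
    config: TrainConfig,
    initial_params: AENParams,
) -> tuple[AENParams, list[float]]:
    """Fit one autoencoder with damped Levenberg–Marquardt.

    Returns the final parameters and the trace of SSE values over accepted
    steps (starting with the initial SSE); the trace is non-increasing by
    construction since steps that do not reduce the SSE are rejected and the
    damping factor raised.  Termination: relative SSE decrease below
    ``convergence_tol``, ``max_iterations`` accepted/attempted iterations,
    or damping overflow (no downhill step found up to ``lm_lambda_max``).
    """
    _check_dims(initial_params.n_channels, features.n_channels)
    p = features.values
    r, n = p.shape
    if n <= initial_params.n_free:
        warnings.warn(
            f"only {n} windows for {initial_params.n_free} free parameters; "
            "the fit is under-determined",
            stacklevel=2,
        )

    theta = _pack(initial_params)
    res, jac = _residuals_and_jacobian(theta, p)
    sse = float(res @ res)
    if not np.isfinite(sse):
        raise TrainingError("non-finite SSE at the initial point")
    trace = [sse]
    lam = config.lm_lambda_init
    eye = np.eye(theta.size)

    for _ in range(config.max_iterations):
        jtj = jac.T @ jac
        grad = jac.T @ res
        accepted = False
        while lam <= config.lm_lambda_max:
            try:
                step = np.linalg.solve(jtj + lam * eye, -grad)
            except np.linalg.LinAlgError:
                lam *= config.lm_lambda_up
                continue
            theta_new = theta + step
            res_new, jac_new = _residuals_and_jacobian(theta_new, p)
            sse_new = float(res_new @ res_new)
            if np.isfinite(sse_new) and sse_new < sse:
                accepted = True
                break
            lam *= config.lm_lambda_up
        if not accepted:
            break  # damping overflow: stuck at a (sub)stationary point
        rel_drop = (sse - sse_new) / max(sse, np.finfo(float).tiny)
        theta, res, jac, sse = theta_new, res_new, jac_new, sse_new
        trace.append(sse)
        lam = max(lam * config.lm_lambda_down, 1e-15)
        if rel_drop < config.convergence_tol:
            break

    if not np.all(np.isfinite(theta)):
        raise TrainingError("non-finite parameters at the end of training")
    return _unpack(theta, r), trace


def selection_correlation(act: ActivationSeries) -> float:
    """Pearson correlation between the two hidden time courses.

    A hidden unit with zero variance is perfectly decoupled from the other,
    so its correlation is defined as 0.
    """
    a1, a2 = act.a1, act.a2
    if np.std(a1) == 0.0 or np.std(a2) == 0.0:
        return 0.0
    return float(np.corrcoef(a1, a2)[0, 1])


def _random_params(r: int, scale: float, rng: np.random.Generator) -> AENParams:
    return AENParams(
        iw=rng.uniform(-scale, scale, size=(2, r)),
        lw=rng.uniform(-scale, scale, size=(r, 2)),
        b=rng.uniform(-scale, scale, size=r),
    )


def fit_autoencoder(features: FeatureSeries, config: TrainConfig) -> FitResult:
    """Multi-restart fit with minimum-|correlation| model selection.

    Features are max-normalized per channel for training (undone by folding
    the normalization back into the returned weights), which keeps all
    channels on comparable scale for the uniform weight initialization.
    Each restart draws its initial weights from a deterministic child seed of
    ``config.seed``, so the whole procedure is exactly reproducible.
    """
    p = features.values
    norm = p.max(axis=1)
    norm = np.where(norm > 0, norm, 1.0)
    feats_n = FeatureSeries(
        values=p / norm[:, None],
        frame_rate=features.frame_rate,
        window_seconds=features.window_seconds,
        channel_labels=list(features.channel_labels),
    )

    children = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    best: tuple[float, AENParams, float, list[float]] | None = None
    correlations: list[float] = []
    sses: list[float] = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        init = _random_params(feats_n.n_channels, config.init_scale, rng)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, trace = train_lm(feats_n, config, init)
        except TrainingError:
            n_failed += 1
            continue
        act = forward_hidden(params, feats_n)
        rho = selection_correlation(act)
        correlations.append(rho)
        sses.append(trace[-1])
        if best is None or abs(rho) < abs(best[0]):
            best = (rho, params, trace[-1], trace)
    if best is None:
        raise TrainingError(
            f"all {config.n_restarts} training restarts failed (non-finite SSE)"
        )

    rho, params, sse, trace = best
    # Fold per-channel normalization into the weights: the returned network
    # applies directly to un-normalized feature vectors.
    folded = AENParams(
        iw=params.iw / norm[None, :],
        lw=params.lw * norm[:, None],
        b=params.b * norm,
    )
    return FitResult(
        params=folded,
        selection_correlation=rho,
        sse=sse,
        restart_correlations=correlations,
        restart_sses=sses,
        trace=trace,
        seed=config.seed,
        n_failed=n_failed,
        norm=norm,
    )
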