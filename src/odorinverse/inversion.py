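"""Gradient-descent search of the mass-spectrum feature space.

Rather than searching raw spectrum space — which is sparse and mostly zero,
and resists direct gradient descent — the inverse problem is solved in the
autoencoder bottleneck: find a feature vector X whose predicted odor
impression f(X) matches a target t under the weighted half-sum-of-squares
objective

    L = 1/2 * sum_i m_i (t_i - x_i)^2,

where f is the tail of the nine-layer predictor (feature -> impression) and
the weights m_i emphasize the descriptors being designed for.  The gradient
flows through the sigmoid layers by the chain rule (each layer contributes
diag(z(1-z)) W), the step size decays geometrically, and the iterate with the
smallest objective anywhere along the trajectory is returned — descent on a
non-convex surface need not end at its best point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .neuralnet import MLPParams, NetworkError, PredictiveModel, _check_grid, sigmoid_forward
from .sensory import N_DESCRIPTORS, SensoryProfile, descriptor_index
from .spectra import MassSpectrum

# A feature vector is a plain 1-D float array of length model.feature_dim.
FeatureVector = np.ndarray


class InversionError(ValueError):
    """Raised for malformed targets or diverging searches."""


@dataclass
class InversionTarget:
    """Target impression t (21 scores) and per-descriptor weights m >= 0."""

    target_scores: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.target_scores, dtype=float)
        m = np.asarray(self.weights, dtype=float)
        if t.shape != (N_DESCRIPTORS,) or m.shape != (N_DESCRIPTORS,):
            raise InversionError(
                f"target and weights must both have length {N_DESCRIPTORS}, got {t.shape} and {m.shape}"
            )
        if np.any(m < 0):
            raise InversionError("descriptor weights must be nonnegative")
        if not np.any(m > 0):
            raise InversionError("at least one descriptor weight must be positive")
        object.__setattr__(self, "target_scores", t)
        object.__setattr__(self, "weights", m)


@dataclass
class InversionResult:
    best_feature: FeatureVector
    best_wse: float
    wse_trajectory: np.ndarray
    best_iteration: int


def tail_params(model: PredictiveModel) -> MLPParams:
    """The feature -> impression part of the stack (layers 3..9 of the combined net)."""
    n_enc = model.encoder_ms.n_layers - 1
    return model.combined.slice(n_enc, model.combined.n_layers - 1)


def encode(model: PredictiveModel, s: MassSpectrum) -> FeatureVector:
    """Bottleneck feature of a (normalized, windowed) spectrum: layers 1..3."""
    _check_grid(model, s)
    return sigmoid_forward(model.encoder_ms, s.intensities)[-1]


def feature_to_impression(model: PredictiveModel, x3: FeatureVector) -> np.ndarray:
    """Impression scores for a feature-space point; equals predict_impression(encode(s))
    when x3 = encode(s)."""
    x3 = np.asarray(x3, dtype=float)
    if x3.shape != (model.feature_dim,):
        raise InversionError(f"feature has shape {x3.shape}, model expects ({model.feature_dim},)")
    return sigmoid_forward(tail_params(model), x3)[-1]


def wse(pred: np.ndarray | SensoryProfile, target: InversionTarget) -> float:
    """Weighted half-sum-of-squares error between predicted and target scores."""
    x = pred.scores if isinstance(pred, SensoryProfile) else np.asarray(pred, dtype=float)
    if x.shape != (N_DESCRIPTORS,):
        raise InversionError(f"prediction must have length {N_DESCRIPTORS}, got {x.shape}")
    return float(0.5 * np.sum(target.weights * (target.target_scores - x) ** 2))


def jacobian_f39(model: PredictiveModel, x3: FeatureVector) -> np.ndarray:
    """Jacobian of the feature -> impression map, shape (21, feature_dim).

    Chain-rule product over the tail layers: each contributes
    diag(z*(1-z)) @ W with z the layer's post-sigmoid activation.
    """
    tail = tail_params(model)
    acts = sigmoid_forward(tail, np.asarray(x3, dtype=float))
    jac: np.ndarray | None = None
    for k, w in enumerate(tail.weights):
        z = acts[k + 1]
        layer_jac = (z * (1.0 - z))[:, None] * w
        jac = layer_jac if jac is None else layer_jac @ jac
    assert jac is not None
    return jac


def wse_gradient(model: PredictiveModel, x3: FeatureVector, target: InversionTarget):
    """(dL/dx3, predicted scores, L) at a feature point.

    Reverse-mode through the tail: dL/dX9 has components m_i (x_i - t_i).
    """
    tail = tail_params(model)
    acts = sigmoid_forward(tail, np.asarray(x3, dtype=float))
    pred = acts[-1]
    loss = float(0.5 * np.sum(target.weights * (target.target_scores - pred) ** 2))
    v = target.weights * (pred - target.target_scores)
    for k in range(len(tail.weights) - 1, -1, -1):
        z = acts[k + 1]
        v = (v * z * (1.0 - z)) @ tail.weights[k]
    return v, pred, loss


def descent_step(x3: FeatureVector, grad: np.ndarray, eta: float) -> FeatureVector:
    """One gradient-descent update x3 - eta*grad."""
    if eta <= 0:
        raise InversionError(f"step size must be positive, got {eta}")
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise InversionError("non-finite gradient")
    return np.asarray(x3, dtype=float) - eta * grad


def invert(
    model: PredictiveModel,
    start: FeatureVector,
    target: InversionTarget,
    eta0: float = 0.1,
    gamma: float = 0.99,
    n_iters: int = 2000,
    clip_to_unit: bool = False,
) -> InversionResult:
    """Descend the feature space toward the target impression.

    Steps eta_tau = eta0*gamma**tau for tau = 0..n_iters-1; the trajectory
    records the objective at the start and after every update (length
    n_iters+1), and the returned feature is the trajectory's argmin, not
    necessarily the last iterate.  ``clip_to_unit`` optionally projects each
    iterate back into [0, 1]; by default the search is unconstrained since
    the tail map is defined for all reals.
    """
    if n_iters < 1:
        raise InversionError("n_iters must be >= 1")
    x = np.asarray(start, dtype=float).copy()
    if x.shape != (model.feature_dim,):
        raise InversionError(f"start feature has shape {x.shape}, model expects ({model.feature_dim},)")
    traj = np.empty(n_iters + 1)
    grad, _, loss = wse_gradient(model, x, target)
    traj[0] = loss
    best_x, best_loss, best_iter = x.copy(), loss, 0
    for tau in range(n_iters):
        x = descent_step(x, grad, eta0 * gamma**tau)
        if clip_to_unit:
            x = np.clip(x, 0.0, 1.0)
        grad, _, loss = wse_gradient(model, x, target)
        if not np.isfinite(loss):
            raise InversionError(f"non-finite objective at iteration {tau + 1}")
        traj[tau + 1] = loss
        if loss < best_loss:
            best_x, best_loss, best_iter = x.copy(), loss, tau + 1
    return InversionResult(best_x, best_loss, traj, best_iter)


def make_boosted_target(
    model: PredictiveModel,
    s: MassSpectrum,
    descriptor: str,
    factor: float,
    weights: np.ndarray,
) -> InversionTarget:
    """Target = the model's own prediction with one descriptor scaled by ``factor``.

    Boosted values may exceed 1 (a warning is emitted): the 'virtual true
    value' is defined before any clipping, and the sigmoid output simply
    cannot reach it — the search still pulls the descriptor upward.
    """
    if factor <= 0:
        raise InversionError(f"boost factor must be positive, got {factor}")
    j = descriptor_index(descriptor)
    pred = sigmoid_forward(model.combined, s.intensities)[-1]
    t = pred.copy()
    t[j] = factor * t[j]
    if t[j] > 1.0:
        warnings.warn(
            f"boosted target for {descriptor!r} is {t[j]:.3f} > 1; the sigmoid output "
            "cannot reach it exactly",
            stacklevel=2,
        )
    return InversionTarget(t, np.asarray(weights, dtype=float))


def uniform_weights(emphasis: str | None = None, base: float = 1.0, other: float = 1.0) -> np.ndarray:
    """Weight vector m: ``base`` on the emphasized descriptor, ``other`` elsewhere."""
    m = np.full(N_DESCRIPTORS, other, dtype=float)
    if emphasis is not None:
        m[descriptor_index(emphasis)] = base
    return m
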