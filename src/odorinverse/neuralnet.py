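"""Sigmoid multilayer-perceptron core and the predictive-model training pipeline.

The odor-impression predictor is a nine-layer sigmoid MLP assembled from
three pretrained parts:

* the encoder half of a five-layer mass-spectrum autoencoder
  (212 -> K_M -> D_M), trained on synthetic random mixtures of library
  spectra;
* a five-layer feature converter (D_M -> K_P1 -> K_P2 -> K_P3 -> D_S)
  mapping spectrum features to sensory features;
* the decoder half of a five-layer sensory autoencoder (D_S -> K_S -> 21).

All training is plain backpropagation on a half-sum-of-squares loss with an
L2 (ridge) weight penalty, momentum, and a geometrically decaying learning
rate eta_tau = eta0 * gamma**tau.  Weights start from Glorot-uniform (Xavier)
initialization; biases start at zero and are excluded from the ridge penalty.
After composition the full nine-layer stack is fine-tuned end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit
from sklearn.model_selection import KFold

from .sensory import DESCRIPTORS, SensoryDataset, SensoryProfile
from .spectra import DEFAULT_MZ_START, MassSpectrum, SpectrumLibrary, mix_spectra

# Default architecture and per-stage hyperparameters of the predictive model.
# Subscripts: M = mass-spectrum autoencoder, S = sensory autoencoder,
# P = feature converter, F = fine-tuning of the composed stack.
DEFAULT_HYPERPARAMS: dict[str, float | int] = {
    "K_M": 85,
    "D_M": 70,
    "lambda_M": 7.5e-5,
    "eta0_M": 0.5,
    "gamma_M": 0.99,
    "alpha_M": 0.3,
    "K_S": 20,
    "D_S": 15,
    "lambda_S": 2.0e-9,
    "eta0_S": 0.4,
    "gamma_S": 0.99,
    "alpha_S": 0.3,
    "K_P1": 30,
    "K_P2": 70,
    "K_P3": 45,
    "lambda_P": 1.0e-5,
    "eta0_P": 0.4,
    "gamma_P": 0.99,
    "alpha_P": 0.25,
    "lambda_F": 2.0e-5,
    "eta0_F": 0.35,
    "gamma_F": 0.99,
    "alpha_F": 0.025,
    "n_updates": 2000,
    "n_pretrain": 500_000,
    "pretrain_components": 3,
}


class NetworkError(ValueError):
    """Raised for inconsistent network shapes or degenerate training states."""


def sigmoid(a: np.ndarray) -> np.ndarray:
    return expit(a)


@dataclass
class MLPParams:
    """Weights and biases of a K-layer sigmoid perceptron.

    ``weights[k]`` has shape (n(k+1), n(k)) and maps layer k to the
    pre-activation of layer k+1; ``biases[k]`` has length n(k+1).
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = [int(s) for s in self.layer_sizes]
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise NetworkError(f"invalid layer sizes {sizes}")
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise NetworkError("need exactly one weight matrix and bias vector per layer transition")
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[k + 1], sizes[k]):
                raise NetworkError(f"weight {k} has shape {w.shape}, expected {(sizes[k + 1], sizes[k])}")
            if b.shape != (sizes[k + 1],):
                raise NetworkError(f"bias {k} has shape {b.shape}, expected {(sizes[k + 1],)}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise NetworkError(f"non-finite parameter in layer transition {k}")
        object.__setattr__(self, "layer_sizes", sizes)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def copy(self) -> "MLPParams":
        return MLPParams(list(self.layer_sizes), [w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def slice(self, start: int, stop: int) -> "MLPParams":
        """Sub-network spanning layers start..stop (0-based, inclusive)."""
        if not (0 <= start < stop < self.n_layers):
            raise NetworkError(f"invalid layer slice [{start}, {stop}] of a {self.n_layers}-layer net")
        return MLPParams(
            self.layer_sizes[start : stop + 1],
            [w.copy() for w in self.weights[start:stop]],
            [b.copy() for b in self.biases[start:stop]],
        )


def xavier_init(layer_sizes: Sequence[int], rng: np.random.Generator, gain: float = 1.0) -> MLPParams:
    """Glorot-uniform initialization: w ~ U(+-sqrt(6/(n_in+n_out))), biases zero."""
    sizes = [int(s) for s in layer_sizes]
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        bound = gain * np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return MLPParams(sizes, weights, biases)


def sigmoid_forward(params: MLPParams, x: np.ndarray) -> list[np.ndarray]:
    """Forward pass returning every layer X^(1..K); accepts a vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    acts = [x[None, :] if single else x]
    if acts[0].shape[1] != params.layer_sizes[0]:
        raise NetworkError(
            f"input has dimension {acts[0].shape[1]}, network expects {params.layer_sizes[0]}"
        )
    for w, b in zip(params.weights, params.biases):
        acts.append(sigmoid(acts[-1] @ w.T + b))
    return [a[0] for a in acts] if single else acts


def forward_output(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Output layer only."""
    return sigmoid_forward(params, x)[-1]


@dataclass
class TrainingConfig:
    """Backpropagation schedule for one training stage.

    eta_tau = eta0 * gamma**tau with tau counting epochs by default (one
    update per epoch in full-batch mode, so the update index coincides with
    the epoch index there); set ``schedule_unit='update'`` to decay per
    parameter update instead.  ``batch_size=None`` means full batch.  The
    loss is the per-sample mean of 1/2*||error||^2 plus lambda/2*||W||^2
    (biases unpenalized); updates use momentum
    dtheta_tau = -eta_tau*grad + alpha*dtheta_{tau-1}.
    """

    eta0: float = 0.4
    gamma: float = 0.99
    alpha: float = 0.0
    lambda_reg: float = 0.0
    n_updates: int = 2000
    batch_size: int | None = None
    schedule_unit: Literal["epoch", "update"] = "epoch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta0 <= 0:
            raise NetworkError("eta0 must be positive")
        if not (0 < self.gamma <= 1):
            raise NetworkError("gamma must be in (0, 1]")
        if self.alpha < 0 or self.lambda_reg < 0:
            raise NetworkError("alpha and lambda_reg must be nonnegative")
        if self.n_updates < 0:
            raise NetworkError("n_updates must be nonnegative")
        if self.schedule_unit not in ("epoch", "update"):
            raise NetworkError(f"unknown schedule_unit {self.schedule_unit!r}")


def _backprop(params: MLPParams, X: np.ndarray, T: np.ndarray, lam: float):
    """Mean half-SSE loss + ridge penalty and its gradients on one batch."""
    acts = sigmoid_forward(params, X)
    n = X.shape[0]
    err = acts[-1] - T
    loss = 0.5 * np.sum(err**2) / n + 0.5 * lam * sum(np.sum(w**2) for w in params.weights)
    grads_w: list[np.ndarray] = [None] * len(params.weights)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(params.biases)  # type: ignore[list-item]
    delta = err * acts[-1] * (1.0 - acts[-1])
    for k in range(len(params.weights) - 1, -1, -1):
        grads_w[k] = delta.T @ acts[k] / n + lam * params.weights[k]
        grads_b[k] = delta.mean(axis=0)
        if k > 0:
            delta = (delta @ params.weights[k]) * acts[k] * (1.0 - acts[k])
    return loss, grads_w, grads_b


def train_sgd(
    params: MLPParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
) -> tuple[MLPParams, np.ndarray]:
    """Momentum SGD on half-SSE + ridge; returns new params and per-update loss.

    The loss history records the (regularized) batch loss at each of the
    ``n_updates`` parameter updates, evaluated before the update is applied.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] != T.shape[0]:
        raise NetworkError(f"{X.shape[0]} inputs but {T.shape[0]} targets")
    if X.shape[1] != params.layer_sizes[0] or T.shape[1] != params.layer_sizes[-1]:
        raise NetworkError(
            f"data dims ({X.shape[1]}, {T.shape[1]}) do not match network "
            f"({params.layer_sizes[0]}, {params.layer_sizes[-1]})"
        )
    params = params.copy()
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    batch = n if config.batch_size is None else min(config.batch_size, n)
    updates_per_epoch = max(1, n // batch) if batch < n else 1

    vel_w = [np.zeros_like(w) for w in params.weights]
    vel_b = [np.zeros_like(b) for b in params.biases]
    losses = np.empty(config.n_updates)
    order = rng.permutation(n)
    pos = 0
    for tau in range(config.n_updates):
        if batch < n:
            if pos + batch > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos : pos + batch]
            pos += batch
            Xb, Tb = X[idx], T[idx]
        else:
            Xb, Tb = X, T
        loss, gw, gb = _backprop(params, Xb, Tb, config.lambda_reg)
        if not np.isfinite(loss):
            raise NetworkError(f"non-finite loss at update {tau}")
        losses[tau] = loss
        sched_idx = tau // updates_per_epoch if config.schedule_unit == "epoch" else tau
        eta = config.eta0 * config.gamma**sched_idx
        for k in range(len(params.weights)):
            vel_w[k] = -eta * gw[k] + config.alpha * vel_w[k]
            vel_b[k] = -eta * gb[k] + config.alpha * vel_b[k]
            params.weights[k] = params.weights[k] + vel_w[k]
            params.biases[k] = params.biases[k] + vel_b[k]
    return params, losses


def train_autoencoder(
    data: np.ndarray,
    hidden1: int,
    bottleneck: int,
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MLPParams, np.ndarray]:
    """Train a symmetric five-layer autoencoder (n, hidden1, bottleneck, hidden1, n).

    The encoder is layers 1..3, the decoder layers 3..5 (see
    :meth:`MLPParams.slice`).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise NetworkError("autoencoder training data is empty")
    n = data.shape[1]
    if hidden1 < 1 or bottleneck < 1:
        raise NetworkError("autoencoder layer sizes must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = xavier_init([n, hidden1, bottleneck, hidden1, n], rng)
    return train_sgd(params, data, data, config)


def encoder_part(ae: MLPParams) -> MLPParams:
    """Layers 1..3 of a five-layer autoencoder."""
    if ae.n_layers != 5:
        raise NetworkError(f"expected a 5-layer autoencoder, got {ae.n_layers} layers")
    return ae.slice(0, 2)


def decoder_part(ae: MLPParams) -> MLPParams:
    """Layers 3..5 of a five-layer autoencoder."""
    if ae.n_layers != 5:
        raise NetworkError(f"expected a 5-layer autoencoder, got {ae.n_layers} layers")
    return ae.slice(2, 4)


def make_pretraining_set(
    library: SpectrumLibrary,
    n: int,
    k_components: int = 3,
    rng: np.random.Generator | None = None,
) -> list[MassSpectrum]:
    """Synthetic mixtures for autoencoder pretraining.

    Each sample linearly combines ``k_components`` distinct library spectra
    with ratios drawn uniformly on the simplex, then base-peak renormalizes.
    """
    if n < 1:
        raise NetworkError("need at least one pretraining sample")
    if k_components < 1 or k_components > len(library):
        raise NetworkError(
            f"k_components={k_components} must be in [1, {len(library)}] for this library"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    n_lib = len(library)
    for i in range(n):
        idx = rng.choice(n_lib, size=k_components, replace=False)
        ratios = rng.dirichlet(np.ones(k_components))
        out.append(
            mix_spectra([library[int(j)] for j in idx], ratios, renormalize=True, id=f"synmix{i}")
        )
    return out


@dataclass
class PredictiveModel:
    """The composed nine-layer spectrum -> odor-impression predictor.

    ``combined`` concatenates the mass-spectrum encoder, the feature
    converter, and the sensory decoder; the parts are kept both for
    provenance and because inversion and recovery address them separately.
    ``ms_decoder`` (layers 3..5 of the spectrum autoencoder) is not part of
    the predictive stack but provides the baseline spectrum reconstruction.
    """

    encoder_ms: MLPParams
    converter: MLPParams
    decoder_sensory: MLPParams
    combined: MLPParams
    ms_decoder: MLPParams | None = None
    descriptors: tuple[str, ...] = DESCRIPTORS
    mz_start: int = DEFAULT_MZ_START
    sensory_norm: float | None = None

    @property
    def ms_dim(self) -> int:
        return self.combined.layer_sizes[0]

    @property
    def feature_dim(self) -> int:
        return self.encoder_ms.layer_sizes[-1]

    @property
    def sensory_feature_dim(self) -> int:
        return self.decoder_sensory.layer_sizes[0]

    @property
    def sensory_dim(self) -> int:
        return self.combined.layer_sizes[-1]


def compose_model(
    encoder_ms: MLPParams,
    converter: MLPParams,
    decoder_sensory: MLPParams,
    ms_decoder: MLPParams | None = None,
    descriptors: tuple[str, ...] = DESCRIPTORS,
    mz_start: int = DEFAULT_MZ_START,
    sensory_norm: float | None = None,
) -> PredictiveModel:
    """Concatenate the three parts into one nine-layer stack.

    Predictions through the combined stack equal
    decoder(converter(encoder(x))) exactly — composition copies parameters,
    it does not retrain.
    """
    if encoder_ms.layer_sizes[-1] != converter.layer_sizes[0]:
        raise NetworkError(
            f"junction mismatch: encoder output {encoder_ms.layer_sizes[-1]} "
            f"!= converter input {converter.layer_sizes[0]}"
        )
    if converter.layer_sizes[-1] != decoder_sensory.layer_sizes[0]:
        raise NetworkError(
            f"junction mismatch: converter output {converter.layer_sizes[-1]} "
            f"!= decoder input {decoder_sensory.layer_sizes[0]}"
        )
    combined = MLPParams(
        encoder_ms.layer_sizes + converter.layer_sizes[1:] + decoder_sensory.layer_sizes[1:],
        [w.copy() for w in encoder_ms.weights + converter.weights + decoder_sensory.weights],
        [b.copy() for b in encoder_ms.biases + converter.biases + decoder_sensory.biases],
    )
    return PredictiveModel(
        encoder_ms=encoder_ms.copy(),
        converter=converter.copy(),
        decoder_sensory=decoder_sensory.copy(),
        combined=combined,
        ms_decoder=ms_decoder.copy() if ms_decoder is not None else None,
        descriptors=descriptors,
        mz_start=mz_start,
        sensory_norm=sensory_norm,
    )


def fine_tune(
    model: PredictiveModel,
    spectra: np.ndarray,
    scores: np.ndarray,
    config: TrainingConfig,
) -> tuple[PredictiveModel, np.ndarray]:
    """Backpropagate through all nine layers jointly on (spectrum, profile) pairs.

    Returns a new model whose parts are re-sliced views of the fine-tuned
    stack; the spectrum-autoencoder decoder is untouched (it is not part of
    the predictive stack).
    """
    combined, losses = train_sgd(model.combined, spectra, scores, config)
    n_enc = model.encoder_ms.n_layers - 1
    n_conv = model.converter.n_layers - 1
    new = PredictiveModel(
        encoder_ms=combined.slice(0, n_enc),
        converter=combined.slice(n_enc, n_enc + n_conv),
        decoder_sensory=combined.slice(n_enc + n_conv, combined.n_layers - 1),
        combined=combined,
        ms_decoder=model.ms_decoder.copy() if model.ms_decoder is not None else None,
        descriptors=model.descriptors,
        mz_start=model.mz_start,
        sensory_norm=model.sensory_norm,
    )
    return new, losses


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition; test folds are disjoint, cover all n, sizes differ by <= 1."""
    if not (2 <= k <= n):
        raise NetworkError(f"need 2 <= k <= n, got k={k}, n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in kf.split(np.arange(n))]


def _check_grid(model: PredictiveModel, s: MassSpectrum) -> None:
    if len(s.intensities) != model.ms_dim or s.mz_start != model.mz_start:
        raise NetworkError(
            f"spectrum {s.id!r} grid (start {s.mz_start}, {len(s.intensities)} bins) does not "
            f"match model grid (start {model.mz_start}, {model.ms_dim} bins)"
        )


def predict_impression(model: PredictiveModel, s: MassSpectrum) -> SensoryProfile:
    """Forward the (normalized, windowed) spectrum through the nine-layer stack."""
    _check_grid(model, s)
    scores = forward_output(model.combined, s.intensities)
    return SensoryProfile(s.id, scores)


# ---------------------------------------------------------------------------
# Training pipeline and evaluation
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Architecture plus per-stage schedules for the full training pipeline.

    Defaults are the model's standard operating point (``DEFAULT_HYPERPARAMS``);
    the ``scaled`` constructor shrinks only the data volumes, keeping the
    architecture.
    """

    hidden_ms: int = int(DEFAULT_HYPERPARAMS["K_M"])
    feature_ms: int = int(DEFAULT_HYPERPARAMS["D_M"])
    hidden_s: int = int(DEFAULT_HYPERPARAMS["K_S"])
    feature_s: int = int(DEFAULT_HYPERPARAMS["D_S"])
    converter_hidden: tuple[int, int, int] = (
        int(DEFAULT_HYPERPARAMS["K_P1"]),
        int(DEFAULT_HYPERPARAMS["K_P2"]),
        int(DEFAULT_HYPERPARAMS["K_P3"]),
    )
    n_pretrain: int = int(DEFAULT_HYPERPARAMS["n_pretrain"])
    pretrain_components: int = int(DEFAULT_HYPERPARAMS["pretrain_components"])
    cfg_ms: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(
            eta0=DEFAULT_HYPERPARAMS["eta0_M"],
            gamma=DEFAULT_HYPERPARAMS["gamma_M"],
            alpha=DEFAULT_HYPERPARAMS["alpha_M"],
            lambda_reg=DEFAULT_HYPERPARAMS["lambda_M"],
            n_updates=int(DEFAULT_HYPERPARAMS["n_updates"]),
            batch_size=64,
        )
    )
    cfg_s: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(
            eta0=DEFAULT_HYPERPARAMS["eta0_S"],
            gamma=DEFAULT_HYPERPARAMS["gamma_S"],
            alpha=DEFAULT_HYPERPARAMS["alpha_S"],
            lambda_reg=DEFAULT_HYPERPARAMS["lambda_S"],
            n_updates=int(DEFAULT_HYPERPARAMS["n_updates"]),
        )
    )
    cfg_p: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(
            eta0=DEFAULT_HYPERPARAMS["eta0_P"],
            gamma=DEFAULT_HYPERPARAMS["gamma_P"],
            alpha=DEFAULT_HYPERPARAMS["alpha_P"],
            lambda_reg=DEFAULT_HYPERPARAMS["lambda_P"],
            n_updates=int(DEFAULT_HYPERPARAMS["n_updates"]),
        )
    )
    cfg_f: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(
            eta0=DEFAULT_HYPERPARAMS["eta0_F"],
            gamma=DEFAULT_HYPERPARAMS["gamma_F"],
            alpha=DEFAULT_HYPERPARAMS["alpha_F"],
            lambda_reg=DEFAULT_HYPERPARAMS["lambda_F"],
            n_updates=int(DEFAULT_HYPERPARAMS["n_updates"]),
        )
    )

    @classmethod
    def desk_scale(
        cls, n_pretrain: int = 3000, n_updates: int = 12_000, ae_updates: int = 40_000
    ) -> "PipelineConfig":
        """Standard architecture sized for a laptop-scale synthetic study.

        The pretraining set shrinks to a few thousand mixtures and every
        stage gets a longer heavy-momentum schedule: with a sum-of-squares
        loss on sigmoid outputs, near-zero targets saturate the output units
        and shrink gradients, so small desk-scale runs need the extra
        updates and inertia that the full-scale data volume otherwise
        provides.  The spectrum autoencoder uses minibatches of 128 (eta0
        3.0, alpha 0.9, ``ae_updates`` steps); the sensory autoencoder and
        converter run ``n_updates`` full-batch steps at eta0 1.0 / alpha
        0.9; fine-tuning runs two thirds as many at its standard rate.
        Decay factors are chosen so the final step size is a few percent of
        the initial one.
        """
        cfg = cls(n_pretrain=n_pretrain)
        cfg.cfg_ms = replace(
            cfg.cfg_ms, eta0=3.0, gamma=0.99993, alpha=0.9, n_updates=ae_updates,
            batch_size=128, schedule_unit="update",
        )
        cfg.cfg_s = replace(
            cfg.cfg_s, eta0=1.0, gamma=0.9997, alpha=0.9, n_updates=n_updates,
            schedule_unit="update",
        )
        cfg.cfg_p = replace(
            cfg.cfg_p, eta0=1.0, gamma=0.9997, alpha=0.9, n_updates=n_updates,
            schedule_unit="update",
        )
        cfg.cfg_f = replace(
            cfg.cfg_f, gamma=0.9998, alpha=0.9, n_updates=max(1, 2 * n_updates // 3),
            schedule_unit="update",
        )
        return cfg


@dataclass
class TrainingReport:
    """Loss histories and reconstruction diagnostics from one pipeline run."""

    loss_ms: np.ndarray
    loss_s: np.ndarray
    loss_p: np.ndarray
    loss_f: np.ndarray
    ae_ms: MLPParams
    ae_s: MLPParams


def train_pipeline(
    library: SpectrumLibrary,
    sensory: SensoryDataset,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    train_ids: Sequence[str] | None = None,
) -> tuple[PredictiveModel, TrainingReport]:
    """Pretrain the two autoencoders and the converter, compose, fine-tune.

    ``library`` spectra must already be windowed and base-peak normalized,
    and ``sensory`` must be dataset-normalized.  ``train_ids`` restricts the
    supervised stages (sensory autoencoder, converter, fine-tuning) to a
    subset of molecules, e.g. the training side of a cross-validation fold;
    the spectrum autoencoder always pretrains on mixtures of the full
    library, which carries no sensory labels.
    """
    if config is None:
        config = PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    ids = list(train_ids) if train_ids is not None else [i for i in library.ids if i in sensory]
    missing = [i for i in ids if i not in sensory or i not in library]
    if missing:
        raise NetworkError(f"molecules without both spectrum and profile: {missing[:5]}")

    # Stage M: spectrum autoencoder on synthetic random mixtures.
    mixtures = make_pretraining_set(library, config.n_pretrain, config.pretrain_components, rng)
    X_mix = np.stack([m.intensities for m in mixtures])
    cfg_ms = replace(config.cfg_ms, seed=int(rng.integers(2**31)))
    ae_ms, loss_ms = train_autoencoder(X_mix, config.hidden_ms, config.feature_ms, cfg_ms)

    X_spec = np.stack([library[i].intensities for i in ids])
    Y_sens = np.stack([sensory[i].scores for i in ids])

    # Stage S: sensory autoencoder on the labelled molecules.
    cfg_s = replace(config.cfg_s, seed=int(rng.integers(2**31)))
    ae_s, loss_s = train_autoencoder(Y_sens, config.hidden_s, config.feature_s, cfg_s)

    # Stage P: converter between the two bottleneck features.
    feats_ms = forward_output(encoder_part(ae_ms), X_spec)
    feats_s = forward_output(encoder_part(ae_s), Y_sens)
    k1, k2, k3 = config.converter_hidden
    conv_sizes = [config.feature_ms, k1, k2, k3, config.feature_s]
    cfg_p = replace(config.cfg_p, seed=int(rng.integers(2**31)))
    conv0 = xavier_init(conv_sizes, rng)
    converter, loss_p = train_sgd(conv0, feats_ms, feats_s, cfg_p)

    # Stage F: compose and fine-tune end to end on (spectrum, profile) pairs.
    model = compose_model(
        encoder_part(ae_ms),
        converter,
        decoder_part(ae_s),
        ms_decoder=decoder_part(ae_ms),
        mz_start=library.mz_start,
        sensory_norm=sensory.normalization_constant,
    )
    cfg_f = replace(config.cfg_f, seed=int(rng.integers(2**31)))
    model, loss_f = fine_tune(model, X_spec, Y_sens, cfg_f)
    report = TrainingReport(loss_ms, loss_s, loss_p, loss_f, ae_ms, ae_s)
    return model, report


def pooled_pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson r pooled over all (molecule, descriptor) entries."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    return float(np.corrcoef(p, t)[0, 1])


def evaluate_model(model: PredictiveModel, spectra: np.ndarray, scores: np.ndarray) -> dict:
    """Held-out accuracy: pooled and per-descriptor Pearson correlations."""
    pred = forward_output(model.combined, np.atleast_2d(spectra))
    truth = np.atleast_2d(scores)
    per_desc = {}
    for j, name in enumerate(model.descriptors):
        sd_p, sd_t = pred[:, j].std(), truth[:, j].std()
        per_desc[name] = (
            float(np.corrcoef(pred[:, j], truth[:, j])[0, 1]) if sd_p > 0 and sd_t > 0 else float("nan")
        )
    return {"pooled_r": pooled_pearson(pred, truth), "per_descriptor_r": per_desc, "predictions": pred}


# ---------------------------------------------------------------------------
# Serialization: versioned JSON (human-readable, text-only)
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "odorinverse-model"
_MODEL_VERSION = 1


def _params_to_json(p: MLPParams) -> dict:
    return {
        "layer_sizes": p.layer_sizes,
        "weights": [w.tolist() for w in p.weights],
        "biases": [b.tolist() for b in p.biases],
    }


def _params_from_json(d: dict) -> MLPParams:
    return MLPParams(
        list(d["layer_sizes"]),
        [np.asarray(w, dtype=float) for w in d["weights"]],
        [np.asarray(b, dtype=float) for b in d["biases"]],
    )


def save_model(model: PredictiveModel, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "descriptors": list(model.descriptors),
        "mz_start": model.mz_start,
        "sensory_norm": model.sensory_norm,
        "part_depths": [model.encoder_ms.n_layers, model.converter.n_layers, model.decoder_sensory.n_layers],
        "combined": _params_to_json(model.combined),
        "ms_decoder": _params_to_json(model.ms_decoder) if model.ms_decoder is not None else None,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> PredictiveModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _MODEL_FORMAT:
        raise NetworkError(f"{path}: not an odorinverse model file")
    if doc.get("version") != _MODEL_VERSION:
        raise NetworkError(f"{path}: unsupported model version {doc.get('version')}")
    combined = _params_from_json(doc["combined"])
    d_enc, d_conv, _ = doc["part_depths"]
    n_enc, n_conv = d_enc - 1, d_conv - 1
    return PredictiveModel(
        encoder_ms=combined.slice(0, n_enc),
        converter=combined.slice(n_enc, n_enc + n_conv),
        decoder_sensory=combined.slice(n_enc + n_conv, combined.n_layers - 1),
        combined=combined,
        ms_decoder=_params_from_json(doc["ms_decoder"]) if doc["ms_decoder"] is not None else None,
        descriptors=tuple(doc["descriptors"]),
        mz_start=int(doc["mz_start"]),
        sensory_norm=doc["sensory_norm"],
    )
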