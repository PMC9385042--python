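"""Recover a physical mass spectrum from a target bottleneck feature.

The autoencoder decoder gives a quick reconstruction, but a greedy randomized
coordinate line search in raw spectrum space reaches a lower feature-space
error: at each iteration one m/z bin is nudged up or down by a geometrically
shrinking step, the candidate is clipped to nonnegative intensities and
base-peak renormalized, and the move is kept only if the squared distance
between its encoded feature and the target strictly decreases.  Acceptance is
greedy, so the error trajectory is monotone and the search — warm-started
from the decoder output by default — can only improve on that baseline.

The proposal rule (single-bin, +-delta) is one concrete choice of randomized
line search; it is isolated behind ``propose`` so alternatives can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .inversion import FeatureVector
from .neuralnet import PredictiveModel, sigmoid_forward
from .spectra import MassSpectrum, normalize_spectrum


class RecoveryError(ValueError):
    """Raised for invalid recovery setups."""


@dataclass
class RecoveryResult:
    spectrum: MassSpectrum
    feature_sse: float
    sse_trajectory: np.ndarray
    accepted_moves: int


def _encode_vec(model: PredictiveModel, intensities: np.ndarray) -> np.ndarray:
    return sigmoid_forward(model.encoder_ms, intensities)[-1]


def feature_sse(model: PredictiveModel, intensities: np.ndarray, target: FeatureVector) -> float:
    d = _encode_vec(model, intensities) - target
    return float(d @ d)


def decode_baseline(model: PredictiveModel, x3: FeatureVector) -> MassSpectrum:
    """Decoder-half reconstruction of a feature, clipped to >= 0 and unit-max normalized."""
    if model.ms_decoder is None:
        raise RecoveryError("model carries no spectrum-autoencoder decoder")
    x3 = np.asarray(x3, dtype=float)
    if x3.shape != (model.feature_dim,):
        raise RecoveryError(f"feature has shape {x3.shape}, model expects ({model.feature_dim},)")
    out = sigmoid_forward(model.ms_decoder, x3)[-1]
    out = np.clip(out, 0.0, None)
    return normalize_spectrum(MassSpectrum("decoded", model.mz_start, out))


def _default_propose(
    intensities: np.ndarray, delta: float, rng: np.random.Generator
) -> np.ndarray:
    """Nudge one uniformly chosen bin by +-delta, clip to >= 0, renormalize to unit max."""
    cand = intensities.copy()
    j = int(rng.integers(len(cand)))
    cand[j] = max(0.0, cand[j] + delta * (1.0 if rng.random() < 0.5 else -1.0))
    peak = cand.max()
    if peak <= 0:
        return intensities
    return cand / peak


def recover_spectrum(
    model: PredictiveModel,
    target: FeatureVector,
    init: MassSpectrum | None = None,
    delta0: float = 0.5,
    delta_decay: float = 0.9999,
    n_iters: int = 100_000,
    rng: np.random.Generator | int | None = None,
    propose: Callable[[np.ndarray, float, np.random.Generator], np.ndarray] | None = None,
) -> RecoveryResult:
    """Greedy randomized line search for a spectrum encoding to ``target``.

    Step magnitude delta_tau = delta0 * delta_decay**tau; a proposal is
    accepted only if the feature-space SSE strictly decreases, so the
    trajectory (initial SSE followed by one value per iteration) is monotone
    non-increasing.  ``init`` defaults to the decoder baseline.
    """
    if delta0 <= 0:
        raise RecoveryError(f"delta0 must be positive, got {delta0}")
    if not (0 < delta_decay <= 1):
        raise RecoveryError(f"delta_decay must be in (0, 1], got {delta_decay}")
    if n_iters < 0:
        raise RecoveryError("n_iters must be nonnegative")
    target = np.asarray(target, dtype=float)
    if target.shape != (model.feature_dim,):
        raise RecoveryError(f"target feature has shape {target.shape}, model expects ({model.feature_dim},)")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if propose is None:
        propose = _default_propose

    if init is None:
        current = decode_baseline(model, target)
    else:
        if len(init.intensities) != model.ms_dim or init.mz_start != model.mz_start:
            raise RecoveryError(
                f"init spectrum grid (start {init.mz_start}, {len(init.intensities)} bins) "
                f"does not match model grid"
            )
        current = normalize_spectrum(init)
    x = current.intensities.copy()
    sse = feature_sse(model, x, target)
    traj = np.empty(n_iters + 1)
    traj[0] = sse
    accepted = 0
    for tau in range(n_iters):
        delta = delta0 * delta_decay**tau
        cand = propose(x, delta, rng)
        cand_sse = feature_sse(model, cand, target)
        if not np.isfinite(cand_sse):
            raise RecoveryError(f"non-finite feature SSE at iteration {tau + 1}")
        if cand_sse < sse:
            x, sse = cand, cand_sse
            accepted += 1
        traj[tau + 1] = sse
    spectrum = MassSpectrum("recovered", model.mz_start, x)
    return RecoveryResult(spectrum, sse, traj, accepted)
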