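"""Desk-scale synthetic fixtures with the statistical structure the method assumes.

Real inputs to the pipeline are a library of electron-ionization spectra and
a panel-averaged sensory table; this module fabricates both so every stage
runs and is testable offline.  Library spectra are sparse sticks — a handful
of peaks at random m/z positions with log-uniform intensities, base-peak
normalized — mimicking the dominant-base-peak-plus-minor-fragments shape of
EI spectra.  Sensory scores come from a *planted* ground-truth model: a small
random nine-layer sigmoid network mapping spectrum to 21 descriptor scores,
plus optional truncated Gaussian panel noise.  A pipeline trained on such a
world should recover the planted map, which is what the recovery tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neuralnet import MLPParams, PredictiveModel, compose_model, forward_output
from .sensory import DESCRIPTORS, SensoryDataset, SensoryProfile
from .spectra import DEFAULT_MZ_START, MassSpectrum, SpectrumLibrary


class SyntheticError(ValueError):
    """Raised for invalid generator settings."""


@dataclass
class SyntheticWorld:
    """A complete synthetic study: spectra, a planted truth map, and sensory data."""

    library: SpectrumLibrary
    planted_model: PredictiveModel
    sensory_dataset: SensoryDataset
    rng_seed: int
    noise_sd: float


def generate_library(
    n_molecules: int,
    n_bins: int = 212,
    n_peaks_range: tuple[int, int] = (5, 25),
    n_motifs: int = 15,
    rng: np.random.Generator | int | None = None,
    mz_start: int = DEFAULT_MZ_START,
    id_prefix: str = "mol",
) -> SpectrumLibrary:
    """Sparse nonnegative stick spectra sharing fragment motifs, unit-max normalized.

    Electron-ionization spectra of organic odorants are built from recurring
    fragment series (alkyl ions at 43/57/71..., aromatic ions at 77/91/105,
    and so on): molecules in one flavor library overlap heavily in peak
    positions, and that shared structure is what lets a spectrum predict an
    odor impression in the first place.  The generator mirrors this: it draws
    ``n_motifs`` sparse fragment patterns (4-8 peaks each, log-uniform
    intensities spanning two decades), and each molecule combines one to
    three motifs at Dirichlet-random proportions plus two faint
    molecule-specific peaks (intensity <= 0.1 after scaling) that make every
    spectrum linearly independent.  Support sizes are trimmed or padded into
    ``n_peaks_range``; the base peak is scaled to exactly 1.
    """
    if n_molecules < 1:
        raise SyntheticError("n_molecules must be >= 1")
    lo, hi = n_peaks_range
    if not (1 <= lo <= hi <= n_bins):
        raise SyntheticError(f"invalid n_peaks_range {n_peaks_range} for {n_bins} bins")
    if n_motifs < 1:
        raise SyntheticError("n_motifs must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    motifs = np.zeros((n_motifs, n_bins))
    for m in range(n_motifs):
        size = int(rng.integers(4, min(9, n_bins + 1)))
        pos = rng.choice(n_bins, size=size, replace=False)
        motifs[m, pos] = 10.0 ** rng.uniform(-2.0, 0.0, size=size)

    spectra = []
    for i in range(n_molecules):
        k = int(rng.integers(1, min(3, n_motifs) + 1))
        chosen = rng.choice(n_motifs, size=k, replace=False)
        vec = rng.dirichlet(np.ones(k)) @ motifs[chosen]
        # faint molecule-specific peaks: identifiability without drowning the motifs
        uniq = rng.choice(n_bins, size=2, replace=False)
        vec[uniq] += rng.uniform(0.01, 0.1, size=2) * vec.max()
        support = np.nonzero(vec)[0]
        if len(support) > hi:  # keep the strongest peaks
            drop = support[np.argsort(vec[support])[: len(support) - hi]]
            vec[drop] = 0.0
        elif len(support) < lo:  # pad with faint random peaks
            empty = np.setdiff1d(np.arange(n_bins), support)
            add = rng.choice(empty, size=lo - len(support), replace=False)
            vec[add] = rng.uniform(0.01, 0.1, size=len(add)) * vec.max()
        vec /= vec.max()
        spectra.append(MassSpectrum(f"{id_prefix}{i:04d}", mz_start, vec))
    return SpectrumLibrary(spectra)


def make_planted_model(
    n_bins: int = 212,
    rng: np.random.Generator | int | None = None,
    amplification: float = 1.2,
    output_bias_spread: float = 1.0,
    input_mean: np.ndarray | None = None,
    mz_start: int = DEFAULT_MZ_START,
) -> PredictiveModel:
    """A small random nine-layer spectrum -> impression map used as ground truth.

    A naive deep random sigmoid net washes out its input — every molecule
    maps to nearly the same scores, which would make correlation-based
    recovery checks meaningless.  Two measures keep the planted map
    input-sensitive: each layer's weight scale is set so signal variance is
    amplified by ``amplification`` per layer in the linear regime
    (sigma_w = 4*amplification/sqrt(n_in)), and each bias centers the
    preactivation at zero for mean-level inputs (``input_mean`` for the first
    layer, 0.5 for the rest) so neurons stay responsive instead of
    saturating.  Output-layer biases get an extra uniform
    (+-``output_bias_spread``) offset so descriptor base rates differ.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    sizes = [n_bins, 30, 16, 12, 14, 10, 8, 12, len(DESCRIPTORS)]
    if input_mean is None:
        # typical mean level of sparse unit-max stick spectra
        input_mean = np.full(n_bins, 0.015)
    center = np.asarray(input_mean, dtype=float)
    weights, biases = [], []
    for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        sigma = 4.0 * amplification / np.sqrt(n_in)
        bound = sigma * np.sqrt(3.0)
        w = rng.uniform(-bound, bound, size=(n_out, n_in))
        b = -w @ center
        if i == len(sizes) - 2:
            b = b + rng.uniform(-output_bias_spread, output_bias_spread, n_out)
        weights.append(w)
        biases.append(b)
        center = np.full(n_out, 0.5)
    stack = MLPParams(sizes, weights, biases)
    return compose_model(stack.slice(0, 2), stack.slice(2, 6), stack.slice(6, 8), mz_start=mz_start)


def generate_world(
    n_molecules: int = 100,
    noise_sd: float = 0.02,
    n_bins: int = 212,
    n_peaks_range: tuple[int, int] = (5, 25),
    seed: int = 0,
) -> SyntheticWorld:
    """Build a library, plant a truth model, and score every molecule.

    Sensory scores are the planted model's predictions plus Gaussian noise of
    sd ``noise_sd`` (default 0.02, a few percent of the unit score range, the
    size of residual panel-averaging error), clipped back into [0, 1].
    """
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    library = generate_library(n_molecules, n_bins=n_bins, n_peaks_range=n_peaks_range, rng=rng)
    planted = make_planted_model(
        n_bins=n_bins, rng=rng, input_mean=library.matrix().mean(axis=1), mz_start=library.mz_start
    )
    X = library.matrix().T
    scores = forward_output(planted.combined, X)
    if noise_sd > 0:
        scores = np.clip(scores + rng.normal(0.0, noise_sd, size=scores.shape), 0.0, 1.0)
    dataset = SensoryDataset(
        [SensoryProfile(mid, row) for mid, row in zip(library.ids, scores)],
        normalization_constant=1.0,
    )
    return SyntheticWorld(library, planted, dataset, rng_seed=seed, noise_sd=noise_sd)
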