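"""Nonnegative least-squares unmixing of a spectrum against a component library.

Because ion intensities superpose linearly in the mixing ratios, a (recovered)
mass spectrum can be expressed as a nonnegative combination of library
spectra: minimize ||A c - y||^2 subject to c >= 0, with A's columns the
component spectra.  The Lawson-Hanson active-set solver (scipy's ``nnls``)
returns exact zeros for non-contributors, so "how many molecules make up this
scent" is simply the number of strictly positive coefficients.  Errors are
reported both in raw spectrum space and — where a model is supplied — in the
autoencoder feature space, which is the scale the design pipeline optimizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .inversion import encode
from .neuralnet import PredictiveModel
from .spectra import MassSpectrum, SpectrumLibrary, SpectrumError, normalize_spectrum


@dataclass
class MixtureComposition:
    """NNLS coefficients over a library plus reconstruction errors."""

    component_ids: list[str]
    coefficients: np.ndarray
    raw_sse: float
    feature_sse: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (len(self.component_ids),):
            raise SpectrumError(
                f"{len(self.component_ids)} component ids but coefficient shape {c.shape}"
            )
        if np.any(c < 0):
            raise SpectrumError("NNLS coefficients must be nonnegative")
        object.__setattr__(self, "coefficients", c)

    def nonzero(self, eps: float = 0.0) -> dict[str, float]:
        """Contributing components and their mixing coefficients."""
        return {
            cid: float(c)
            for cid, c in zip(self.component_ids, self.coefficients)
            if c > eps
        }


def nnls_decompose(
    library: SpectrumLibrary,
    target: MassSpectrum,
    model: PredictiveModel | None = None,
    restrict_ids: Sequence[str] | None = None,
) -> MixtureComposition:
    """Least-squares mixture coefficients c >= 0 with ||A c - target|| minimal.

    ``restrict_ids`` solves over a sub-library (the remaining coefficients are
    reported as exact zeros), supporting noise reduction by dropping
    less-contributory molecules.  If ``model`` is given, the feature-space SSE
    between the normalized approximation and the normalized target is also
    reported.
    """
    if target.mz_start != library.mz_start or len(target.intensities) != library.n_bins:
        raise SpectrumError(
            f"target grid (start {target.mz_start}, {len(target.intensities)} bins) does not "
            f"match library grid (start {library.mz_start}, {library.n_bins} bins)"
        )
    ids = library.ids
    if restrict_ids is not None:
        active = [i for i, cid in enumerate(ids) if cid in set(restrict_ids)]
        if not active:
            raise SpectrumError("restriction excludes every library spectrum")
    else:
        active = list(range(len(ids)))
    A = library.matrix()[:, active]
    c_active, _ = nnls(A, target.intensities)
    # the solver can leave O(eps) dust where the active-set answer is an exact
    # zero; prune it so "contributor" keeps its strict meaning
    if c_active.max() > 0:
        c_active[c_active < 1e-10 * c_active.max()] = 0.0
    coeffs = np.zeros(len(ids))
    coeffs[active] = c_active
    resid = A @ c_active - target.intensities
    raw_sse = float(resid @ resid)
    feat_sse = None
    if model is not None:
        approx = approximate_spectrum(library, coeffs, id=f"approx:{target.id}")
        if approx.intensities.max() > 0 and target.intensities.max() > 0:
            feat_sse = feature_space_error(model, approx, target)
    return MixtureComposition(ids, coeffs, raw_sse, feat_sse)


def approximate_spectrum(library: SpectrumLibrary, coefficients: np.ndarray, id: str = "approx") -> MassSpectrum:
    """The mixture A c implied by a coefficient vector (raw scale, not renormalized)."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(library),):
        raise SpectrumError(f"need {len(library)} coefficients, got shape {coefficients.shape}")
    return MassSpectrum(id, library.mz_start, library.matrix() @ coefficients)


def count_contributors(comp: MixtureComposition, eps: float = 0.0) -> int:
    """Number of library molecules with coefficient strictly greater than eps."""
    if eps < 0:
        raise SpectrumError("eps must be nonnegative")
    return int(np.sum(comp.coefficients > eps))


def feature_space_error(model: PredictiveModel, approx: MassSpectrum, target: MassSpectrum) -> float:
    """Squared distance between encoded features of two spectra.

    Both spectra are base-peak normalized before encoding, matching how the
    autoencoder was trained.
    """
    fa = encode(model, normalize_spectrum(approx))
    ft = encode(model, normalize_spectrum(target))
    d = fa - ft
    return float(d @ d)
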