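"""Mass-spectrum data model, windowing, normalization, mixing, and library I/O.

Spectra are electron-ionization-style stick spectra binned on a contiguous
unit m/z grid.  The working window is the closed interval [51, 262]
(212 bins): below 51 solvent peaks dominate, above 262 fragments contribute
little to odor perception.  Bin ``i`` of a :class:`MassSpectrum` stores the
intensity at ``m/z = mz_start + i``; absent peaks are zero.  Because ion
counts add, the spectrum of a mixture is the linear superposition of the
component spectra weighted by the mixing ratios — the physical fact the whole
inverse-design pipeline rests on.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_MZ_START = 51
DEFAULT_MZ_END = 262
DEFAULT_N_BINS = DEFAULT_MZ_END - DEFAULT_MZ_START + 1  # 212


class SpectrumError(ValueError):
    """Raised for malformed spectra or library files."""


@dataclass
class MassSpectrum:
    """A nonnegative intensity vector on a contiguous unit m/z grid.

    Parameters
    ----------
    id : str
        Identifier, unique within a library.
    mz_start : int
        m/z value of the first bin.
    intensities : array-like of float
        One nonnegative intensity per unit m/z bin.
    """

    id: str
    mz_start: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise SpectrumError(f"spectrum {self.id!r}: intensities must be a nonempty 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise SpectrumError(f"spectrum {self.id!r}: non-finite intensity")
        if np.any(arr < 0):
            raise SpectrumError(f"spectrum {self.id!r}: negative intensity")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "mz_start", int(self.mz_start))

    @property
    def mz_end(self) -> int:
        return self.mz_start + len(self.intensities) - 1

    @property
    def mz(self) -> np.ndarray:
        """Integer m/z value of each bin."""
        return np.arange(self.mz_start, self.mz_end + 1)

    def copy(self, *, id: str | None = None) -> "MassSpectrum":
        return MassSpectrum(id if id is not None else self.id, self.mz_start, self.intensities.copy())


class SpectrumLibrary:
    """Ordered collection of :class:`MassSpectrum` sharing one m/z grid."""

    def __init__(self, spectra: Iterable[MassSpectrum]):
        spectra = list(spectra)
        if not spectra:
            raise SpectrumError("library must contain at least one spectrum")
        grid = (spectra[0].mz_start, len(spectra[0].intensities))
        index: dict[str, int] = {}
        for i, s in enumerate(spectra):
            if (s.mz_start, len(s.intensities)) != grid:
                raise SpectrumError(
                    f"spectrum {s.id!r} is on grid starting {s.mz_start} length "
                    f"{len(s.intensities)}, expected {grid[0]} length {grid[1]}"
                )
            if s.id in index:
                raise SpectrumError(f"duplicate spectrum id {s.id!r}")
            index[s.id] = i
        self._spectra = spectra
        self._index = index

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._spectra]

    @property
    def mz_start(self) -> int:
        return self._spectra[0].mz_start

    @property
    def n_bins(self) -> int:
        return len(self._spectra[0].intensities)

    def __len__(self) -> int:
        return len(self._spectra)

    def __iter__(self) -> Iterator[MassSpectrum]:
        return iter(self._spectra)

    def __getitem__(self, key: int | str) -> MassSpectrum:
        if isinstance(key, str):
            if key not in self._index:
                raise KeyError(f"no spectrum with id {key!r}")
            return self._spectra[self._index[key]]
        return self._spectra[key]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def matrix(self) -> np.ndarray:
        """Library as a dense array, shape (n_bins, n_spectra), one column per spectrum."""
        return np.stack([s.intensities for s in self._spectra], axis=1)

    def subset(self, ids: Sequence[str]) -> "SpectrumLibrary":
        return SpectrumLibrary([self[i].copy() for i in ids])

    def map(self, fn) -> "SpectrumLibrary":
        """Apply a spectrum -> spectrum function to every member."""
        return SpectrumLibrary([fn(s) for s in self._spectra])


def window_spectrum(s: MassSpectrum, lo: int = DEFAULT_MZ_START, hi: int = DEFAULT_MZ_END) -> MassSpectrum:
    """Restrict a spectrum to the closed m/z window [lo, hi], zero-filling outside its support."""
    if lo > hi:
        raise SpectrumError(f"invalid window: lo={lo} > hi={hi}")
    out = np.zeros(hi - lo + 1)
    src_lo = max(lo, s.mz_start)
    src_hi = min(hi, s.mz_end)
    if src_lo <= src_hi:
        out[src_lo - lo : src_hi - lo + 1] = s.intensities[src_lo - s.mz_start : src_hi - s.mz_start + 1]
    return MassSpectrum(s.id, lo, out)


def normalize_spectrum(s: MassSpectrum) -> MassSpectrum:
    """Base-peak normalization: divide by the spectrum's own maximum so max == 1."""
    peak = s.intensities.max()
    if peak <= 0:
        raise SpectrumError(f"spectrum {s.id!r} is all-zero and cannot be normalized")
    return MassSpectrum(s.id, s.mz_start, s.intensities / peak)


def mix_spectra(
    components: Sequence[MassSpectrum],
    ratios: Sequence[float],
    renormalize: bool = False,
    id: str = "mixture",
) -> MassSpectrum:
    """Linear superposition sum_i ratio_i * s_i of spectra on a common grid.

    With ``renormalize`` the combination is base-peak normalized, matching how
    model inputs are prepared; left raw it preserves the mixing-ratio scale
    needed for unmixing targets.
    """
    if len(components) == 0:
        raise SpectrumError("mix_spectra needs at least one component")
    if len(ratios) != len(components):
        raise SpectrumError(f"{len(components)} components but {len(ratios)} ratios")
    ratios_arr = np.asarray(ratios, dtype=float)
    if np.any(ratios_arr < 0):
        raise SpectrumError("mixing ratios must be nonnegative")
    if not np.any(ratios_arr > 0):
        raise SpectrumError("at least one mixing ratio must be positive")
    grid = (components[0].mz_start, len(components[0].intensities))
    for s in components:
        if (s.mz_start, len(s.intensities)) != grid:
            raise SpectrumError(f"component {s.id!r} is not on the common m/z grid")
    total = np.zeros(grid[1])
    for r, s in zip(ratios_arr, components):
        total += r * s.intensities
    mixed = MassSpectrum(id, grid[0], total)
    return normalize_spectrum(mixed) if renormalize else mixed


# ---------------------------------------------------------------------------
# Library I/O.  Two plain-text dialects:
#  * MSP: blocks of "NAME: <id>", optional metadata lines, "Num Peaks: n",
#    then n whitespace/semicolon-separated (m/z, intensity) pairs.
#  * CSV: one row per molecule ("id" column), one column per integer m/z bin.
# Intensities are stored on whatever scale the file declares; normalization
# is always an explicit separate step.
# ---------------------------------------------------------------------------

_PEAK_SPLIT = re.compile(r"[;\s]+")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("msp", "csv"):
        raise SpectrumError(f"unknown library format {fmt!r} (expected 'msp' or 'csv')")
    return fmt


def read_library(path: str | Path, format: str | None = None) -> SpectrumLibrary:
    """Read a spectrum library from an MSP or CSV file, preserving record order.

    The returned library is on the raw grid declared in the file; apply
    :func:`window_spectrum` / :func:`normalize_spectrum` explicitly afterwards.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "msp":
        return _read_msp(path)
    return _read_csv(path)


def _read_msp(path: Path) -> SpectrumLibrary:
    records: list[tuple[str, list[tuple[int, float]]]] = []
    name: str | None = None
    expected_peaks: int | None = None
    peaks: list[tuple[int, float]] = []

    def flush(lineno: int) -> None:
        nonlocal name, expected_peaks, peaks
        if name is None:
            return
        if expected_peaks is not None and len(peaks) != expected_peaks:
            raise SpectrumError(
                f"{path}:{lineno}: record {name!r} declares {expected_peaks} peaks but lists {len(peaks)}"
            )
        records.append((name, peaks))
        name, expected_peaks, peaks = None, None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(lineno)
                continue
            key, _, value = line.partition(":")
            key_l = key.strip().lower()
            if key_l == "name":
                flush(lineno)
                name = value.strip()
                if not name:
                    raise SpectrumError(f"{path}:{lineno}: empty NAME")
            elif key_l in ("num peaks", "numpeaks"):
                try:
                    expected_peaks = int(value)
                except ValueError:
                    raise SpectrumError(f"{path}:{lineno}: non-integer peak count {value.strip()!r}") from None
            elif name is not None and expected_peaks is not None:
                tokens = [t for t in _PEAK_SPLIT.split(line) if t]
                if len(tokens) % 2:
                    raise SpectrumError(f"{path}:{lineno}: odd number of peak values")
                for mz_tok, int_tok in zip(tokens[::2], tokens[1::2]):
                    try:
                        mz = int(round(float(mz_tok)))
                        inten = float(int_tok)
                    except ValueError:
                        raise SpectrumError(f"{path}:{lineno}: non-numeric peak entry {mz_tok!r} {int_tok!r}") from None
                    peaks.append((mz, inten))
            # other "Key: value" metadata lines are ignored
        flush(lineno if records or name else 0)

    if not records:
        raise SpectrumError(f"{path}: no spectra found")
    lo = min(mz for _, pk in records for mz, _ in pk)
    hi = max(mz for _, pk in records for mz, _ in pk)
    spectra = []
    seen: set[str] = set()
    for rec_name, pk in records:
        if rec_name in seen:
            raise SpectrumError(f"{path}: duplicate NAME {rec_name!r}")
        seen.add(rec_name)
        vec = np.zeros(hi - lo + 1)
        for mz, inten in pk:
            vec[mz - lo] += inten
        spectra.append(MassSpectrum(rec_name, lo, vec))
    return SpectrumLibrary(spectra)


def _read_csv(path: Path) -> SpectrumLibrary:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: CSV library needs an id column plus m/z columns")
    id_col = df.columns[0]
    try:
        mz_values = [int(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise SpectrumError(f"{path}: non-integer m/z column header: {exc}") from None
    if mz_values != list(range(mz_values[0], mz_values[0] + len(mz_values))):
        raise SpectrumError(f"{path}: m/z columns must form a contiguous unit grid")
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise SpectrumError(f"{path}: non-numeric or non-finite intensity value")
    spectra = [
        MassSpectrum(str(mol_id), mz_values[0], row) for mol_id, row in zip(df[id_col].astype(str), mat)
    ]
    return SpectrumLibrary(spectra)


def write_library(library: SpectrumLibrary, path: str | Path, format: str | None = None) -> None:
    """Write a library to MSP or CSV with 12 significant digits."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "msp":
        with open(path, "w") as fh:
            for s in library:
                nz = np.nonzero(s.intensities)[0]
                fh.write(f"NAME: {s.id}\n")
                fh.write(f"Num Peaks: {len(nz)}\n")
                for i in nz:
                    fh.write(f"{s.mz_start + i} {s.intensities[i]:.12g}\n")
                fh.write("\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            first = library[0]
            writer.writerow(["id"] + [str(m) for m in first.mz])
            for s in library:
                writer.writerow([s.id] + [f"{v:.12g}" for v in s.intensities])
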