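"""Odor-descriptor data model: per-subject averaging and dataset normalization.

Sensory panels score each molecule on 21 fixed perceptual descriptors
(pleasantness, intensity, and 19 semantic axes such as 'fruit' or 'sweet').
A subject who did not evaluate a descriptor contributes a score of 0, and the
panel average divides by the full panel size.  Because the predictive model
uses sigmoid outputs, the whole dataset is scaled into [0, 1] by one global
divisor — the maximum score anywhere in the table — and that constant is kept
so predictions can be mapped back to the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DESCRIPTORS: tuple[str, ...] = (
    "pleasantness",
    "intensity",
    "bakery",
    "sweet",
    "fruit",
    "fish",
    "garlic",
    "spices",
    "cold",
    "sour",
    "burnt",
    "acid",
    "warm",
    "musky",
    "sweaty",
    "ammonia/urinous",
    "decayed",
    "wood",
    "grass",
    "flower",
    "chemical",
)

N_DESCRIPTORS = len(DESCRIPTORS)
_DESC_INDEX = {d: i for i, d in enumerate(DESCRIPTORS)}


class SensoryError(ValueError):
    """Raised for malformed sensory data."""


def descriptor_index(name: str) -> int:
    if name not in _DESC_INDEX:
        raise SensoryError(f"unknown odor descriptor {name!r}")
    return _DESC_INDEX[name]


@dataclass
class SensoryProfile:
    """Scores of one molecule on the 21 descriptors, in fixed order."""

    molecule_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.shape != (N_DESCRIPTORS,):
            raise SensoryError(
                f"profile {self.molecule_id!r}: expected {N_DESCRIPTORS} scores, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise SensoryError(f"profile {self.molecule_id!r}: non-finite score")
        object.__setattr__(self, "scores", arr)

    def __getitem__(self, descriptor: str) -> float:
        return float(self.scores[descriptor_index(descriptor)])


class SensoryDataset:
    """Collection of profiles keyed by molecule id, with its normalization constant.

    ``normalization_constant`` is None for raw data and records the global
    divisor after :func:`normalize_dataset`.
    """

    def __init__(self, profiles: Iterable[SensoryProfile], normalization_constant: float | None = None):
        profiles = list(profiles)
        if not profiles:
            raise SensoryError("dataset must contain at least one profile")
        index: dict[str, int] = {}
        for i, p in enumerate(profiles):
            if p.molecule_id in index:
                raise SensoryError(f"duplicate molecule id {p.molecule_id!r}")
            index[p.molecule_id] = i
        self._profiles = profiles
        self._index = index
        self.normalization_constant = normalization_constant

    @property
    def ids(self) -> list[str]:
        return [p.molecule_id for p in self._profiles]

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[SensoryProfile]:
        return iter(self._profiles)

    def __getitem__(self, key: int | str) -> SensoryProfile:
        if isinstance(key, str):
            if key not in self._index:
                raise KeyError(f"no profile for molecule {key!r}")
            return self._profiles[self._index[key]]
        return self._profiles[key]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def matrix(self) -> np.ndarray:
        """Dataset as an array of shape (n_molecules, 21)."""
        return np.stack([p.scores for p in self._profiles], axis=0)

    def subset(self, ids: Sequence[str]) -> "SensoryDataset":
        return SensoryDataset([self[i] for i in ids], self.normalization_constant)


def average_subjects(
    records: pd.DataFrame | Iterable[tuple[str, str, str, float]],
    n_subjects: int,
) -> SensoryDataset:
    """Average long-form per-subject scores into one profile per molecule.

    ``records`` holds (molecule_id, subject_id, descriptor, score) rows; a
    descriptor a subject did not score counts as 0, so the average always
    divides by ``n_subjects`` regardless of how many rows a molecule has.
    """
    if n_subjects <= 0:
        raise SensoryError(f"n_subjects must be positive, got {n_subjects}")
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["molecule_id", "subject_id", "descriptor", "score"])
    else:
        records = records.rename(columns={c: c.lower() for c in records.columns})
    required = {"molecule_id", "subject_id", "descriptor", "score"}
    if not required.issubset(records.columns):
        raise SensoryError(f"long-form records need columns {sorted(required)}")
    unknown = set(records["descriptor"]) - set(DESCRIPTORS)
    if unknown:
        raise SensoryError(f"unknown odor descriptor(s): {sorted(unknown)}")
    if (records["score"] < 0).any():
        raise SensoryError("sensory scores must be nonnegative")

    profiles = []
    for mol_id, grp in records.groupby("molecule_id", sort=False):
        scores = np.zeros(N_DESCRIPTORS)
        sums = grp.groupby("descriptor")["score"].sum()
        for desc, total in sums.items():
            scores[_DESC_INDEX[desc]] = total / n_subjects
        profiles.append(SensoryProfile(str(mol_id), scores))
    return SensoryDataset(profiles)


def normalize_dataset(d: SensoryDataset) -> SensoryDataset:
    """Divide every score by the single global maximum over the whole dataset."""
    mat = d.matrix()
    peak = mat.max()
    if peak <= 0:
        raise SensoryError("all sensory scores are zero; cannot normalize")
    profiles = [SensoryProfile(p.molecule_id, p.scores / peak) for p in d]
    return SensoryDataset(profiles, normalization_constant=float(peak))


def read_sensory_csv(path: str | Path, form: str = "wide", n_subjects: int | None = None) -> SensoryDataset:
    """Read sensory data from CSV.

    ``form='wide'``: molecule rows x 21 descriptor columns (plus an id column).
    ``form='long'``: (molecule_id, subject_id, descriptor, score) rows,
    averaged with :func:`average_subjects` (``n_subjects`` required).
    """
    df = pd.read_csv(path)
    if form == "long":
        if n_subjects is None:
            raise SensoryError("long-form input needs n_subjects")
        return average_subjects(df, n_subjects)
    if form != "wide":
        raise SensoryError(f"unknown form {form!r}")
    id_col = df.columns[0]
    missing = [d for d in DESCRIPTORS if d not in df.columns]
    if missing:
        raise SensoryError(f"{path}: missing descriptor column(s) {missing}")
    profiles = [
        SensoryProfile(str(row[id_col]), row[list(DESCRIPTORS)].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]
    return SensoryDataset(profiles)


def write_sensory_csv(d: SensoryDataset, path: str | Path) -> None:
    """Write wide-form CSV: id column followed by the 21 descriptor columns."""
    df = pd.DataFrame(d.matrix(), columns=list(DESCRIPTORS))
    df.insert(0, "id", d.ids)
    df.to_csv(path, index=False, float_format="%.12g")
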