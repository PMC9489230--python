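"""Spectral dataset container and plain-text interchange.

A :class:`SpectraSet` is the universal currency of the toolkit: a uniform
wavelength grid, one reflectance row per leaf sample, the wet-chemistry
reference value (chlorophyll content, arbitrary units) and a domain label
(cultivar / instrument / batch).  CSV is the sole interchange format:
``sample_id, domain, reference_value, <430>, <431>, ... <2500>``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "read_spectra_csv", "write_spectra_csv", "trim_range"]

_META_COLUMNS = ("sample_id", "domain", "reference_value")


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the interchange contract."""


@dataclass
class SpectraSet:
    """Reflectance spectra on a uniform nm grid with per-sample metadata.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, uniformly spaced wavelength grid in nm.
    reflectance
        ``(n_samples, n_wavelengths)`` matrix.
    reference_value
        Measured reference quantity per sample (chlorophyll content).
    domain_label
        Categorical domain per sample (e.g. cultivar name).
    sample_id
        Unique identifier per sample.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    reference_value: np.ndarray
    domain_label: np.ndarray
    sample_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.reference_value = np.asarray(self.reference_value, dtype=float)
        self.domain_label = np.asarray(self.domain_label)
        if self.sample_id is None:
            self.sample_id = np.array([f"s{i:05d}" for i in range(self.n_samples)])
        else:
            self.sample_id = np.asarray(self.sample_id, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n, w = self.reflectance.shape
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size != w:
            raise SpectraFormatError(
                f"wavelength grid length {self.wavelengths_nm.size} != matrix width {w}"
            )
        diffs = np.diff(self.wavelengths_nm)
        if w > 1 and not np.all(diffs > 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if w > 2 and not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
            raise SpectraFormatError("wavelength grid must be uniformly spaced")
        for name, vec in (
            ("reference_value", self.reference_value),
            ("domain_label", self.domain_label),
            ("sample_id", self.sample_id),
        ):
            if len(vec) != n:
                raise SpectraFormatError(f"{name} length {len(vec)} != {n} samples")
        if np.isnan(self.reflectance).any():
            raise SpectraFormatError("reflectance contains NaN")
        ids, counts = np.unique(self.sample_id, return_counts=True)
        if (counts > 1).any():
            raise SpectraFormatError(f"duplicate sample ids: {ids[counts > 1][:5]}")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    @property
    def step_nm(self) -> float:
        if self.n_wavelengths < 2:
            return float("nan")
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def __len__(self) -> int:
        return self.n_samples

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SpectraSet":
        """Row subset (copy), preserving the wavelength grid."""
        idx = np.asarray(indices)
        if idx.dtype != bool:
            idx = idx.astype(int, copy=False)
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm.copy(),
            reflectance=self.reflectance[idx].copy(),
            reference_value=self.reference_value[idx].copy(),
            domain_label=self.domain_label[idx].copy(),
            sample_id=self.sample_id[idx].copy(),
        )

    def with_reflectance(self, matrix: np.ndarray,
                         wavelengths_nm: np.ndarray | None = None) -> "SpectraSet":
        """Same samples, new reflectance matrix (after preprocessing)."""
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraSet(
            wavelengths_nm=np.asarray(wl, float).copy(),
            reflectance=np.asarray(matrix, float).copy(),
            reference_value=self.reference_value.copy(),
            domain_label=self.domain_label.copy(),
            sample_id=self.sample_id.copy(),
        )

    @staticmethod
    def concat(sets: Sequence["SpectraSet"]) -> "SpectraSet":
        """Stack several sets sharing a wavelength grid."""
        first = sets[0]
        for s in sets[1:]:
            if not np.array_equal(s.wavelengths_nm, first.wavelengths_nm):
                raise SpectraFormatError("cannot concat sets on different grids")
        return SpectraSet(
            wavelengths_nm=first.wavelengths_nm.copy(),
            reflectance=np.vstack([s.reflectance for s in sets]),
            reference_value=np.concatenate([s.reference_value for s in sets]),
            domain_label=np.concatenate([s.domain_label for s in sets]),
            sample_id=np.concatenate([s.sample_id for s in sets]),
        )


def write_spectra_csv(data: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` in the interchange CSV layout."""
    cols = {c: getattr(data, a) for c, a in
            zip(_META_COLUMNS, ("sample_id", "domain_label", "reference_value"))}
    frame = pd.DataFrame(cols)
    wl_names = [_format_wavelength(w) for w in data.wavelengths_nm]
    frame = pd.concat(
        [frame, pd.DataFrame(data.reflectance, columns=wl_names)], axis=1
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def _format_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read the interchange CSV, validating layout and grid uniformity."""
    frame = pd.read_csv(path)
    for i, expected in enumerate(_META_COLUMNS):
        if i >= len(frame.columns) or frame.columns[i] != expected:
            got = frame.columns[i] if i < len(frame.columns) else "<missing>"
            raise SpectraFormatError(
                f"column {i} must be '{expected}', found '{got}'"
            )
    wl_cols = list(frame.columns[len(_META_COLUMNS):])
    if not wl_cols:
        raise SpectraFormatError("no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength column: {exc}") from exc
    return SpectraSet(
        wavelengths_nm=wavelengths,
        reflectance=frame[wl_cols].to_numpy(dtype=float),
        reference_value=frame["reference_value"].to_numpy(dtype=float),
        domain_label=frame["domain"].to_numpy(),
        sample_id=frame["sample_id"].to_numpy(dtype=object),
    )


def trim_range(data: SpectraSet, low_nm: float = 430.0,
               high_nm: float = 2500.0) -> SpectraSet:
    """Keep wavelengths within ``[low_nm, high_nm]`` (inclusive bounds).

    Mirrors the standard practice of discarding the noisy short-wavelength
    head of field spectroradiometer scans before modelling.
    """
    if low_nm > high_nm:
        raise ValueError(f"low_nm {low_nm} > high_nm {high_nm}")
    mask = (data.wavelengths_nm >= low_nm) & (data.wavelengths_nm <= high_nm)
    if not mask.any():
        raise ValueError(f"no wavelengths remain in [{low_nm}, {high_nm}]")
    return data.with_reflectance(
        data.reflectance[:, mask], wavelengths_nm=data.wavelengths_nm[mask]
    )
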