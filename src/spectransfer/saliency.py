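"""Gradient saliency for spectral regression models.

Which wavelengths does a trained network actually use?  The procedure:

1. keep only *correctly predicted samples* — relative prediction error
   within a threshold (default 5%, inclusive);
2. for each such sample, compute the gradient of the scalar output with
   respect to every input wavelength;
3. take each sample's top-``k`` wavelengths by absolute gradient
   (default 100; ties broken toward the lower wavelength);
4. count how often each wavelength appears — the frequency spectrum is
   the saliency map.

By construction ``sum(frequency) = n_correct × top_k`` whenever the
spectrum is at least ``top_k`` wide.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import SpectraSet

__all__ = ["SaliencyMap", "error_rate", "select_correct", "saliency_map",
           "band_mass_fraction"]


@dataclass
class SaliencyMap:
    wavelengths_nm: np.ndarray
    frequency: np.ndarray
    n_correct_samples: int
    error_rate_threshold: float = 5.0
    top_k: int = 100

    def top_wavelengths(self, k: int | None = None) -> np.ndarray:
        """Wavelengths ranked by frequency (ties: lower wavelength first)."""
        k = k if k is not None else self.top_k
        order = np.lexsort((self.wavelengths_nm, -self.frequency))
        return self.wavelengths_nm[order[:k]]


def error_rate(predicted: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """Signed relative prediction error in percent."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if np.any(m == 0):
        raise ValueError("measured value of 0 makes the error rate undefined")
    return (p - m) / m * 100.0


def select_correct(model, data: SpectraSet,
                   threshold: float = 5.0) -> np.ndarray:
    """Indices of samples with |relative error| ≤ threshold percent."""
    rates = error_rate(model.predict(data), data.reference_value)
    return np.flatnonzero(np.abs(rates) <= threshold)


def saliency_map(model, data: SpectraSet, threshold: float = 5.0,
                 top_k: int = 100) -> SaliencyMap:
    """Frequency of top-gradient wavelengths over correctly predicted samples.

    ``model`` must expose ``predict`` and ``input_gradients`` (a trained
    CNN).  Returns an all-zero map with a warning when no sample passes
    the error gate.
    """
    width = data.n_wavelengths
    if width < top_k:
        raise ValueError(f"spectrum width {width} < top_k {top_k}")
    correct = select_correct(model, data, threshold)
    freq = np.zeros(width, dtype=int)
    if correct.size == 0:
        warnings.warn("no correctly predicted samples; empty saliency map")
        return SaliencyMap(data.wavelengths_nm.copy(), freq, 0,
                           threshold, top_k)
    grads = model.input_gradients(data.subset(correct))
    mag = np.abs(grads)
    # descending |gradient|, ties toward the lower wavelength index:
    # stable argsort of -|g| preserves index order among equals
    ranked = np.argsort(-mag, axis=1, kind="stable")[:, :top_k]
    np.add.at(freq, ranked.ravel(), 1)
    return SaliencyMap(data.wavelengths_nm.copy(), freq, int(correct.size),
                       threshold, top_k)


def band_mass_fraction(smap: SaliencyMap,
                       intervals: list[tuple[float, float]]) -> float:
    """Fraction of total saliency frequency inside the given nm intervals."""
    total = smap.frequency.sum()
    if total == 0:
        return 0.0
    mask = np.zeros_like(smap.frequency, dtype=bool)
    for lo, hi in intervals:
        mask |= (smap.wavelengths_nm >= lo) & (smap.wavelengths_nm <= hi)
    return float(smap.frequency[mask].sum() / total)
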