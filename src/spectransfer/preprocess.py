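"""Spectral pretreatment operators and ordered pipelines.

Implements the four scatter/baseline corrections standard in chemometrics —
standard normal variate (SNV), multiplicative scatter correction (MSC),
polynomial detrending, and Savitzky–Golay first derivative (FD) — and the
eight named pipelines used throughout the toolkit::

    none, msc, snv, fd, msc+fd, snv+fd, fd+msc, fd+snv

Pipeline names read left to right in application order.  Stateful steps
(the MSC reference spectrum) are fitted on calibration data only and then
applied unchanged to validation / prediction / target-domain data, so no
information leaks across splits or domains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraSet

__all__ = [
    "snv", "msc", "detrend", "sg_fd",
    "PreprocessPipeline", "make_pipeline", "PIPELINE_NAMES",
]


class DegenerateSpectrumError(ValueError):
    pass


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum.

    Removes per-sample multiplicative scatter and additive offset.  Uses the
    sample standard deviation (divisor ``n−1``).
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero variance) at row(s) {bad[:5].tolist()}"
        )
    return (x - mean) / sd


def msc(spectra: np.ndarray,
        reference: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference by ordinary least
    squares, ``x ≈ â·ref + b̂``, and replaced by ``(x − b̂)/â``.  If no
    reference is given the column mean of ``spectra`` is used (and returned,
    so it can be reapplied to new data).
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != x.shape[1]:
        raise ValueError(f"reference length {ref.size} != width {x.shape[1]}")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateSpectrumError("zero-variance MSC reference spectrum")
    slope = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(slope == 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"MSC slope exactly zero at row(s) {bad[:5].tolist()}"
        )
    intercept = x.mean(axis=1) - slope * ref.mean()
    return (x - intercept[:, None]) / slope[:, None], ref


def detrend(spectra: np.ndarray, wavelengths: np.ndarray,
            order: int = 2) -> np.ndarray:
    """Subtract a per-spectrum least-squares polynomial baseline in λ."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if order < 1:
        raise ValueError("detrend order must be >= 1")
    if x.shape[1] <= order + 1:
        raise ValueError(
            f"need more than order+1={order + 1} wavelengths, have {x.shape[1]}"
        )
    # Shared Vandermonde basis: project every row onto it and subtract.
    wl = np.asarray(wavelengths, dtype=float)
    wl_s = (wl - wl.mean()) / (wl.std() or 1.0)  # scaled for conditioning
    basis = np.vander(wl_s, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
    return x - (basis @ coef).T


def sg_fd(spectra: np.ndarray, window: int = 15, polyorder: int = 2,
          step_nm: float = 1.0) -> np.ndarray:
    """Savitzky–Golay first derivative with respect to wavelength.

    Output has the same width as the input: the derivative is computed on
    the interior and the edge values are filled with the nearest valid
    interior value, preserving the network input-width contract.
    Units are reflectance per nm.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > x.shape[1]:
        raise ValueError(f"window {window} exceeds spectrum width {x.shape[1]}")
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    d = savgol_filter(x, window_length=window, polyorder=polyorder,
                      deriv=1, delta=step_nm, axis=1, mode="interp")
    half = window // 2
    d[:, :half] = d[:, [half]]
    d[:, -half:] = d[:, [-half - 1]]
    return d


# --------------------------------------------------------------------------
# pipelines

#: The eight pretreatment pipelines compared in cross-cultivar transfer.
PIPELINE_NAMES = ("none", "msc", "snv", "fd",
                  "msc+fd", "snv+fd", "fd+msc", "fd+snv")

_STEPS = {"none", "snv", "msc", "detrend", "fd", "sg_fd"}


@dataclass
class PreprocessPipeline:
    """Ordered pretreatment steps with fit/apply semantics.

    ``fit_apply`` fits stateful steps (the MSC reference) on the calibration
    set and transforms it; ``apply`` reuses the fitted state on any other
    set.  ``sg_window``/``sg_polyorder`` configure the FD smoothing stage;
    ``fd_mode='difference'`` replaces the SG derivative by a first
    difference after SG smoothing.
    """

    steps: tuple[str, ...]
    sg_window: int = 15
    sg_polyorder: int = 2
    detrend_order: int = 2
    fd_mode: str = "savgol"
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.steps = tuple(s.strip().lower() for s in self.steps)
        for s in self.steps:
            if s not in _STEPS:
                raise ValueError(f"unknown pretreatment step '{s}'")
        if self.fd_mode not in ("savgol", "difference"):
            raise ValueError("fd_mode must be 'savgol' or 'difference'")

    @property
    def name(self) -> str:
        active = [s for s in self.steps if s != "none"]
        return "+".join(s if s not in ("sg_fd",) else "fd" for s in active) or "none"

    def _run(self, matrix: np.ndarray, wavelengths: np.ndarray,
             fit: bool) -> np.ndarray:
        x = matrix
        step_nm = float(wavelengths[1] - wavelengths[0]) if len(wavelengths) > 1 else 1.0
        for s in self.steps:
            if s == "none":
                continue
            if s == "snv":
                x = snv(x)
            elif s == "msc":
                if fit:
                    x, self.msc_reference = msc(x, None)
                else:
                    if self.msc_reference is None:
                        raise RuntimeError("MSC step not fitted; call fit_apply first")
                    x, _ = msc(x, self.msc_reference)
            elif s == "detrend":
                x = detrend(x, wavelengths, order=self.detrend_order)
            elif s in ("fd", "sg_fd"):
                if self.fd_mode == "savgol":
                    x = sg_fd(x, self.sg_window, self.sg_polyorder, step_nm)
                else:
                    sm = savgol_filter(x, self.sg_window, self.sg_polyorder,
                                       axis=1, mode="interp")
                    d = np.diff(sm, axis=1) / step_nm
                    x = np.concatenate([d[:, [0]], d], axis=1)
        return x

    def fit_apply(self, fit_on: SpectraSet) -> SpectraSet:
        return fit_on.with_reflectance(
            self._run(fit_on.reflectance, fit_on.wavelengths_nm, fit=True)
        )

    def apply(self, data: SpectraSet) -> SpectraSet:
        return data.with_reflectance(
            self._run(data.reflectance, data.wavelengths_nm, fit=False)
        )

    def fit_apply_all(self, fit_on: SpectraSet,
                      *others: SpectraSet) -> list[SpectraSet]:
        """Fit on the first set, apply the identical transform to all sets."""
        for other in others:
            if not np.array_equal(other.wavelengths_nm, fit_on.wavelengths_nm):
                raise ValueError("all sets must share one wavelength grid")
        out = [self.fit_apply(fit_on)]
        out.extend(self.apply(o) for o in others)
        return out


def make_pipeline(name: str, **kwargs) -> PreprocessPipeline:
    """Build a pipeline from a row label like ``'FD + SNV'`` (case-insensitive).

    ``+`` separates steps; left-most is applied first.
    """
    label = name.strip().lower().replace(" ", "")
    steps = tuple(label.split("+")) if label else ("none",)
    return PreprocessPipeline(steps=steps, **kwargs)


def available_pipelines(**kwargs) -> dict[str, PreprocessPipeline]:
    """All eight standard pipelines keyed by canonical name."""
    return {n: make_pipeline(n, **kwargs) for n in PIPELINE_NAMES}


def iter_steps(names: Iterable[str]) -> tuple[str, ...]:
    return tuple(n.strip().lower() for n in names)
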