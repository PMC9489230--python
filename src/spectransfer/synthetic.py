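"""Two-domain synthetic leaf-reflectance generator.

Real paired-cultivar spectra are rarely public, so benchmarking a
calibration-transfer method needs a generator whose ground truth is known.
Each spectrum is a smooth continuum minus Gaussian absorption features.
*Informative* features have amplitudes monotone in the sample's chlorophyll
content (the red absorption valley near 670 nm and its green/red-edge
companions); *nuisance* features (water/protein bands in the NIR) are
independent of it.  The clean spectrum is then corrupted by the standard
Martens scatter model — per-sample multiplicative factor ``a`` and additive
offset ``b`` plus a smooth baseline tilt and i.i.d. noise — which is exactly
the corruption SNV/MSC/derivative pretreatments are designed to invert.

The target domain differs from the source by (i) shifted scatter
distributions, (ii) a small displacement of the informative peak centres,
and (iii) a mild quadratic nonlinearity in the chlorophyll-to-amplitude map,
emulating the between-cultivar shift that breaks a naively transferred model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import SpectraSet

__all__ = ["SyntheticConfig", "DomainShift", "generate", "ground_truth_bands"]


@dataclass
class DomainShift:
    """How the target domain deviates from the source.

    ``log_scatter_shift`` shifts the log-normal multiplicative scatter
    location; ``offset_shift`` the additive-offset mean; ``peak_shift_nm``
    displaces informative band centres; ``nonlinearity`` is the coefficient
    of the quadratic term in the chlorophyll→amplitude map.
    """

    log_scatter_shift: float = 0.08
    offset_shift: float = 0.01
    peak_shift_nm: float = 3.0
    nonlinearity: float = 0.15

    @classmethod
    def none(cls) -> "DomainShift":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a two-cultivar leaf study.

    The default grid is 430–2500 nm at 1 nm (2071 variables) and the default
    reference range 9.7–56.1 matches typical extract-chemistry chlorophyll
    values for field cotton leaves.
    """

    n_samples_per_domain: int = 600
    wavelength_start_nm: float = 430.0
    wavelength_end_nm: float = 2500.0
    step_nm: float = 1.0
    chl_range: tuple[float, float] = (9.7, 56.1)
    #: (center nm, width nm, amplitude sensitivity) absorption features whose
    #: depth grows with chlorophyll: red valley 670, green 550, red edge 715.
    informative_bands: Sequence[tuple[float, float, float]] = (
        (670.0, 12.0, 0.12),
        (550.0, 10.0, 0.06),
        (715.0, 18.0, 0.08),
    )
    #: chlorophyll-independent features: water bands near 1450/1940 nm and a
    #: protein/N band near 2200 nm, with per-sample random depth.
    nuisance_bands: Sequence[tuple[float, float, float]] = (
        (1450.0, 30.0, 0.05),
        (1940.0, 35.0, 0.08),
        (2200.0, 25.0, 0.04),
    )
    domain_shift: DomainShift = field(default_factory=DomainShift)
    scatter_log_sd: float = 0.08
    offset_sd: float = 0.01
    tilt_sd: float = 0.01
    noise_sd: float = 0.002
    seed: int = 0
    source_name: str = "source"
    target_name: str = "target"

    def validate(self) -> None:
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength_end_nm must exceed wavelength_start_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if not self.informative_bands:
            raise ValueError("informative_bands must be non-empty")
        lo, hi = self.chl_range
        if not lo < hi:
            raise ValueError("chl_range must be (min, max) with min < max")
        if self.n_samples_per_domain < 1:
            raise ValueError("n_samples_per_domain must be >= 1")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n = int(np.floor((self.wavelength_end_nm - self.wavelength_start_nm)
                         / self.step_nm)) + 1
        return self.wavelength_start_nm + self.step_nm * np.arange(n)


def _continuum(wl: np.ndarray) -> np.ndarray:
    # Logistic ramp ~0.1 in the visible to ~0.5 in the NIR: the gross shape of
    # a green-leaf reflectance curve without its absorption features.
    return 0.1 + 0.4 / (1.0 + np.exp(-(wl - 720.0) / 40.0))


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _clean_spectra(cfg: SyntheticConfig, chl: np.ndarray, rng: np.random.Generator,
                   *, peak_shift: float, nonlinearity: float) -> np.ndarray:
    wl = cfg.wavelengths_nm
    n = chl.size
    c_norm = chl / cfg.chl_range[1]  # in (0, 1]
    amp = c_norm + nonlinearity * c_norm ** 2
    spectra = np.tile(_continuum(wl), (n, 1))
    for center, width, sens in cfg.informative_bands:
        spectra -= np.outer(sens * amp, _gauss(wl, center + peak_shift, width))
    for center, width, sens in cfg.nuisance_bands:
        depth = sens * rng.uniform(0.5, 1.5, size=n)
        spectra -= np.outer(depth, _gauss(wl, center, width))
    return np.clip(spectra, 1e-6, 1.0)


def _corrupt(cfg: SyntheticConfig, spectra: np.ndarray, rng: np.random.Generator,
             *, log_scatter_shift: float, offset_shift: float) -> np.ndarray:
    n, w = spectra.shape
    wl01 = np.linspace(-1.0, 1.0, w)
    a = np.exp(rng.normal(log_scatter_shift, cfg.scatter_log_sd, size=n))
    b = rng.normal(offset_shift, cfg.offset_sd, size=n)
    tilt = (rng.normal(0.0, cfg.tilt_sd, size=(n, 1)) * wl01
            + rng.normal(0.0, cfg.tilt_sd / 2, size=(n, 1)) * wl01 ** 2)
    out = a[:, None] * (spectra + tilt) + b[:, None]
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, size=(n, w))
    return out


def generate(config: SyntheticConfig) -> tuple[SpectraSet, SpectraSet]:
    """Generate the (source, target) domain pair, deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths_nm
    lo, hi = config.chl_range
    sets = []
    for domain, shifted in ((config.source_name, False), (config.target_name, True)):
        n = config.n_samples_per_domain
        chl = rng.uniform(lo, hi, size=n)
        sh = config.domain_shift if shifted else DomainShift.none()
        clean = _clean_spectra(config, chl, rng,
                               peak_shift=sh.peak_shift_nm,
                               nonlinearity=sh.nonlinearity)
        refl = _corrupt(config, clean, rng,
                        log_scatter_shift=sh.log_scatter_shift,
                        offset_shift=sh.offset_shift)
        sets.append(SpectraSet(
            wavelengths_nm=wl.copy(),
            reflectance=refl,
            reference_value=chl,
            domain_label=np.array([domain] * n),
            sample_id=np.array([f"{domain}_{i:05d}" for i in range(n)], dtype=object),
        ))
    return sets[0], sets[1]


def ground_truth_bands(config: SyntheticConfig) -> list[tuple[float, float]]:
    """Oracle intervals ``center ± 2·width`` of the informative bands only.

    Used to validate wavelength-attribution methods: a saliency map that has
    learned the chlorophyll signal should concentrate inside these intervals.
    """
    config.validate()
    return [(c - 2.0 * w, c + 2.0 * w) for c, w, _ in config.informative_bands]
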