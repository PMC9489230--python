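"""Outlier screening for spectra and reference values.

Two detectors, whose union defines removal:

* **PCA + Hotelling T²** on the mean-centred reflectance: samples whose T²
  over the retained principal components exceeds the F-distribution limit
  at the chosen confidence are flagged.
* **Boxplot fences** on the reference values (optionally on PCA scores):
  values outside ``[Q1 − k·IQR, Q3 + k·IQR]`` are flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .dataset import SpectraSet

__all__ = ["OutlierReport", "hotelling_t2", "boxplot_outliers", "combined_outliers"]


@dataclass
class OutlierReport:
    flagged_ids: list
    flagged_indices: np.ndarray
    t2_values: np.ndarray | None = None
    t2_limit: float | None = None
    boxplot_bounds: tuple[float, float] | None = None
    n_components: int | None = None
    confidence: float | None = None

    def as_dict(self) -> dict:
        return {
            "flagged_ids": [str(i) for i in self.flagged_ids],
            "n_flagged": int(self.flagged_indices.size),
            "t2_limit": self.t2_limit,
            "boxplot_bounds": self.boxplot_bounds,
            "n_components": self.n_components,
            "confidence": self.confidence,
        }


def _pick_components(explained_ratio: np.ndarray, min_explained: float,
                     cap: int) -> int:
    cum = np.cumsum(explained_ratio)
    k = int(np.searchsorted(cum, min_explained) + 1)
    return min(k, cap, explained_ratio.size)


def hotelling_t2(data: SpectraSet, n_components: int | None = None,
                 confidence: float = 0.99, min_explained: float = 0.95,
                 max_components: int = 10) -> OutlierReport:
    """Flag samples with extreme Hotelling T² on PCA scores.

    If ``n_components`` is not given, the smallest count explaining
    ``min_explained`` of the variance is used, capped at
    ``max_components``.  The control limit is
    ``k(n²−1)/(n(n−k)) · F(confidence; k, n−k)``.
    """
    n = data.n_samples
    if n_components is not None and n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components is not None and n_components >= min(n, data.n_wavelengths):
        raise ValueError(
            f"n_components={n_components} must be < min(samples, wavelengths)"
        )
    full = PCA(n_components=min(n - 1, data.n_wavelengths, 30))
    scores = full.fit_transform(data.reflectance)
    k = n_components or _pick_components(full.explained_variance_ratio_,
                                         min_explained, max_components)
    score_var = scores[:, :k].var(axis=0, ddof=1)
    t2 = np.sum(scores[:, :k] ** 2 / score_var, axis=1)
    f_crit = stats.f.ppf(confidence, k, n - k)
    limit = k * (n ** 2 - 1) / (n * (n - k)) * f_crit
    flagged = np.flatnonzero(t2 > limit)
    return OutlierReport(
        flagged_ids=list(data.sample_id[flagged]),
        flagged_indices=flagged,
        t2_values=t2, t2_limit=float(limit),
        n_components=k, confidence=confidence,
    )


def boxplot_outliers(values: np.ndarray, k: float = 1.5,
                     sample_id: np.ndarray | None = None) -> OutlierReport:
    """Flag values outside the Tukey fences ``[Q1 − k·IQR, Q3 + k·IQR]``."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError(f"need at least 4 values, have {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    flagged = np.flatnonzero((v < lower) | (v > upper))
    ids = sample_id[flagged] if sample_id is not None else flagged
    return OutlierReport(
        flagged_ids=list(ids), flagged_indices=flagged,
        boxplot_bounds=(float(lower), float(upper)),
    )


def combined_outliers(data: SpectraSet, n_components: int | None = None,
                      confidence: float = 0.99, k: float = 1.5,
                      boxplot_on: str = "reference") -> OutlierReport:
    """Union of the T² and boxplot detectors.

    ``boxplot_on`` selects what the fences screen: the reference values
    (default) or the first principal-component scores (``'scores'``).
    """
    t2_rep = hotelling_t2(data, n_components=n_components, confidence=confidence)
    if boxplot_on == "reference":
        box_values = data.reference_value
    elif boxplot_on == "scores":
        box_values = PCA(n_components=1).fit_transform(data.reflectance).ravel()
    else:
        raise ValueError("boxplot_on must be 'reference' or 'scores'")
    box_rep = boxplot_outliers(box_values, k=k, sample_id=data.sample_id)
    flagged = np.union1d(t2_rep.flagged_indices, box_rep.flagged_indices)
    return OutlierReport(
        flagged_ids=list(data.sample_id[flagged]),
        flagged_indices=flagged,
        t2_values=t2_rep.t2_values, t2_limit=t2_rep.t2_limit,
        boxplot_bounds=box_rep.boxplot_bounds,
        n_components=t2_rep.n_components, confidence=confidence,
    )
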