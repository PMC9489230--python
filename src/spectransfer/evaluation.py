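"""Dataset splits, regression metrics and experiment protocols.

The split schemes are the rank-ordered interleavings standard in
chemometrics (Kennard-Stone-like coverage without the distance machinery):
sort samples by the reference value and deal consecutive runs into the
splits, so every split spans the full reference range.

* ``rank_split_2to1`` — within each consecutive triple of the sorted
  samples, the 1st and 3rd go to calibration and the 2nd to prediction;
  leftovers go to calibration.  Pooling two domains of 769 samples each
  therefore yields calibration/prediction sizes 1026/512.
* ``rank_split_3to1to1`` — within each consecutive quintet, positions
  {1, 3, 5} go to calibration, {2} to validation and {4} to prediction;
  leftovers to calibration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet

__all__ = ["MetricsReport", "SplitAssignment", "metrics",
           "rank_split_2to1", "rank_split_3to1to1", "half_calibration",
           "architecture_sweep", "chl_from_absorbance",
           "ETHANOL95_COEFFICIENTS"]


@dataclass
class MetricsReport:
    """R² and RMSE for one split. ``r2`` is ``nan`` when undefined."""

    r2: float
    rmse: float
    split_name: str = ""
    n: int = 0

    def as_dict(self) -> dict:
        return {"split": self.split_name, "n": self.n,
                "r2": self.r2, "rmse": self.rmse}


def metrics(predicted: np.ndarray, measured: np.ndarray,
            split_name: str = "", r2_mode: str = "ss") -> MetricsReport:
    """RMSE and coefficient of determination.

    ``r2_mode='ss'`` (default) uses ``1 − SS_res/SS_tot`` (can be negative);
    ``'pearson2'`` the squared Pearson correlation.  Zero-variance measured
    values yield ``r2 = nan`` with RMSE still computed.
    """
    p = np.asarray(predicted, float).ravel()
    m = np.asarray(measured, float).ravel()
    if p.size != m.size or p.size == 0:
        raise ValueError(f"length mismatch or empty: {p.size} vs {m.size}")
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        r2 = float("nan")
    elif r2_mode == "ss":
        r2 = 1.0 - float(np.sum((p - m) ** 2)) / ss_tot
    elif r2_mode == "pearson2":
        r2 = float(np.corrcoef(p, m)[0, 1] ** 2)
    else:
        raise ValueError("r2_mode must be 'ss' or 'pearson2'")
    return MetricsReport(r2=r2, rmse=rmse, split_name=split_name, n=p.size)


@dataclass
class SplitAssignment:
    """Disjoint index sets whose union is the full sample range."""

    scheme: str
    calibration: np.ndarray
    prediction: np.ndarray
    validation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    seed: int = 0

    def splits(self) -> dict[str, np.ndarray]:
        out = {"calibration": self.calibration}
        if self.validation.size:
            out["validation"] = self.validation
        out["prediction"] = self.prediction
        return out


def _rank_order(data: SpectraSet) -> np.ndarray:
    return np.argsort(data.reference_value, kind="stable")


def rank_split_2to1(data: SpectraSet) -> SplitAssignment:
    """2:1 calibration/prediction split on reference-sorted samples."""
    n = data.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, have {n}")
    order = _rank_order(data)
    pos = np.arange(n) % 3
    leftover = np.arange(n) >= n - n % 3
    cal = order[(pos != 1) | leftover]
    pred = order[(pos == 1) & ~leftover]
    return SplitAssignment("rank_2to1", calibration=np.sort(cal),
                           prediction=np.sort(pred))


def rank_split_3to1to1(data: SpectraSet, seed: int = 0) -> SplitAssignment:
    """3:1:1 calibration/validation/prediction split on sorted samples.

    The in-quintet pattern (cal, val, cal, pred, cal) may be cyclically
    rotated by ``seed % 5`` to vary which rank positions land where; the
    split sizes are unaffected.
    """
    n = data.n_samples
    if n < 5:
        raise ValueError(f"need at least 5 samples, have {n}")
    order = _rank_order(data)
    pattern = np.array(["c", "v", "c", "p", "c"])
    pattern = np.roll(pattern, seed % 5)
    pos = pattern[np.arange(n) % 5]
    leftover = np.arange(n) >= n - n % 5
    cal = order[(pos == "c") | leftover]
    val = order[(pos == "v") & ~leftover]
    pred = order[(pos == "p") & ~leftover]
    return SplitAssignment("rank_3to1to1", calibration=np.sort(cal),
                           prediction=np.sort(pred), validation=np.sort(val),
                           seed=seed)


def half_calibration(data: SpectraSet, split: SplitAssignment,
                     seed: int = 0) -> SplitAssignment:
    """Retain a rank-stratified half of the calibration set.

    The calibration indices are sorted by reference value; one sample per
    consecutive pair is kept at random (seeded), plus any leftover, so the
    reduced set still covers the full reference range.  Validation and
    prediction sets are untouched.
    """
    cal = split.calibration
    if cal.size < 2:
        raise ValueError("calibration set must have at least 2 samples")
    rng = np.random.default_rng(seed)
    by_rank = cal[np.argsort(data.reference_value[cal], kind="stable")]
    n_pairs = cal.size // 2
    pick = rng.integers(0, 2, size=n_pairs)
    kept = [by_rank[2 * i + pick[i]] for i in range(n_pairs)]
    kept.extend(by_rank[2 * n_pairs:])
    return SplitAssignment(split.scheme + "+half", calibration=np.sort(kept),
                           prediction=split.prediction.copy(),
                           validation=split.validation.copy(), seed=seed)


def architecture_sweep(arch_names: list[str], source: SpectraSet,
                       target: SpectraSet, train_cfg, transfer_cfg=None,
                       n_runs: int = 10, n_best: int = 3, seed: int = 0,
                       split_seed: int = 0) -> list[dict]:
    """Pretrain + fine-tune each architecture ``n_runs`` times.

    Per architecture the ``n_best`` smallest target-prediction RMSEs are
    averaged — a protocol robust to the run-to-run variance of small-data
    CNN training.  Returns one report row per architecture, in input order.
    """
    from .transfer import TransferConfig, transfer_experiment  # lazy: avoid cycle

    if n_runs < n_best:
        raise ValueError(f"need at least {n_best} runs, got {n_runs}")
    transfer_cfg = transfer_cfg or TransferConfig()
    rows = []
    for arch in arch_names:
        rmses, r2s = [], []
        for run in range(n_runs):
            result = transfer_experiment(
                arch, source, target, train_cfg, transfer_cfg,
                seed=seed + 1000 * run, split_seed=split_seed,
            )
            rep = result.target_reports["prediction"]
            rmses.append(rep.rmse)
            r2s.append(rep.r2)
        best = np.argsort(rmses)[:n_best]
        rows.append({
            "architecture": arch,
            "rmse_mean_best": float(np.mean([rmses[i] for i in best])),
            "r2_mean_best": float(np.mean([r2s[i] for i in best])),
            "rmse_all": rmses,
        })
    return rows


#: Chlorophyll/carotenoid coefficients for 95% ethanol extracts
#: (Lichtenthaler & Wellburn convention): contents in µg/mL from
#: absorbances at 665, 649 and 470 nm.
ETHANOL95_COEFFICIENTS = {
    "chl_a": {"a665": 13.95, "a649": -6.88},
    "chl_b": {"a649": 24.96, "a665": -7.32},
}


def chl_from_absorbance(a470: float, a649: float, a665: float,
                        coefficients: dict | None = None) -> dict[str, float]:
    """Chlorophyll a, b and total from extract absorbances.

    The coefficient set is configuration data (defaults: the 95%-ethanol
    literature values above); ``a470`` is accepted for completeness of the
    assay triple (it enters carotenoid formulas, not the chlorophylls).
    """
    for name, val in (("a470", a470), ("a649", a649), ("a665", a665)):
        if val < 0:
            raise ValueError(f"negative absorbance {name}={val}")
    coefs = coefficients or ETHANOL95_COEFFICIENTS
    values = {"a470": a470, "a649": a649, "a665": a665}
    chl_a = sum(c * values[k] for k, c in coefs["chl_a"].items())
    chl_b = sum(c * values[k] for k, c in coefs["chl_b"].items())
    return {"chl_a": chl_a, "chl_b": chl_b, "chl_total": chl_a + chl_b}
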