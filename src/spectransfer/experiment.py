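"""End-to-end reproducible experiments bound to a plain-text config.

``run_experiment`` executes the full chain — generate (or load) → outlier
screen → split → pretreat → pretrain → fine-tune → evaluate → saliency —
and writes every report as JSON/CSV with a provenance header (config hash,
seed, package version), so re-running the same config reproduces the same
files.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cnn import TrainConfig
from .dataset import SpectraSet, read_spectra_csv, trim_range
from .outliers import combined_outliers
from .preprocess import PIPELINE_NAMES, make_pipeline
from .saliency import band_mass_fraction, saliency_map
from .synthetic import SyntheticConfig, generate, ground_truth_bands
from .transfer import TransferConfig, transfer_experiment

log = logging.getLogger("spectransfer")

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Declarative description of one transfer experiment."""

    seed: int = 0
    source_csv: str | None = None
    target_csv: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    trim: tuple[float, float] | None = None
    remove_outliers: bool = True
    pretreat: str = "fd+snv"
    arch: str = "cnn1"
    train: TrainConfig = field(default_factory=TrainConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    saliency_threshold: float = 5.0
    saliency_top_k: int = 100
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__)
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown config key '{key}'")
            if key == "synthetic":
                cfg.synthetic = SyntheticConfig(**value)
            elif key == "train":
                cfg.train = TrainConfig(**value)
            elif key == "transfer":
                ft = value.pop("ft_train_config", None)
                cfg.transfer = TransferConfig(**value)
                if ft:
                    cfg.transfer.ft_train_config = TrainConfig(**ft)
            elif key == "trim":
                cfg.trim = tuple(value) if value else None
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.pretreat.lower().replace(" ", "") not in PIPELINE_NAMES:
            raise ValueError(
                f"unknown pretreat '{self.pretreat}'; choose from {PIPELINE_NAMES}"
            )
        for path in (self.source_csv, self.target_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        self.train.validate()
        self.transfer.validate()

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            return str(o)
        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(cfg: ExperimentConfig) -> dict:
    return {"config_hash": cfg.digest(), "seed": cfg.seed,
            "version": __version__}


def _load_domains(cfg: ExperimentConfig) -> tuple[SpectraSet, SpectraSet]:
    if cfg.source_csv and cfg.target_csv:
        src = read_spectra_csv(cfg.source_csv)
        tgt = read_spectra_csv(cfg.target_csv)
    else:
        syn = cfg.synthetic
        syn.seed = cfg.seed
        src, tgt = generate(syn)
    if cfg.trim:
        src = trim_range(src, *cfg.trim)
        tgt = trim_range(tgt, *cfg.trim)
    return src, tgt


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full pipeline; returns (and writes) the result bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": _provenance(cfg)}

    log.info("stage: load/generate domains")
    source, target = _load_domains(cfg)

    if cfg.remove_outliers:
        log.info("stage: outlier screen")
        reports = {}
        cleaned = []
        for name, dom in (("source", source), ("target", target)):
            rep = combined_outliers(dom)
            keep = np.setdiff1d(np.arange(dom.n_samples), rep.flagged_indices)
            cleaned.append(dom.subset(keep))
            reports[name] = rep.as_dict()
        source, target = cleaned
        bundle["outliers"] = reports

    log.info("stage: pretreat (%s) + pretrain (%s) + fine-tune",
             cfg.pretreat, cfg.arch)
    pipeline = make_pipeline(cfg.pretreat)
    result = transfer_experiment(cfg.arch, source, target, cfg.train,
                                 cfg.transfer, seed=cfg.seed,
                                 pipeline=pipeline)
    bundle["transfer"] = result.as_dict()

    log.info("stage: saliency")
    t_pred_idx = result.target_split.splits()["prediction"]
    t_pred = pipeline.apply(target.subset(t_pred_idx))
    smap = saliency_map(result.fine_tuned, t_pred,
                        threshold=cfg.saliency_threshold,
                        top_k=min(cfg.saliency_top_k, t_pred.n_wavelengths))
    sal = {"n_correct": smap.n_correct_samples,
           "top_k": smap.top_k,
           "total_frequency": int(smap.frequency.sum())}
    if not (cfg.source_csv and cfg.target_csv):
        sal["informative_band_mass"] = band_mass_fraction(
            smap, ground_truth_bands(cfg.synthetic))
    bundle["saliency"] = sal

    (out / "experiment.json").write_text(
        json.dumps(bundle, indent=2, default=float) + "\n")
    freq_csv = out / "saliency_frequency.csv"
    with freq_csv.open("w") as fh:
        fh.write("wavelength_nm,frequency\n")
        for wl, fr in zip(smap.wavelengths_nm, smap.frequency):
            fh.write(f"{wl:g},{fr}\n")
    log.info("wrote %s", out / "experiment.json")
    return bundle
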