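"""Cross-domain model transfer: fine-tuning and classical standardization.

The main route is **fine-tuning**: a CNN pretrained on the source cultivar
continues training on the target calibration set with everything frozen
except the last two fully connected layers (the 32-node layer and the
output node by default).  Because the frozen prefix is fixed, its
activations are precomputed once and only the trainable suffix is
optimised, which makes fine-tuning cheap.

Two classical calibration-transfer baselines are included:

* **DS (direct standardization)** — a ridge-stabilized least-squares matrix
  mapping target-domain spectra into the source space, fitted on standard
  samples paired across domains by reference-value rank (unpaired cultivar
  samples cannot be physically matched; rank is the only order statistic
  the domains share).
* **TCA (transfer component analysis)** — a kernel eigenproblem finding a
  shared subspace that minimizes the maximum mean discrepancy (MMD)
  between the projected domains while preserving variance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from . import nn
from .cnn import CNNRegressor, TrainConfig, build, train, _fit_network
from .dataset import SpectraSet
from .evaluation import (MetricsReport, SplitAssignment, metrics,
                         rank_split_3to1to1)
from .preprocess import PreprocessPipeline

__all__ = ["TransferConfig", "TransferResult", "fine_tune", "size_sweep",
           "DSTransform", "ds_fit", "TCATransform", "tca_fit", "mmd",
           "transfer_experiment", "stratified_subsample"]


@dataclass
class TransferConfig:
    """Fine-tuning settings.

    ``trainable_fc_layers`` counts trainable Dense layers from the output
    backwards (2 = the last hidden FC layer plus the output node).
    ``target_fraction`` subsamples the target calibration set
    (rank-stratified, seeded).  Batch size drops to 32 automatically when
    the subsample is smaller than 64 unless overridden.
    """

    trainable_fc_layers: int = 2
    target_fraction: float = 1.0
    batch_size_override: int | None = None
    ft_train_config: TrainConfig = field(
        default_factory=lambda: TrainConfig(initial_lr=0.0005))
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must be in (0, 1]")
        if self.trainable_fc_layers < 1:
            raise ValueError("trainable_fc_layers must be >= 1")


def stratified_subsample(reference: np.ndarray, fraction: float,
                         seed: int) -> np.ndarray:
    """Rank-stratified subsample: one draw per contiguous rank block."""
    n = reference.size
    k = max(1, int(round(fraction * n)))
    if k >= n:
        return np.arange(n)
    order = np.argsort(reference, kind="stable")
    rng = np.random.default_rng(seed)
    picks = [blk[rng.integers(0, blk.size)]
             for blk in np.array_split(order, k)]
    return np.sort(np.asarray(picks))


def _freeze_for_fine_tuning(net: nn.Network, trainable_fc: int) -> int:
    """Freeze all layers except the trailing ``trainable_fc`` Dense layers.

    Returns the index of the first trainable layer.
    """
    dense_idx = [i for i, l in enumerate(net.layers) if isinstance(l, nn.Dense)]
    if trainable_fc > len(dense_idx):
        raise ValueError(
            f"model has only {len(dense_idx)} fully connected layers"
        )
    first_trainable = dense_idx[-trainable_fc]
    for i, layer in enumerate(net.layers):
        layer.frozen = i < first_trainable
    return first_trainable


def fine_tune(pretrained: CNNRegressor, target_cal: SpectraSet,
              cfg: TransferConfig,
              val_set: SpectraSet | None = None) -> CNNRegressor:
    """Fine-tune a pretrained CNN on (a fraction of) the target calibration set.

    The pretrained model is left untouched; a clone is returned.  Frozen
    parameters are bit-identical before and after.  The output bias is not
    re-initialised — fine-tuning resumes from the pretrained weights.
    """
    if not pretrained.trained:
        raise ValueError("fine_tune requires a trained model")
    cfg.validate()
    keep = stratified_subsample(target_cal.reference_value,
                                cfg.target_fraction, cfg.seed)
    if keep.size == 0:
        raise ValueError("empty fine-tuning subsample")
    sub = target_cal.subset(keep)

    model = pretrained.clone()
    net = model.network
    first_trainable = _freeze_for_fine_tuning(net, cfg.trainable_fc_layers)

    ft_cfg = replace(cfg.ft_train_config)
    if cfg.batch_size_override is not None:
        ft_cfg.batch_size = cfg.batch_size_override
    elif sub.n_samples < 64:
        ft_cfg.batch_size = 32

    # frozen prefix is deterministic (inference-mode BN): precompute features
    prefix = nn.Network(net.layers[:first_trainable])
    suffix = nn.Network(net.layers[first_trainable:])

    def features(s: SpectraSet) -> np.ndarray:
        x = model._as_input(s).astype(np.float32)
        outs = [prefix.forward(x[i:i + 256], train=False)
                for i in range(0, x.shape[0], 256)]
        return np.concatenate(outs) if outs else np.empty((0,))

    f_train = features(sub)
    y_train = sub.reference_value.astype(np.float32)
    if val_set is not None:
        f_val = features(val_set)
        y_val = val_set.reference_value.astype(np.float32)
    else:
        f_val = np.empty((0,) + f_train.shape[1:], dtype=np.float32)
        y_val = np.empty(0, dtype=np.float32)

    history = _fit_network(suffix, f_train, y_train, f_val, y_val, ft_cfg)
    model.history = history
    model.trained = True
    return model


def size_sweep(pretrained: CNNRegressor, target_cal: SpectraSet,
               target_val: SpectraSet, target_pred: SpectraSet,
               fractions: list[float], cfg: TransferConfig | None = None,
               seed: int = 0) -> list[dict]:
    """Fine-tune once per calibration fraction with fixed val/pred sets."""
    cfg = cfg or TransferConfig()
    rows = []
    for frac in fractions:
        run_cfg = replace(cfg, target_fraction=frac, seed=seed)
        tuned = fine_tune(pretrained, target_cal, run_cfg, val_set=target_val)
        rows.append({
            "fraction": frac,
            "n_finetune": int(max(1, round(frac * target_cal.n_samples))),
            "calibration": metrics(tuned.predict(target_cal),
                                   target_cal.reference_value, "calibration"),
            "validation": metrics(tuned.predict(target_val),
                                  target_val.reference_value, "validation"),
            "prediction": metrics(tuned.predict(target_pred),
                                  target_pred.reference_value, "prediction"),
        })
    return rows


# --------------------------------------------------------------------------
# direct standardization

@dataclass
class DSTransform:
    """Spectra-space linear map from target to source domain."""

    transformation_matrix: np.ndarray
    n_standards: int
    pairing: str = "reference_rank"

    def apply(self, data: SpectraSet) -> SpectraSet:
        return data.with_reflectance(data.reflectance @ self.transformation_matrix)


def ds_fit(source_cal: SpectraSet, target_cal: SpectraSet,
           n_standards: int = 100, seed: int = 0,
           ridge: float = 1e-6) -> DSTransform:
    """Fit the DS transformation matrix on rank-paired standard samples.

    ``n_standards`` samples are drawn from each domain (seeded), sorted by
    reference value, and paired rank-to-rank.  The matrix ``F`` solves
    ``T·F ≈ S`` in ridge-stabilized least squares (``ridge`` scales the
    penalty by ``trace(TᵀT)/p``; 0 recovers the classical pseudo-inverse).
    """
    for name, s in (("source", source_cal), ("target", target_cal)):
        if s.n_samples < n_standards:
            raise ValueError(
                f"{name} set has {s.n_samples} samples < n_standards={n_standards}"
            )
    rng = np.random.default_rng(seed)
    idx_s = rng.choice(source_cal.n_samples, n_standards, replace=False)
    idx_t = rng.choice(target_cal.n_samples, n_standards, replace=False)
    src = source_cal.subset(idx_s)
    tgt = target_cal.subset(idx_t)
    s_mat = src.reflectance[np.argsort(src.reference_value, kind="stable")]
    t_mat = tgt.reflectance[np.argsort(tgt.reference_value, kind="stable")]
    p = t_mat.shape[1]
    gram = t_mat.T @ t_mat
    lam = ridge * np.trace(gram) / p
    f = np.linalg.solve(gram + lam * np.eye(p), t_mat.T @ s_mat)
    return DSTransform(transformation_matrix=f, n_standards=n_standards)


# --------------------------------------------------------------------------
# transfer component analysis

@dataclass
class TCATransform:
    """Kernel projection onto transfer components shared by both domains."""

    components: np.ndarray          # (n_train, n_components)
    train_data: np.ndarray          # instances the kernel is anchored on
    kernel: str
    gamma: float | None
    n_components: int
    mu: float

    def _kernel_against_train(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return x @ self.train_data.T
        sq = (np.sum(x ** 2, axis=1)[:, None]
              + np.sum(self.train_data ** 2, axis=1)[None, :]
              - 2.0 * x @ self.train_data.T)
        return np.exp(-self.gamma * np.maximum(sq, 0.0))

    def project(self, data: SpectraSet | np.ndarray) -> np.ndarray:
        x = data.reflectance if isinstance(data, SpectraSet) else np.asarray(data)
        return self._kernel_against_train(np.atleast_2d(x)) @ self.components


def tca_fit(source: SpectraSet, target: SpectraSet, n_components: int = 30,
            mu: float = 1.0, kernel: str = "linear",
            gamma: float | None = None) -> TCATransform:
    """Solve the TCA generalized eigenproblem on the stacked domains.

    Minimizes the MMD between projected domains subject to variance
    preservation: the top generalized eigenvectors of
    ``K H K  w = λ (K L K + μ I) w`` where ``L`` encodes the between-domain
    mean contrast and ``H`` the centering operator.
    """
    x = np.vstack([source.reflectance, target.reflectance])
    n_s, n_t = source.n_samples, target.n_samples
    n = n_s + n_t
    if n_components >= n:
        raise ValueError(f"n_components={n_components} must be < combined n={n}")
    if kernel == "linear":
        k_mat = x @ x.T
    elif kernel == "rbf":
        gamma = gamma if gamma is not None else 1.0 / x.shape[1]
        sq = (np.sum(x ** 2, 1)[:, None] + np.sum(x ** 2, 1)[None, :]
              - 2.0 * x @ x.T)
        k_mat = np.exp(-gamma * np.maximum(sq, 0.0))
    else:
        raise ValueError("kernel must be 'linear' or 'rbf'")
    l_vec = np.concatenate([np.full(n_s, 1.0 / n_s), np.full(n_t, -1.0 / n_t)])
    l_mat = np.outer(l_vec, l_vec)
    h_mat = np.eye(n) - np.full((n, n), 1.0 / n)
    klk = k_mat @ l_mat @ k_mat
    khk = k_mat @ h_mat @ k_mat
    a = (khk + khk.T) / 2.0
    b = (klk + klk.T) / 2.0 + mu * np.eye(n)
    try:
        eigval, eigvec = scipy.linalg.eigh(a, b)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular TCA system; increase the regularization mu > 0"
        ) from exc
    top = np.argsort(eigval)[::-1][:n_components]
    return TCATransform(components=eigvec[:, top], train_data=x,
                        kernel=kernel, gamma=gamma,
                        n_components=n_components, mu=mu)


def mmd(a: np.ndarray, b: np.ndarray) -> float:
    """Scale-normalized squared mean discrepancy between two sample sets.

    The squared distance of the domain means is divided by the pooled
    total variance, making the statistic comparable across spaces of
    different dimension and scale.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.vstack([a, b])
    scale = float(np.sum(pooled.var(axis=0)))
    return float(diff @ diff) / (scale if scale > 0 else 1.0)


# --------------------------------------------------------------------------
# end-to-end transfer experiment

@dataclass
class TransferResult:
    """Pretrain-then-fine-tune outcome for one (source → target) run."""

    arch: str
    pretrained: CNNRegressor
    fine_tuned: CNNRegressor
    source_reports: dict[str, MetricsReport]
    target_reports: dict[str, MetricsReport]
    source_model_on_target: MetricsReport
    source_split: SplitAssignment
    target_split: SplitAssignment

    def as_dict(self) -> dict:
        return {
            "architecture": self.arch,
            "source": {k: v.as_dict() for k, v in self.source_reports.items()},
            "target": {k: v.as_dict() for k, v in self.target_reports.items()},
            "source_model_on_target": self.source_model_on_target.as_dict(),
        }


def transfer_experiment(arch: str, source: SpectraSet, target: SpectraSet,
                        train_cfg: TrainConfig,
                        transfer_cfg: TransferConfig | None = None,
                        seed: int = 0, split_seed: int = 0,
                        pipeline: PreprocessPipeline | None = None) -> TransferResult:
    """Split, (optionally) pretreat, pretrain on source, fine-tune on target.

    Both domains are split 3:1:1 by reference rank.  A pretreatment
    pipeline, when given, is fitted on the source calibration set only and
    applied unchanged everywhere.
    """
    transfer_cfg = transfer_cfg or TransferConfig()
    s_split = rank_split_3to1to1(source, split_seed)
    t_split = rank_split_3to1to1(target, split_seed)
    s_sets = {k: source.subset(v) for k, v in s_split.splits().items()}
    t_sets = {k: target.subset(v) for k, v in t_split.splits().items()}
    if pipeline is not None:
        fitted = pipeline.fit_apply(s_sets["calibration"])
        s_sets = {k: (fitted if k == "calibration" else pipeline.apply(v))
                  for k, v in s_sets.items()}
        t_sets = {k: pipeline.apply(v) for k, v in t_sets.items()}

    width = s_sets["calibration"].n_wavelengths
    model = build(arch, seed=seed, input_width=width)
    pre_cfg = replace(train_cfg, seed=seed)
    model = train(model, s_sets["calibration"], s_sets["validation"], pre_cfg)

    run_cfg = replace(transfer_cfg, seed=transfer_cfg.seed + seed,
                      ft_train_config=replace(transfer_cfg.ft_train_config,
                                              seed=seed + 1))
    tuned = fine_tune(model, t_sets["calibration"], run_cfg,
                      val_set=t_sets["validation"])

    source_reports = {k: metrics(model.predict(v), v.reference_value, k)
                      for k, v in s_sets.items()}
    target_reports = {k: metrics(tuned.predict(v), v.reference_value, k)
                      for k, v in t_sets.items()}
    on_target = metrics(model.predict(t_sets["prediction"]),
                        t_sets["prediction"].reference_value, "prediction")
    return TransferResult(
        arch=arch if isinstance(arch, str) else arch.name,
        pretrained=model, fine_tuned=tuned,
        source_reports=source_reports, target_reports=target_reports,
        source_model_on_target=on_target,
        source_split=s_split, target_split=t_split,
    )
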