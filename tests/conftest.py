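"""Shared fixtures: small synthetic datasets and the benchmark runs.

The expensive fixtures are session-scoped so the transfer, size-sweep and
saliency checks share one set of trained networks.
"""
from __future__ import annotations

import numpy as np
import pytest

import spectransfer as st


@pytest.fixture(scope="session")
def small_domains():
    """A fast two-domain pair on a coarse grid (for structural tests)."""
    cfg = st.SyntheticConfig(n_samples_per_domain=120, step_nm=10.0, seed=7)
    return st.generate(cfg) + (cfg,)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_linear_set(n: int = 40, width: int = 30, seed: int = 0,
                    noise: float = 0.0) -> st.SpectraSet:
    """Rank-1 linear fixture: y is an exact linear functional of the rows."""
    gen = np.random.default_rng(seed)
    direction = gen.normal(size=width)
    scores = gen.uniform(-1, 1, size=n)
    x = np.outer(scores, direction) + 0.1 * gen.normal(size=(n, width)) * noise
    y = 3.0 * scores + 10.0
    wl = 500.0 + np.arange(width)
    return st.SpectraSet(wavelengths_nm=wl, reflectance=x, reference_value=y,
                         domain_label=np.array(["d"] * n))


# ---------------------------------------------------------------------------
# scaled two-domain benchmark: 600 samples/domain on a 10 nm grid, CNN1
# pretrained per seed on the FD+SNV source domain and fine-tuned on the
# target. Shared by the transfer, size-sweep and baseline-comparison checks.

BENCH_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def benchmark_config():
    return st.SyntheticConfig(n_samples_per_domain=600, step_nm=10.0, seed=11)


@pytest.fixture(scope="session")
def benchmark_domains(benchmark_config):
    return st.generate(benchmark_config)


@pytest.fixture(scope="session")
def benchmark_train_config():
    # full-scale stepped schedule (600 epochs, decade per 200) scaled 4x down
    return st.TrainConfig(max_epochs=150, lr_decay_every=50)


@pytest.fixture(scope="session")
def benchmark_runs(benchmark_domains, benchmark_train_config):
    """One pretrain+fine-tune per seed on the FD+SNV benchmark."""
    source, target = benchmark_domains
    pipe = st.make_pipeline("fd+snv")
    return [st.transfer_experiment("cnn1", source, target,
                                   benchmark_train_config,
                                   st.TransferConfig(), seed=seed,
                                   pipeline=pipe)
            for seed in BENCH_SEEDS]


@pytest.fixture(scope="session")
def benchmark_preprocessed(benchmark_domains, benchmark_runs):
    """FD+SNV-pretreated source/target splits matching the benchmark runs."""
    source, target = benchmark_domains
    pipe = st.make_pipeline("fd+snv")
    s_split = benchmark_runs[0].source_split
    t_split = benchmark_runs[0].target_split
    out = {"source_calibration":
           pipe.fit_apply(source.subset(s_split.calibration))}
    for name, idx in t_split.splits().items():
        out[f"target_{name}"] = pipe.apply(target.subset(idx))
    return out


@pytest.fixture(scope="session")
def saliency_benchmark():
    """Full-resolution (1 nm, 2071-column) saliency benchmark run.

    Scatter correction by MSC keeps the chlorophyll information local in
    wavelength (SNV's global rescaling would spread it), so the gradient
    attribution can be validated against the generator's band oracle.
    """
    cfg = st.SyntheticConfig(n_samples_per_domain=600, step_nm=1.0, seed=11)
    source, target = st.generate(cfg)
    train_cfg = st.TrainConfig(max_epochs=100, lr_decay_every=40)
    pipe = st.make_pipeline("msc")
    result = st.transfer_experiment("cnn1", source, target, train_cfg,
                                    st.TransferConfig(), seed=0,
                                    pipeline=pipe)
    apply_pipe = st.make_pipeline("msc")
    apply_pipe.fit_apply(source.subset(result.source_split.calibration))
    t_pred = apply_pipe.apply(target.subset(result.target_split.prediction))
    smap = st.saliency_map(result.fine_tuned, t_pred, top_k=100)
    return cfg, result, smap
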