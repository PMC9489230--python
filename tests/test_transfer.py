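"""Fine-tuning mechanics, DS and TCA standardization."""
import numpy as np
import pytest

import spectransfer as st
from spectransfer import nn
from spectransfer.transfer import stratified_subsample

from conftest import make_linear_set


def _pretrained(width=30, seed=0):
    data = make_linear_set(n=80, width=width, seed=seed)
    model = st.build("cnn1", seed=seed, input_width=width)
    cfg = st.TrainConfig(max_epochs=25, lr_decay_every=10, seed=seed)
    return st.train(model, data, data, cfg), data


class TestFineTune:
    def test_zero_lr_leaves_predictions_unchanged(self):
        model, data = _pretrained()
        cfg = st.TransferConfig(
            ft_train_config=st.TrainConfig(initial_lr=0.0, max_epochs=3))
        tuned = st.fine_tune(model, data, cfg)
        np.testing.assert_allclose(tuned.predict(data), model.predict(data),
                                   atol=1e-6)

    def test_frozen_parameters_bitwise_identical(self):
        model, data = _pretrained(seed=1)
        conv_before = [p.copy() for l in model.network.layers
                       if isinstance(l, nn.Conv1d) for p in l.params()]
        bn_before = [l.running_mean.copy() for l in model.network.layers
                     if isinstance(l, nn.BatchNorm1d)]
        tuned = st.fine_tune(model, data, st.TransferConfig(
            ft_train_config=st.TrainConfig(max_epochs=5)))
        conv_after = [p.copy() for l in tuned.network.layers
                      if isinstance(l, nn.Conv1d) for p in l.params()]
        bn_after = [l.running_mean.copy() for l in tuned.network.layers
                    if isinstance(l, nn.BatchNorm1d)]
        for b, a in zip(conv_before + bn_before, conv_after + bn_after):
            np.testing.assert_array_equal(b, a)

    def test_only_last_two_fc_layers_trainable(self):
        model, data = _pretrained(seed=2)
        dense_before = [p.copy() for l in model.network.layers
                        if isinstance(l, nn.Dense) for p in l.params()]
        tuned = st.fine_tune(model, data, st.TransferConfig(
            ft_train_config=st.TrainConfig(max_epochs=5)))
        dense_after = [p for l in tuned.network.layers
                       if isinstance(l, nn.Dense) for p in l.params()]
        # first Dense (512-node) frozen; last two updated
        np.testing.assert_array_equal(dense_before[0], dense_after[0])
        assert any(not np.array_equal(b, a)
                   for b, a in zip(dense_before[2:], dense_after[2:]))

    def test_pretrained_model_untouched(self):
        model, data = _pretrained(seed=3)
        before = model.predict(data).copy()
        st.fine_tune(model, data, st.TransferConfig(
            ft_train_config=st.TrainConfig(max_epochs=5)))
        np.testing.assert_array_equal(model.predict(data), before)

    def test_untrained_model_rejected(self):
        model = st.build("cnn1", input_width=30)
        with pytest.raises(ValueError, match="trained"):
            st.fine_tune(model, make_linear_set(width=30), st.TransferConfig())

    def test_invalid_fraction_rejected(self):
        model, data = _pretrained()
        with pytest.raises(ValueError, match="fraction"):
            st.fine_tune(model, data,
                         st.TransferConfig(target_fraction=0.0))


class TestStratifiedSubsample:
    def test_covers_reference_range(self, rng):
        y = rng.uniform(0, 100, size=200)
        idx = stratified_subsample(y, 0.1, seed=0)
        assert idx.size == 20
        assert y[idx].min() < 10 and y[idx].max() > 90

    def test_full_fraction_all_samples(self, rng):
        y = rng.uniform(size=50)
        np.testing.assert_array_equal(stratified_subsample(y, 1.0, 0),
                                      np.arange(50))


class TestSizeSweep:
    def test_fraction_one_equals_single_fine_tune(self):
        model, data = _pretrained(seed=4)
        cfg = st.TransferConfig(ft_train_config=st.TrainConfig(max_epochs=4))
        rows = st.size_sweep(model, data, data, data, [1.0], cfg, seed=9)
        tuned = st.fine_tune(model, data,
                             st.TransferConfig(
                                 target_fraction=1.0, seed=9,
                                 ft_train_config=st.TrainConfig(max_epochs=4)),
                             val_set=data)
        assert rows[0]["prediction"].rmse == pytest.approx(
            st.metrics(tuned.predict(data), data.reference_value).rmse,
            abs=1e-10)

    def test_fraction_zero_rejected(self):
        model, data = _pretrained()
        with pytest.raises(ValueError):
            st.size_sweep(model, data, data, data, [0.0])

    def test_small_subsample_uses_batch_32(self):
        cfg = st.TransferConfig()
        assert cfg.batch_size_override is None  # auto rule applies below 64


class TestDS:
    def test_identity_on_identical_domains(self):
        data = make_linear_set(n=60, width=12, seed=5)
        ds = st.ds_fit(data, data, n_standards=60, seed=0)
        mapped = ds.apply(data)
        np.testing.assert_allclose(mapped.reflectance, data.reflectance,
                                   atol=1e-6)

    def test_inverts_diagonal_scaling(self):
        src = make_linear_set(n=40, width=8, seed=6)
        tgt = src.with_reflectance(2.0 * src.reflectance)
        ds = st.ds_fit(src, tgt, n_standards=40, seed=0)
        np.testing.assert_allclose(ds.apply(tgt).reflectance,
                                   src.reflectance, atol=1e-5)

    def test_different_seeds_different_matrices(self, benchmark_domains):
        source, target = benchmark_domains
        f = [st.ds_fit(source, target, n_standards=100, seed=s)
             .transformation_matrix for s in (0, 1, 2)]
        assert not np.allclose(f[0], f[1])
        assert not np.allclose(f[1], f[2])

    def test_too_few_samples_rejected(self):
        data = make_linear_set(n=20, width=8)
        with pytest.raises(ValueError, match="n_standards"):
            st.ds_fit(data, data, n_standards=50)


class TestTCA:
    def test_identical_domains_zero_mmd(self):
        data = make_linear_set(n=50, width=10, seed=7)
        tca = st.tca_fit(data, data, n_components=5)
        z = tca.project(data)
        assert st.mmd(z, z) == 0.0

    def test_reduces_mmd_between_shifted_domains(self, benchmark_domains):
        source, target = benchmark_domains
        raw = st.mmd(source.reflectance, target.reflectance)
        tca = st.tca_fit(source, target, n_components=20)
        projected = st.mmd(tca.project(source), tca.project(target))
        assert projected < raw

    def test_component_bound_enforced(self):
        data = make_linear_set(n=20, width=10)
        with pytest.raises(ValueError, match="n_components"):
            st.tca_fit(data, data, n_components=40)

    def test_projection_dimension(self):
        data = make_linear_set(n=30, width=10, seed=8)
        tca = st.tca_fit(data, data, n_components=4)
        assert tca.project(data).shape == (30, 4)
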