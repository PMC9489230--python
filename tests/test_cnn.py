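"""CNN construction, schedule, reproducibility, capacity."""
import numpy as np
import pytest

import spectransfer as st
from spectransfer import nn

from conftest import make_linear_set


class TestArchitectures:
    def test_table_of_self_designed_nets(self):
        for k in range(1, 5):
            spec = st.ARCHITECTURES[f"cnn{k}"]
            assert spec.conv_layers == tuple((32, 3, True) for _ in range(k))
            assert spec.fc_layers == (512, 32)

    def test_alexnet_conv_stack(self):
        spec = st.ARCHITECTURES["alexnet"]
        assert spec.conv_layers == ((96, 11, True), (256, 5, True),
                                    (384, 3, True), (384, 3, False),
                                    (256, 3, False))
        assert spec.fc_layers == (4096, 4096)

    def test_vggnet9_conv_stack(self):
        spec = st.ARCHITECTURES["vggnet9"]
        assert spec.conv_layers == ((64, 5, False), (64, 3, True),
                                    (128, 3, False), (128, 3, True),
                                    (256, 3, False), (256, 3, False),
                                    (256, 3, True))

    def test_forward_shape_contract(self):
        model = st.build("cnn1", seed=0, input_width=300)
        out = model.network.forward(np.zeros((4, 1, 300), np.float32), False)
        assert out.shape == (4, 1)

    def test_complexity_ordering(self):
        widths = {name: st.build(name, input_width=700).network.n_parameters()
                  for name in ("cnn1", "vggnet9")}
        assert widths["vggnet9"] > widths["cnn1"]

    def test_same_seed_identical_initial_outputs(self):
        x = np.random.default_rng(1).normal(size=(3, 1, 200)).astype(np.float32)
        a = st.build("cnn2", seed=5, input_width=200)
        b = st.build("cnn2", seed=5, input_width=200)
        np.testing.assert_array_equal(a.network.forward(x, False),
                                      b.network.forward(x, False))

    def test_excessive_pooling_rejected(self):
        with pytest.raises(ValueError, match="below 1"):
            st.build("cnn4", input_width=20)

    def test_unknown_architecture(self):
        with pytest.raises(ValueError, match="unknown"):
            st.build("cnn9")


class TestSchedule:
    def test_decade_steps_at_200_epochs(self):
        cfg = st.TrainConfig()
        assert st.learning_rate(cfg, 0) == pytest.approx(0.005)
        assert st.learning_rate(cfg, 199) == pytest.approx(0.005)
        assert st.learning_rate(cfg, 200) == pytest.approx(0.0005)
        assert st.learning_rate(cfg, 400) == pytest.approx(0.00005)

    def test_default_batch_size_is_64(self):
        assert st.TrainConfig().batch_size == 64

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            st.TrainConfig(batch_size=0).validate()
        with pytest.raises(ValueError):
            st.TrainConfig(lr_decay_factor=1.0).validate()


class TestGradients:
    def test_dense_backward_matches_numeric(self, rng):
        layer = nn.Dense(6, 3, rng)
        x = rng.normal(size=(4, 6)).astype(np.float32)
        out = layer.forward(x, True)
        g = np.ones_like(out)
        dx = layer.backward(g)
        eps = 1e-3
        for i in (0, 3):
            for j in (0, 5):
                xp = x.copy(); xp[i, j] += eps
                xm = x.copy(); xm[i, j] -= eps
                num = (layer.forward(xp, True).sum()
                       - layer.forward(xm, True).sum()) / (2 * eps)
                assert dx[i, j] == pytest.approx(num, rel=1e-2, abs=1e-3)

    def test_conv_backward_matches_numeric(self, rng):
        layer = nn.Conv1d(1, 2, 3, rng)
        x = rng.normal(size=(2, 1, 12)).astype(np.float32)
        out = layer.forward(x, True)
        dx = layer.backward(np.ones_like(out))
        eps = 1e-3
        for j in (0, 5, 11):
            xp = x.copy(); xp[0, 0, j] += eps
            xm = x.copy(); xm[0, 0, j] -= eps
            num = (layer.forward(xp, True).sum()
                   - layer.forward(xm, True).sum()) / (2 * eps)
            assert dx[0, 0, j] == pytest.approx(num, rel=1e-2, abs=1e-3)

    def test_batchnorm_eval_backward_is_linear_map(self, rng):
        layer = nn.BatchNorm1d(3)
        layer.running_var[...] = [1.0, 4.0, 9.0]
        x = rng.normal(size=(5, 3)).astype(np.float32)
        layer.forward(x, train=False)
        dx = layer.backward(np.ones((5, 3), np.float32))
        np.testing.assert_allclose(dx, 1.0 / np.sqrt([1, 4, 9]) *
                                   np.ones((5, 3)), atol=1e-4)


class TestTraining:
    def test_memorizes_single_sample(self):
        data = make_linear_set(n=1, width=40)
        model = st.build("cnn1", seed=0, input_width=40)
        cfg = st.TrainConfig(max_epochs=120, batch_size=1, lr_decay_every=60,
                             seed=0)
        model = st.train(model, data, data, cfg)
        assert model.history["train_loss"][-1] < 1e-2

    def test_reproducible_given_seed(self):
        data = make_linear_set(n=24, width=30, seed=3)
        preds = []
        for _ in range(2):
            model = st.build("cnn1", seed=4, input_width=30)
            model = st.train(model, data, data,
                             st.TrainConfig(max_epochs=5, seed=4))
            preds.append(model.predict(data))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_validation_checkpoint_no_worse_than_start(self):
        data = make_linear_set(n=60, width=30, seed=5)
        model = st.build("cnn1", seed=0, input_width=30)
        model = st.train(model, data, data, st.TrainConfig(max_epochs=30,
                                                           seed=0))
        assert model.history["val_loss"][-1] <= model.history["val_loss"][0]
        assert min(model.history["val_loss"]) <= model.history["val_loss"][0]

    def test_empty_training_set_rejected(self):
        data = make_linear_set(n=5, width=30)
        model = st.build("cnn1", input_width=30)
        with pytest.raises(ValueError, match="empty"):
            st.train(model, data.subset([]), data, st.TrainConfig())

    def test_solvable_fixture_reaches_high_r2(self, benchmark_runs):
        """Pretrained source model explains its own prediction split."""
        rep = benchmark_runs[0].source_reports["prediction"]
        assert rep.r2 > 0.95
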