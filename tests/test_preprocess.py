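"""Pretreatment operator algebra: SNV, MSC, detrend, SG first derivative."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import spectransfer as st
from spectransfer.preprocess import DegenerateSpectrumError, available_pipelines


class TestSNV:
    def test_hand_computed_row(self):
        # sample SD of [1,2,3] is 1 (divisor n-1)
        out = st.snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_rows_centered_and_scaled(self, rng):
        x = rng.uniform(0, 1, size=(20, 50))
        out = st.snv(x)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        x = rng.uniform(0, 1, size=(10, 40))
        once = st.snv(x)
        np.testing.assert_allclose(st.snv(once), once, atol=1e-10)

    def test_constant_row_raises(self):
        with pytest.raises(DegenerateSpectrumError, match="row"):
            st.snv(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestMSC:
    def test_reference_itself_unchanged(self, rng):
        ref = rng.uniform(0, 1, size=30)
        out, _ = st.msc(ref[None, :], ref)
        np.testing.assert_allclose(out, ref[None, :], atol=1e-10)

    def test_inverts_affine_corruption_exactly(self, rng):
        ref = rng.uniform(0, 1, size=30)
        out, _ = st.msc((2.0 * ref + 3.0)[None, :], ref)
        np.testing.assert_allclose(out, ref[None, :], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # independent OLS via explicit 2x2 normal equations per row
        ref = np.array([1.0, 2.0, 4.0])
        x = rng.uniform(0, 1, size=(6, 3))
        out, _ = st.msc(x, ref)
        design = np.column_stack([ref, np.ones(3)])
        for i in range(6):
            slope, intercept = np.linalg.solve(design.T @ design,
                                               design.T @ x[i])
            np.testing.assert_allclose(out[i], (x[i] - intercept) / slope,
                                       atol=1e-10)

    def test_default_reference_is_fit_mean(self, rng):
        x = rng.uniform(0, 1, size=(8, 20))
        _, ref = st.msc(x)
        np.testing.assert_allclose(ref, x.mean(axis=0))


class TestDetrend:
    wl = np.linspace(400.0, 700.0, 31)

    def test_annihilates_quadratic(self):
        row = 2.0 + 0.01 * self.wl + 3e-5 * self.wl ** 2
        out = st.detrend(row[None, :], self.wl, order=2)
        np.testing.assert_allclose(out, 0, atol=1e-9)

    def test_residual_orthogonal_to_basis(self, rng):
        x = rng.uniform(0, 1, size=(5, 31))
        out = st.detrend(x, self.wl, order=2)
        wl_s = (self.wl - self.wl.mean()) / self.wl.std()
        basis = np.vander(wl_s, 3, increasing=True)
        np.testing.assert_allclose(out @ basis, 0, atol=1e-8)

    def test_projection_oracle_quadratic_plus_bump(self):
        bump = np.exp(-0.5 * ((self.wl - 550) / 20) ** 2)
        quad = 1.0 + 0.002 * self.wl + 1e-5 * self.wl ** 2
        out = st.detrend((quad + bump)[None, :], self.wl, order=2)
        # oracle: bump minus its own quadratic least-squares projection
        wl_s = (self.wl - self.wl.mean()) / self.wl.std()
        basis = np.vander(wl_s, 3, increasing=True)
        proj = basis @ np.linalg.lstsq(basis, bump, rcond=None)[0]
        np.testing.assert_allclose(out[0], bump - proj, atol=1e-8)

    def test_order_too_large_raises(self):
        with pytest.raises(ValueError):
            st.detrend(np.ones((1, 4)), np.arange(4.0), order=5)


class TestSGDerivative:
    def test_line_gives_slope(self):
        wl = 430.0 + np.arange(100)
        row = 5.0 + 0.25 * wl
        out = st.sg_fd(row[None, :], window=15, polyorder=2, step_nm=1.0)
        np.testing.assert_allclose(out, 0.25, atol=1e-9)

    def test_constant_gives_zero(self):
        out = st.sg_fd(np.full((2, 60), 7.0))
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_quadratic_matches_analytic_derivative(self):
        wl = np.arange(100.0)
        out = st.sg_fd((wl ** 2)[None, :], window=15, polyorder=2, step_nm=1.0)
        interior = slice(7, -7)
        np.testing.assert_allclose(out[0, interior], 2 * wl[interior],
                                   atol=1e-8)

    def test_respects_grid_step(self):
        wl = np.arange(0, 100, 2.0)
        row = 3.0 * wl
        out = st.sg_fd(row[None, :], step_nm=2.0)
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            st.sg_fd(np.ones((1, 50)), window=14)


class TestPipelines:
    def test_all_eight_constructible(self):
        pipes = available_pipelines()
        assert set(pipes) == {"none", "msc", "snv", "fd",
                              "msc+fd", "snv+fd", "fd+msc", "fd+snv"}

    def test_row_label_parsing_case_insensitive(self):
        pipe = st.make_pipeline("SNV+ FD")
        assert pipe.steps == ("snv", "fd")
        assert st.make_pipeline("FD + SNV").steps == ("fd", "snv")

    def test_none_is_identity(self, small_domains):
        src, _, _ = small_domains
        out = st.make_pipeline("none").fit_apply(src)
        np.testing.assert_array_equal(out.reflectance, src.reflectance)

    def test_fd_snv_invariant_to_scatter(self, rng):
        """[fd, snv] output is unchanged by y = a*x + b corruption."""
        wl = 430.0 + np.arange(200)
        x = np.cumsum(rng.normal(size=(6, 200)), axis=1) / 10 + 1.0
        pipe = st.make_pipeline("fd+snv")
        base = pipe.fit_apply(st.SpectraSet(wl, x, np.ones(6), ["d"] * 6))
        a = rng.uniform(0.5, 2.0, size=(6, 1))
        b = rng.normal(size=(6, 1))
        corrupted = pipe.fit_apply(
            st.SpectraSet(wl, a * x + b, np.ones(6), ["d"] * 6))
        np.testing.assert_allclose(corrupted.reflectance, base.reflectance,
                                   atol=1e-8)

    def test_step_order_matters(self, small_domains):
        src, _, _ = small_domains
        ab = st.make_pipeline("snv+fd").fit_apply(src).reflectance
        ba = st.make_pipeline("fd+snv").fit_apply(src).reflectance
        assert np.abs(ab - ba).max() > 1e-3

    def test_msc_state_fitted_on_calibration_only(self, small_domains):
        src, tgt, _ = small_domains
        pipe = st.make_pipeline("msc")
        pipe.fit_apply(src)
        ref = pipe.msc_reference.copy()
        pipe.apply(tgt)
        np.testing.assert_array_equal(pipe.msc_reference, ref)

    def test_shape_preserved(self, small_domains):
        src, _, _ = small_domains
        for name in ("snv", "msc", "fd", "fd+snv"):
            out = st.make_pipeline(name).fit_apply(src)
            assert out.reflectance.shape == src.reflectance.shape


@settings(max_examples=25, deadline=None)
@given(scale=hs.floats(0.1, 10.0), offset=hs.floats(-5.0, 5.0))
def test_snv_removes_any_affine_corruption(scale, offset):
    base = np.sin(np.linspace(0, 6, 80))[None, :] + 2.0
    np.testing.assert_allclose(st.snv(scale * base + offset), st.snv(base),
                               atol=1e-8)
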