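import numpy as np
import pytest

from bioink_optics.photon_mc import PSFStack
from bioink_optics.projection import (
    DEFAULT_LADDER_PERIODS,
    UNRESOLVED,
    PatternImage,
    blur_at_depth,
    blur_with_kernel,
    direct_convolve,
    make_line_pairs,
    make_sine_grating,
    make_snowflake_pattern,
    make_spoke_pattern,
    michelson_contrast,
    resolution_at_depth,
    threshold_print,
)


def _gauss_stack(sigma_um, pitch=5.0, depths=(250.0,)):
    half = int(6 * sigma_um / pitch)
    xs = (np.arange(2 * half + 1) - half) * pitch
    k1 = np.exp(-(xs**2) / (2 * sigma_um**2))
    k = np.outer(k1, k1)
    k /= k.sum()
    return PSFStack(
        depths=np.asarray(depths, dtype=float),
        kernels=np.repeat(k[None], len(depths), axis=0),
        pitch=pitch,
    )


def _impulse_stack(pitch=5.0, depths=(250.0,)):
    k = np.zeros((31, 31))
    k[15, 15] = 1.0
    return PSFStack(
        depths=np.asarray(depths, dtype=float),
        kernels=np.repeat(k[None], len(depths), axis=0),
        pitch=pitch,
    )


class TestSpokePattern:
    def test_rotational_symmetry(self):
        from scipy import ndimage

        # grid-exact case: 4 spokes under a 90-degree rotation
        p4 = make_spoke_pattern(4, 500.0, 5.0)
        assert np.array_equal(np.rot90(p4.grid), p4.grid)
        # general case up to nearest-neighbour resampling at wedge boundaries
        pat = make_spoke_pattern(12, 2000.0, 2.5)
        rot = ndimage.rotate(pat.grid, 360.0 / 12, reshape=False, order=0)
        assert np.mean(rot == pat.grid) >= 0.99

    def test_duty_cycle_half(self):
        pat = make_spoke_pattern(12, 2000.0, 5.0)
        npx = pat.grid.shape[0]
        c = (npx - 1) / 2.0
        y, x = np.mgrid[0:npx, 0:npx]
        inside = np.hypot(x - c, y - c) <= npx / 2.0
        assert pat.grid[inside].mean() == pytest.approx(0.5, abs=0.02)

    def test_gap_arc_width(self):
        # the gap arc at radius r is pi*r/n_spokes by construction
        assert np.pi * 200.0 / 12 == pytest.approx(52.36, abs=0.01)
        # and the rendered pattern alternates 12 lit and 12 dark arcs at r=200 μm
        pat = make_spoke_pattern(12, 2000.0, 5.0)
        npx = pat.grid.shape[0]
        c = (npx - 1) / 2.0
        thetas = np.linspace(-np.pi, np.pi, 4000, endpoint=False)
        r_px = 200.0 / 5.0
        vals = pat.grid[
            np.round(c + r_px * np.sin(thetas)).astype(int),
            np.round(c + r_px * np.cos(thetas)).astype(int),
        ]
        assert np.sum(np.abs(np.diff(vals)) > 0) == 24
        assert vals.mean() == pytest.approx(0.5, abs=0.03)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_spoke_pattern(12, 10.0, 5.0)


class TestLinePairs:
    def test_block_duty_and_bar_width(self):
        pitch = 5.0
        pat = make_line_pairs([100.0], pitch, n_periods=4)
        assert pat.grid.mean(axis=0)[:80].mean() == pytest.approx(0.5, abs=0.05)
        row = pat.grid[0]
        # bars of width p/2 = 50 μm = 10 px
        runs = np.diff(np.flatnonzero(np.diff(row)))
        assert set(runs.tolist()) == {10}

    def test_degenerate_single_period_square_wave(self):
        pitch = 2.0
        pat = make_line_pairs([8.0], pitch, n_periods=3)
        xs = np.arange(pat.grid.shape[1])
        expected = (np.mod(xs / 4.0, 1.0) < 0.5).astype(float)
        assert np.array_equal(pat.grid[0], expected)

    def test_sub_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_line_pairs([8.0], 5.0)


class TestBlur:
    def test_impulse_identity(self):
        pat = make_line_pairs([60.0], 5.0)
        stack = _impulse_stack()
        out = blur_at_depth(pat, stack, 250.0)
        kh = (stack.kernels.shape[1] - 1) // 2
        core = out.grid[kh:-kh, kh:-kh]
        assert np.allclose(core, pat.grid)

    def test_intensity_conserved(self, gaussian_kernel):
        k, pitch, _ = gaussian_kernel
        pat = make_spoke_pattern(8, 1000.0, pitch)
        out = blur_with_kernel(pat, k)
        assert out.total == pytest.approx(pat.total, rel=1e-6)

    def test_gaussian_contrast_attenuation(self, gaussian_kernel):
        """Closed-form Fourier attenuation of a sinusoidal grating."""
        k, pitch, sigma = gaussian_kernel
        p = 100.0
        pat = make_sine_grating(p, pitch)
        out = blur_with_kernel(pat, k)
        row = out.grid[out.grid.shape[0] // 2]
        m = (k.shape[1] - 1) // 2 + int(p / pitch)
        c = michelson_contrast(row[m:-m])
        assert c == pytest.approx(np.exp(-2 * np.pi**2 * sigma**2 / p**2), abs=0.02)

    def test_fft_matches_direct_sum(self, gaussian_kernel):
        k, pitch, _ = gaussian_kernel
        pat = make_line_pairs([60.0], pitch, n_periods=3, height_um=150.0)
        fft = blur_with_kernel(pat, k).grid
        direct = direct_convolve(pat.grid, k)
        assert np.abs(fft - direct).max() < 1e-6

    def test_pitch_resampling(self):
        stack = _gauss_stack(20.0, pitch=5.0)
        pat = make_line_pairs([100.0], 10.0)  # coarser pattern grid
        out = blur_at_depth(pat, stack, 250.0)
        assert out.total == pytest.approx(pat.total, rel=1e-3)

    def test_depth_not_in_stack_rejected(self):
        stack = _gauss_stack(20.0, depths=(100.0, 200.0))
        pat = make_line_pairs([100.0], 5.0)
        with pytest.raises(ValueError):
            blur_at_depth(pat, stack, 260.0)  # > half a slice spacing beyond


class TestResolution:
    def test_impulse_resolves_smallest_rung(self):
        rep = resolution_at_depth(_impulse_stack(), 250.0, 0.1)
        assert rep.min_resolved == min(DEFAULT_LADDER_PERIODS) / 2

    def test_very_wide_kernel_unresolved(self):
        rep = resolution_at_depth(_gauss_stack(400.0), 250.0, 0.1)
        assert rep.min_resolved == UNRESOLVED

    def test_gaussian_min_resolved_matches_analytic(self):
        """Blurred square-wave contrast has the closed harmonic form
        I(x) = 1/2 + sum_odd (2/(k pi)) sin(2 pi k x/p) exp(-2 pi^2 k^2 s^2/p^2);
        the ladder rung it picks must match the 2D pipeline's."""
        sigma, thr = 20.0, 0.1
        rep = resolution_at_depth(_gauss_stack(sigma), 250.0, thr)

        def analytic_contrast(p):
            x = np.linspace(0, p, 400, endpoint=False)
            prof = 0.5 * np.ones_like(x)
            for k in range(1, 13, 2):
                prof += (
                    (2.0 / (k * np.pi))
                    * np.sin(2 * np.pi * k * x / p)
                    * np.exp(-2 * np.pi**2 * k**2 * sigma**2 / p**2)
                )
            return michelson_contrast(prof)

        resolved = [
            p / 2 for p in DEFAULT_LADDER_PERIODS if analytic_contrast(p) >= thr
        ]
        assert rep.min_resolved == min(resolved)

    def test_contrast_nonincreasing_in_kernel_width(self):
        widths = [5.0, 10.0, 20.0, 40.0, 80.0]
        c = [
            resolution_at_depth(_gauss_stack(s), 250.0, 0.1).contrast_by_feature[50.0]
            for s in widths
        ]
        assert np.all(np.diff(c) <= 1e-12)

    def test_min_resolved_nondecreasing_with_depth(self, idx_psf_stacks):
        stack = idx_psf_stacks["IDX0"].psf_stack
        feats = []
        for d in stack.depths:
            mr = resolution_at_depth(stack, d, 0.1).min_resolved
            feats.append(np.inf if mr == UNRESOLVED else mr)
        assert np.all(np.diff(feats) >= 0)

    def test_index_matched_resolves_finer_at_depth(self, idx_psf_stacks):
        """30% IDX parameters preserve finer detail than 0%: never worse at
        any depth, and strictly finer at the full 250-μm structure depth
        (both inks keep a quasi-ballistic core, so a fine ladder and a firmer
        contrast cutoff are needed to separate them there)."""
        s0 = idx_psf_stacks["IDX0"].psf_stack
        s30 = idx_psf_stacks["IDX30"].psf_stack

        def feat(stack, d, **kw):
            mr = resolution_at_depth(stack, d, **kw).min_resolved
            return np.inf if mr == UNRESOLVED else mr

        for d in s0.depths:
            assert feat(s30, d, threshold=0.1) <= feat(s0, d, threshold=0.1)

        fine = dict(
            threshold=0.25,
            periods=(10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0, 120.0),
            pattern_pitch=2.5,
        )
        r0 = resolution_at_depth(s0, 250.0, **fine)
        r30 = resolution_at_depth(s30, 250.0, **fine)
        assert r30.min_resolved < r0.min_resolved
        # contrast itself is strictly ordered rung by rung
        for f in r0.contrast_by_feature:
            assert r30.contrast_by_feature[f] > r0.contrast_by_feature[f]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            resolution_at_depth(_impulse_stack(), 250.0, 0.0)


class TestThresholdPrint:
    def test_binary_output_tracks_dose(self):
        pat = make_line_pairs([200.0], 5.0)
        out = threshold_print(blur_with_kernel(pat, _gauss_stack(10.0).kernels[0]))
        assert set(np.unique(out.grid)) <= {0.0, 1.0}
        # wide bars survive a mild blur
        assert out.grid.sum() > 0


class TestSnowflake:
    def test_six_fold_symmetry_and_binary(self):
        from scipy import ndimage

        pat = make_snowflake_pattern(1000.0, 5.0)
        assert set(np.unique(pat.grid)) <= {0.0, 1.0}
        rot = ndimage.rotate(pat.grid, 60.0, reshape=False, order=0)
        assert np.mean(rot == pat.grid) >= 0.98


class TestPatternImage:
    def test_binary_validation(self):
        with pytest.raises(ValueError):
            PatternImage(grid=np.array([[0.5]]), pitch=5.0, normalization="binary")
        with pytest.raises(ValueError):
            PatternImage(grid=np.array([[-1.0]]), pitch=5.0, normalization="relative")
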