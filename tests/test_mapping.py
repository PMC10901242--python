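import numpy as np
import pytest
from scipy.signal import butter, freqz

from nirsmap import mapping
from nirsmap.mapping import ControlPointSet, FitError
from nirsmap.types import Homography, ProbabilityMap, ValidationError


def random_homography(rng):
    """A well-conditioned projective transform with mild perspective."""
    H = np.array(
        [
            [rng.uniform(3, 6), rng.uniform(-0.3, 0.3), rng.uniform(0, 50)],
            [rng.uniform(-0.3, 0.3), -rng.uniform(3, 6), rng.uniform(300, 500)],
            [rng.uniform(-3e-4, 3e-4), rng.uniform(-3e-4, 3e-4), 1.0],
        ]
    )
    return Homography(H)


def dlt_oracle(physical, pixels):
    """Independent homography fit: plain (unnormalized) DLT via SVD."""
    rows = []
    for (x, y), (u, v) in zip(physical, pixels):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(rows, dtype=float))
    H = vt[-1].reshape(3, 3)
    return H / H[2, 2]


class TestProjectiveFit:
    def test_exact_recovery_from_noiseless_points(self, rng):
        for _ in range(10):
            h_true = random_homography(rng)
            phys = rng.uniform(0, 60, size=(8, 2))
            pix = h_true.apply(phys)
            h_fit = mapping.fit_projective(ControlPointSet(phys, pix))
            np.testing.assert_allclose(h_fit.matrix, h_true.matrix, atol=1e-6)

    def test_agrees_with_independent_dlt_oracle(self, rng):
        h_true = random_homography(rng)
        phys = rng.uniform(0, 60, size=(6, 2))
        pix = h_true.apply(phys)
        h_fit = mapping.fit_projective(ControlPointSet(phys, pix))
        h_ref = dlt_oracle(phys, pix)
        np.testing.assert_allclose(h_fit.matrix, h_ref, atol=1e-6)

    def test_round_trip_apply_inverse(self, rng):
        h = random_homography(rng)
        pts = rng.uniform(0, 60, size=(50, 2))
        back = h.inverse().apply(h.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_minimum_four_points(self, rng):
        phys = np.array([[0, 0], [60, 0], [60, 80], [0, 80.0]])
        h_true = random_homography(rng)
        pix = h_true.apply(phys)
        h_fit = mapping.fit_projective(ControlPointSet(phys, pix))
        np.testing.assert_allclose(h_fit.matrix, h_true.matrix, atol=1e-6)

    def test_collinear_quad_rejected(self):
        phys = np.array([[0, 0], [1, 1], [2, 2], [0, 5.0]])
        with pytest.raises(ValidationError, match="collinear"):
            ControlPointSet(phys, phys)

    def test_degenerate_pixels_raise_fit_error(self):
        phys = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 3.0]])
        pix = np.zeros_like(phys)  # all pixels coincide
        with pytest.raises(FitError):
            mapping.fit_projective(ControlPointSet(phys, pix))

    def test_fewer_than_four_rejected(self):
        pts = np.array([[0, 0], [1, 0], [0, 1.0]])
        with pytest.raises(ValidationError):
            ControlPointSet(pts, pts)


class TestInterpolation:
    def test_planar_field_reproduced_exactly(self, rng):
        """Linear interpolation is exact for affine value fields."""
        pts = rng.uniform(0, 20, size=(100, 2))
        f = lambda p: np.clip(0.2 + 0.02 * p[:, 0] + 0.01 * p[:, 1], 0, 1)
        pmap = mapping.interpolate_scattered(pts, f(pts), spacing=0.5)
        xs, ys = pmap.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        cells = np.column_stack([gx[pmap.mask], gy[pmap.mask]])
        np.testing.assert_allclose(pmap.values[pmap.mask], f(cells), atol=1e-9)

    def test_undefined_outside_convex_hull(self, rng):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]])
        pmap = mapping.interpolate_scattered(pts, np.ones(4), spacing=1.0, margin=5.0)
        xs, ys = pmap.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        outside = (gx < -1e-9) | (gx > 10) | (gy < -1e-9) | (gy > 10)
        assert not pmap.mask[outside].any()
        assert np.isnan(pmap.values[outside]).all()

    def test_extent_points_fix_grid(self, rng):
        pts_a = rng.uniform(2, 18, size=(30, 2))
        pts_b = rng.uniform(0, 20, size=(30, 2))
        pooled = np.vstack([pts_a, pts_b])
        a = mapping.interpolate_scattered(
            pts_a, np.ones(30), spacing=0.5, extent_points=pooled
        )
        b = mapping.interpolate_scattered(
            pts_b, np.ones(30), spacing=0.5, extent_points=pooled
        )
        assert a.origin == b.origin
        assert a.values.shape == b.values.shape

    def test_values_clipped_to_unit_interval(self):
        pts = np.array([[0, 0], [10, 0], [5, 10.0]])
        pmap = mapping.interpolate_scattered(pts, np.array([-0.5, 1.5, 0.5]))
        assert np.nanmin(pmap.values) >= 0.0
        assert np.nanmax(pmap.values) <= 1.0

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0], [1, 0], [2, 0.0]])
        with pytest.raises(ValidationError):
            mapping.interpolate_scattered(pts, np.ones(3))


class TestConcaveMask:
    def _c_shape(self, rng, n=400):
        """Points on a thick C (annulus missing a quadrant) — concave."""
        theta = rng.uniform(0.25 * np.pi, 1.75 * np.pi, n)
        r = rng.uniform(6, 10, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    def test_alpha_infinity_recovers_convex_hull_area(self, rng):
        pts = rng.uniform(0, 20, size=(200, 2))
        pmap = mapping.interpolate_scattered(pts, np.full(200, 0.5), spacing=0.25)
        mask = mapping.concave_mask(pts, pmap, alpha=np.inf)
        cell_area = pmap.spacing**2
        hull_area = mapping.convex_hull_area(pts)
        assert mask.sum() * cell_area == pytest.approx(hull_area, rel=0.05)

    def test_auto_alpha_carves_concavity(self, rng):
        pts = self._c_shape(rng)
        pmap = mapping.interpolate_scattered(pts, np.full(len(pts), 0.5), spacing=0.25)
        auto = mapping.concave_mask(pts, pmap)
        hull = mapping.concave_mask(pts, pmap, alpha=np.inf)
        # the C's mouth must be (at least partly) carved away
        assert auto.sum() < 0.9 * hull.sum()
        # mask must cover every input point's cell
        xs, ys = pmap.cell_centers()
        ix = np.clip(np.searchsorted(xs, pts[:, 0]) - 1, 0, len(xs) - 2)
        iy = np.clip(np.searchsorted(ys, pts[:, 1]) - 1, 0, len(ys) - 2)
        near = auto[iy, ix] | auto[iy, ix + 1] | auto[iy + 1, ix] | auto[iy + 1, ix + 1]
        assert near.mean() > 0.98

    def test_tiny_alpha_rejected(self, rng):
        pts = rng.uniform(0, 20, size=(50, 2))
        pmap = mapping.interpolate_scattered(pts, np.full(50, 0.5))
        with pytest.raises(ValidationError):
            mapping.concave_mask(pts, pmap, alpha=1e-9)

    def test_mask_monotone_in_alpha(self, rng):
        pts = self._c_shape(rng, n=150)
        pmap = mapping.interpolate_scattered(pts, np.full(150, 0.5), spacing=0.5)
        m_small = mapping.concave_mask(pts, pmap, alpha=3.0)
        m_large = mapping.concave_mask(pts, pmap, alpha=30.0)
        assert not (m_small & ~m_large).any()  # small ⊆ large


class TestLowpass2D:
    def _square_map(self, vals, mask=None):
        vals = np.asarray(vals, dtype=float)
        if mask is None:
            mask = np.ones_like(vals, dtype=bool)
        return ProbabilityMap((0.0, 0.0), 0.5, np.where(mask, vals, np.nan), mask)

    def test_dc_gain_unity(self):
        pmap = self._square_map(np.full((60, 70), 0.42))
        out = mapping.lowpass_2d(pmap)
        np.testing.assert_allclose(out.values[out.mask], 0.42, atol=1e-9)

    def test_nyquist_checkerboard_suppressed_40db(self):
        """Oracle: forward-backward 4th-order Butterworth at 0.1 pi cutoff
        gives |H|^2 < 1e-4 at the Nyquist frequency per axis."""
        b, a = butter(mapping.FILTER_ORDER_2D, mapping.CUTOFF_2D)
        _, h = freqz(b, a, worN=[np.pi])
        assert np.abs(h[0]) ** 2 < 1e-4

        n = 80
        checker = 0.5 + 0.4 * ((np.arange(n)[:, None] + np.arange(n)[None, :]) % 2)
        pmap = self._square_map(checker - 0.2)  # values in {0.3, 0.7}
        out = mapping.lowpass_2d(pmap)
        interior = out.values[20:-20, 20:-20]
        assert np.max(np.abs(interior - 0.5)) < 0.2 * 1e-2  # > 40 dB down

    def test_masked_region_untouched_and_no_bleed(self, rng):
        n = 60
        vals = np.full((n, n), 0.8)
        mask = np.ones((n, n), dtype=bool)
        mask[:, : n // 2] = False  # left half undefined
        out = mapping.lowpass_2d(self._square_map(vals, mask))
        assert not out.mask[:, : n // 2].any()
        assert np.isnan(out.values[:, : n // 2]).all()
        # normalized masked filtering: constant region stays constant even
        # at the mask edge (zeros outside carry no weight)
        np.testing.assert_allclose(out.values[out.mask], 0.8, atol=1e-6)

    def test_output_within_unit_interval(self, rng):
        vals = rng.random((50, 50))
        out = mapping.lowpass_2d(self._square_map(vals))
        assert np.nanmin(out.values) >= 0.0
        assert np.nanmax(out.values) <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            mapping.lowpass_2d(self._square_map(np.zeros((5, 5)), np.zeros((5, 5), bool)))


class TestThresholdAndBuild:
    def test_threshold_boundary_inclusive(self):
        vals = np.array([[0.49, 0.5, 0.51, np.nan]])
        mask = np.array([[True, True, True, False]])
        pmap = ProbabilityMap((0, 0), 1.0, vals, mask)
        binary = mapping.threshold_map(pmap, 0.5)
        np.testing.assert_array_equal(binary.prediction, [[False, True, True, False]])

    def test_build_probability_map_recovers_disc(self, rng):
        """End to end: a probability field that is 1 on a disc and 0
        outside is recovered by the map pipeline up to smoothing blur."""
        pts = rng.uniform(0, 40, size=(1500, 2))
        inside = (pts[:, 0] - 20) ** 2 + (pts[:, 1] - 20) ** 2 < 8.0**2
        pmap = mapping.build_probability_map(pts, inside.astype(float), spacing=0.5)
        xs, ys = pmap.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        r = np.hypot(gx - 20, gy - 20)
        core = pmap.mask & (r < 5.0)
        far = pmap.mask & (r > 12.0)
        assert pmap.values[core].mean() > 0.85
        assert pmap.values[far].mean() < 0.1
        binary = mapping.threshold_map(pmap, 0.5)
        pred_area = binary.prediction.sum() * pmap.spacing**2
        assert pred_area == pytest.approx(np.pi * 8.0**2, rel=0.25)

    def test_shared_boundary_gives_identical_masks(self, rng):
        pooled = rng.uniform(0, 30, size=(400, 2))
        a = mapping.build_probability_map(
            pooled[:200], rng.random(200), boundary_points=pooled
        )
        b = mapping.build_probability_map(
            pooled[200:], rng.random(200), boundary_points=pooled
        )
        assert a.origin == b.origin
        assert a.values.shape == b.values.shape
        agree = (a.mask == b.mask).mean()
        assert agree > 0.95  # masks differ only where interpolation is undefined
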