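"""Measurement operators: projection, profiles, FWHM, tracing, widths."""

import math

import numpy as np
import pytest

from spinemetry import morphometry as mo
from spinemetry import pipeline as pipe
from spinemetry import synthetic as syn

from conftest import make_single_spine, render_and_project

FWHM = mo.FWHM_FACTOR


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjectStack:
    def test_single_plane_is_identity(self):
        vox = np.random.default_rng(0).uniform(0, 10, (1, 8, 9))
        stack = syn.ImageStack(voxels=vox, pixel_size_xy=0.04, z_step=0.192)
        img, px = mo.project_stack(stack)
        assert np.array_equal(img, vox[0])
        assert px == 0.04

    def test_zero_second_plane_ignored(self):
        rng = np.random.default_rng(1)
        plane = rng.uniform(1, 5, (6, 6))
        vox = np.stack([plane, np.zeros_like(plane)])
        stack = syn.ImageStack(voxels=vox, pixel_size_xy=0.04, z_step=0.192)
        img, _ = mo.project_stack(stack)
        assert np.array_equal(img, plane)

    def test_matches_elementwise_max_oracle(self, straight_spine):
        vox = straight_spine["stack"].voxels
        img, _ = mo.project_stack(straight_spine["stack"])
        ny, nx = img.shape
        for iy in range(0, ny, 7):
            for ix in range(0, nx, 7):
                assert img[iy, ix] == max(vox[iz, iy, ix]
                                          for iz in range(vox.shape[0]))


# ---------------------------------------------------------------------------
# line profiles
# ---------------------------------------------------------------------------

class TestExtractLineProfile:
    def test_constant_image(self):
        img = np.full((20, 20), 3.5)
        prof = mo.extract_line_profile(img, 0.04, (0.4, 0.4), (1, 0), 0.4)
        assert np.allclose(prof.intensities, 3.5)

    def test_axis_aligned_identity_with_pixel_row(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 9, (16, 16))
        px = 0.04
        row = 7
        centre = ((8 + 0.5) * px, (row + 0.5) * px)   # pixel centre (8, row)
        prof = mo.extract_line_profile(img, px, centre, (1, 0), 8 * px,
                                       spacing=px)
        # samples land exactly on pixel centres of that row
        expect = img[row, 4:13]
        assert np.allclose(prof.intensities, expect)

    def test_diagonal_on_linear_ramp_matches_closed_form(self):
        px = 0.05
        ny = nx = 30
        xs = (np.arange(nx) + 0.5) * px
        ys = (np.arange(ny) + 0.5) * px
        img = 2.0 * xs[None, :] + 3.0 * ys[:, None] + 1.0
        centre = np.array([0.7, 0.7])
        d = np.array([1.0, 1.0]) / math.sqrt(2)
        prof = mo.extract_line_profile(img, px, centre, d, 0.6)
        expect = 2.0 * (centre[0] + prof.positions * d[0]) \
            + 3.0 * (centre[1] + prof.positions * d[1]) + 1.0
        assert np.allclose(prof.intensities, expect, atol=1e-9)

    def test_out_of_bounds_raises(self):
        img = np.zeros((10, 10))
        with pytest.raises(mo.BoundsError):
            mo.extract_line_profile(img, 0.04, (0.02, 0.02), (1, 0), 2.0)


# ---------------------------------------------------------------------------
# Gaussian FWHM
# ---------------------------------------------------------------------------

class TestGaussianFwhm:
    @staticmethod
    def _gauss_profile(sigma, offset=0.0, n=81, span=0.8):
        x = np.linspace(-span / 2, span / 2, n)
        y = offset + np.exp(-x ** 2 / (2 * sigma ** 2))
        return mo.Profile(positions=x, intensities=y, centre=np.zeros(2),
                          direction=np.array([1.0, 0.0]))

    def test_analytic_identity_on_exact_gaussian(self):
        fit = mo.gaussian_fwhm(self._gauss_profile(0.0850))
        assert fit.converged
        assert fit.fwhm == pytest.approx(FWHM * 0.0850, rel=1e-6)

    def test_offset_invariance(self):
        f0 = mo.gaussian_fwhm(self._gauss_profile(0.06))
        f1 = mo.gaussian_fwhm(self._gauss_profile(0.06, offset=10.0))
        assert f1.fwhm == pytest.approx(f0.fwhm, rel=1e-9)

    def test_fwhm_sigma_identity(self):
        for sigma in (0.02, 0.05, 0.11):
            fit = mo.gaussian_fwhm(self._gauss_profile(sigma))
            assert fit.fwhm / fit.sigma == pytest.approx(FWHM, rel=1e-12)

    def test_constant_profile_raises(self):
        prof = mo.Profile(positions=np.linspace(0, 1, 21),
                          intensities=np.full(21, 2.0),
                          centre=np.zeros(2), direction=np.array([1.0, 0.0]))
        with pytest.raises(mo.DegenerateProfileError):
            mo.gaussian_fwhm(prof)

    def test_disc_profile_fit_matches_halfmax_of_fitted_model(self):
        """For a 0.20 um disc x 0.05 um PSF, the fitted model's half-max
        crossing width (brute force on a fine grid) equals its FWHM."""
        from scipy.ndimage import gaussian_filter1d
        dx = 1e-3
        x = np.arange(-0.35, 0.35 + dx, dx)
        r = 0.10
        chord = np.where(np.abs(x) < r,
                         np.sqrt(np.clip(r * r - x * x, 0, None)), 0.0)
        y = gaussian_filter1d(chord, (0.05 / FWHM) / dx)
        prof = mo.Profile(positions=x[::4], intensities=y[::4],
                          centre=np.zeros(2), direction=np.array([1.0, 0.0]))
        fit = mo.gaussian_fwhm(prof)
        assert fit.converged
        # evaluate the fitted model on a fine grid and cross half-max
        xx = np.arange(-0.35, 0.35, 1e-5)
        model = fit.offset + fit.amplitude * np.exp(
            -((xx - fit.centre) ** 2) / (2 * fit.sigma ** 2))
        half = fit.offset + fit.amplitude / 2
        above = xx[model >= half]
        assert (above[-1] - above[0]) == pytest.approx(fit.fwhm, abs=3e-5)


class TestWidthCorrection:
    def test_projection_correction_inverts_forward_model(self):
        for d in (0.12, 0.20, 0.44):
            apparent = mo.apparent_fwhm_of_disc(d, 0.050)
            assert apparent < d   # projection narrows
            assert mo.correct_width(apparent, 0.050, "projection") == \
                pytest.approx(d, abs=2e-3)

    def test_quadrature_correction(self):
        assert mo.correct_width(0.13, 0.05, "quadrature") == \
            pytest.approx(math.sqrt(0.13 ** 2 - 0.05 ** 2))

    def test_none_is_identity(self):
        assert mo.correct_width(0.2, 0.05, "none") == 0.2


# ---------------------------------------------------------------------------
# spine length
# ---------------------------------------------------------------------------

class TestSpineLength:
    @staticmethod
    def _path(points, boundary=1):
        return mo.SpinePath(polyline=np.asarray(points, float),
                            base_index=0, head_boundary_index=boundary)

    def test_two_segment_straight(self):
        p = self._path([(0, 0), (0, 0.41), (0, 0.82)])
        assert mo.spine_length(p) == pytest.approx(0.82)

    def test_right_angle_is_polyline_not_chord(self):
        p = self._path([(0, 0), (0, 0.3), (0.4, 0.3)])
        assert mo.spine_length(p) == pytest.approx(0.7)

    def test_quarter_circle_arclength(self):
        t = np.linspace(0, np.pi / 2, 1000)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        p = self._path(pts, boundary=500)
        assert mo.spine_length(p) == pytest.approx(np.pi / 2, abs=1e-4)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

class TestTraceSpinePath:
    def test_straight_spine_traces_straight(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        p = path.polyline
        chord = p[-1] - p[0]
        chord = chord / np.linalg.norm(chord)
        rel = p - p[0]
        dev = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        assert dev.max() < px

    def test_arc_neck_arclength_exceeds_chord(self):
        ann = make_single_spine(neck_length=0.6, sagitta=0.10)
        _, image, px, table = render_and_project(ann)
        t = table.iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        g = ann.spines[0].geometry
        # true arclength of the full path, base -> half-max head edge
        true_len = g.neck_length + (1 + math.sqrt(3) / 2) * g.head_width / 2
        measured = mo.spine_length(path)
        chord = np.linalg.norm(path.polyline[-1] - path.polyline[0])
        assert measured > chord
        assert measured == pytest.approx(true_len, rel=0.10)

    def test_background_seed_raises(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        corner = (image.shape[1] - 3, image.shape[0] - 3)
        with pytest.raises(mo.TracingError):
            mo.trace_spine_path(image, px, corner,
                                (t.hint_x_px, t.hint_y_px))


# ---------------------------------------------------------------------------
# widths
# ---------------------------------------------------------------------------

class TestNeckWidth:
    def test_single_profile_equals_its_fit(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        width, fits = mo.neck_width(image, px, path, n_profiles=1)
        conv = [f for f in fits if f.converged]
        assert len(conv) == 1
        assert width == pytest.approx(conv[0].fwhm)

    def test_recovers_true_width_with_projection_correction(self,
                                                           straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        width, _ = mo.neck_width(image, px, path, n_profiles=3)
        corrected = mo.correct_width(width, 0.050, "projection")
        assert corrected == pytest.approx(0.16, rel=0.15)

    def test_arc_profiles_orthogonal_to_analytic_normals(self):
        """On a curved neck the profile directions follow the local
        tangent: compare with the analytic arc normals."""
        ann = make_single_spine(neck_length=0.7, sagitta=0.10,
                                head_width=0.40)
        _, image, px, table = render_and_project(ann)
        t = table.iloc[0]
        cfg = mo.MorphometryConfig()
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px), cfg)
        g = ann.spines[0].geometry
        y_shift, _ = syn.shifted_annotation_offsets(ann, syn.ImagingConfig())
        true_neck = g.path[:-1][:, :2] + np.array([0.0, y_shift])
        arclen = path.arclength
        hi = arclen[path.head_boundary_index]
        for frac in (0.3, 0.5, 0.7):
            s = frac * hi
            i = min(max(int(np.searchsorted(arclen, s)), 1),
                    len(path.polyline) - 2)
            tangent = path.tangent(i)
            # analytic tangent at nearest true neck point
            j = int(np.argmin(np.linalg.norm(true_neck - path.polyline[i],
                                             axis=1)))
            j = min(max(j, 1), len(true_neck) - 2)
            true_t = true_neck[j + 1] - true_neck[j - 1]
            true_t = true_t / np.linalg.norm(true_t)
            ang = math.degrees(math.acos(min(1.0, abs(tangent @ true_t))))
            assert ang < 10.0

    def test_zero_profiles_raises(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        flat = np.zeros_like(image)
        with pytest.raises((mo.MeasurementError, mo.DegenerateProfileError)):
            mo.neck_width(flat, px, path, n_profiles=2)


class TestHeadWidth:
    def test_sphere_head_recovered_within_tolerance(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        apparent = mo.head_width(image, px, path)
        corrected = mo.correct_width(apparent, 0.050, "projection")
        assert corrected == pytest.approx(0.44, rel=0.10)

    def test_point_like_head_is_resolution_limited(self):
        ann = make_single_spine(neck_length=0.5, neck_width=0.05,
                                head_width=0.07)
        _, image, px, table = render_and_project(ann)
        t = table.iloc[0]
        path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                   (t.hint_x_px, t.hint_y_px))
        apparent = mo.head_width(image, px, path)
        # PSF-dominated: apparent width near the resolution limit
        assert apparent < 0.12

    def test_repeatability_across_noise_seeds(self):
        imaging = syn.ImagingConfig(noise_model="poisson",
                                    photons_per_peak=1000)
        widths = []
        ann = make_single_spine()
        for seed in (1, 2):
            _, image, px, table = render_and_project(ann, imaging, seed=seed)
            t = table.iloc[0]
            path = mo.trace_spine_path(image, px, (t.seed_x_px, t.seed_y_px),
                                       (t.hint_x_px, t.hint_y_px))
            widths.append(mo.head_width(image, px, path))
        assert abs(widths[0] - widths[1]) / widths[0] < 0.10


class TestSpineDensity:
    @pytest.mark.parametrize("n,length,expect", [
        (23, 20.0, 11.5),
        (0, 7.0, 0.0),
        (87, 100.0, 8.7),
    ])
    def test_density_arithmetic(self, n, length, expect):
        assert mo.spine_density(n, length) == pytest.approx(expect)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            mo.spine_density(5, 0.0)


# ---------------------------------------------------------------------------
# composite measurement & invariants
# ---------------------------------------------------------------------------

class TestMeasureSpine:
    def test_noiseless_wt_spine_within_tolerances(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        cfg = mo.MorphometryConfig(width_correction="projection")
        m = mo.measure_spine(image, px, (t.seed_x_px, t.seed_y_px),
                             (t.hint_x_px, t.hint_y_px), "s0", cfg)
        assert m.measurable
        assert m.spine_length == pytest.approx(0.84, rel=0.10)
        assert m.neck_length == pytest.approx(0.40, rel=0.15)
        assert m.neck_width == pytest.approx(0.16, rel=0.15)
        assert m.head_width == pytest.approx(0.44, rel=0.10)

    def test_unmeasurable_seed_sets_flags_not_values(self, straight_spine):
        image, px = straight_spine["image"], straight_spine["pixel_size"]
        t = straight_spine["table"].iloc[0]
        corner = (image.shape[1] - 3, image.shape[0] - 3)
        m = mo.measure_spine(image, px, corner, (t.hint_x_px, t.hint_y_px))
        assert not m.measurable
        assert m.spine_length is None and m.head_width is None
        assert "tracing" in m.flags

    def test_batch_row_conservation(self):
        geoms, ann = syn.sample_spine_population(syn.WT_PRESET, 12,
                                                 12 / 11.5 * 10, seed=6)
        imaging = syn.ImagingConfig()
        rows = 0
        for rec in ann.spines:
            patch = pipe.single_spine_annotation(rec, ann.dendrite_radius)
            stack = syn.render_stack(patch, imaging, 0)
            table = pipe.annotation_to_pixel_table(patch, imaging)
            out = pipe.measure_annotation(stack, table,
                                          mo.MorphometryConfig())
            rows += len(out)
        assert rows == 12


class TestMeasurementInvariants:
    @staticmethod
    def _rotated_scene(angle_deg):
        """Dendrite + spine rotated together in the image plane, so only
        the orientation relative to the pixel grid changes."""
        ann = make_single_spine(dendrite_length=2.4)
        th = np.radians(angle_deg - 90.0)      # 90 deg = the reference scene
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1.0]])
        centre = np.array([1.2, 0.0, 0.0])

        def r(pts):
            return (np.atleast_2d(pts) - centre) @ rot.T + centre

        g = ann.spines[0].geometry
        geom = syn.SpineGeometry(
            attachment_point=r(g.attachment_point)[0], path=r(g.path),
            head_width=g.head_width, neck_length=g.neck_length,
            neck_width=g.neck_width, spine_length=g.spine_length)
        rec = syn.SpineRecord(spine_id="s0", geometry=geom,
                              seed_point_um=geom.attachment_point[:2].copy(),
                              head_hint_um=geom.head_center[:2].copy())
        return syn.GroundTruthAnnotation(
            spines=[rec], dendrite_path=r(ann.dendrite_path),
            dendrite_length=ann.dendrite_length,
            dendrite_radius=ann.dendrite_radius)

    def test_isotropy_under_in_plane_rotation(self):
        """Rotating the whole scene by 30/45/60 degrees relative to the
        pixel grid changes measured widths < 5%."""
        ref = None
        for ang in (90, 60, 45, 30):
            ann = self._rotated_scene(ang)
            _, image, px, table = render_and_project(ann)
            t = table.iloc[0]
            path = mo.trace_spine_path(image, px,
                                       (t.seed_x_px, t.seed_y_px),
                                       (t.hint_x_px, t.hint_y_px))
            nw, _ = mo.neck_width(image, px, path)
            hw = mo.head_width(image, px, path)
            if ref is None:
                ref = (nw, hw)
            else:
                assert abs(nw - ref[0]) / ref[0] < 0.05
                assert abs(hw - ref[1]) / ref[1] < 0.05

    def test_width_monotonicity(self):
        """Measured neck width increases strictly with true width."""
        measured = []
        for w in (0.10, 0.15, 0.20, 0.25, 0.30):
            ann = make_single_spine(neck_width=w, head_width=0.5,
                                    neck_length=0.5)
            _, image, px, table = render_and_project(ann)
            t = table.iloc[0]
            path = mo.trace_spine_path(image, px,
                                       (t.seed_x_px, t.seed_y_px),
                                       (t.hint_x_px, t.hint_y_px))
            nw, _ = mo.neck_width(image, px, path)
            measured.append(nw)
        assert np.all(np.diff(measured) > 0)
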