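import numpy as np
import pytest

from dbtpre import (AcquisitionGeometry, backproject, in_focus_plane, project,
                    ramlak_filter)
from dbtpre.geometry import ProjectionSet
from dbtpre.projection import shift_lines
from dbtpre.recon import ReconVolume, ramlak_kernel

from conftest import attenuation_phantom, projection_set


class TestRamLakFilter:
    def test_kernel_invariants(self):
        k = ramlak_kernel(64, pitch=0.5)
        assert k.response[0] == 0.0  # DC removed
        assert np.allclose(k.response[1:32], k.response[:32:-1])  # even
        assert np.argmax(k.response) == 32  # Nyquist

    def test_constant_line_killed(self):
        img = 3.0 * np.ones((4, 64))
        out = ramlak_filter(img, pitch=1.0)
        assert np.max(np.abs(out)) < 1e-6 * 3.0

    def test_impulse_response_matches_dft_oracle(self):
        n = 32
        img = np.zeros((1, n))
        img[0, n // 2] = 1.0
        out = ramlak_filter(img, pitch=0.7)[0]
        # brute-force DFT oracle on the same zero-padded grid
        npad = 64  # filter pads to the next power of two >= 2n
        freqs = np.array([k / (npad * 0.7) if k <= npad // 2
                          else (k - npad) / (npad * 0.7) for k in range(npad)])
        x = np.zeros(npad)
        x[n // 2] = 1.0
        F = np.array([sum(x[m] * np.exp(-2j * np.pi * k * m / npad)
                          for m in range(npad)) for k in range(npad)])
        oracle = np.real(np.array(
            [sum(np.abs(freqs[k]) * F[k] * np.exp(2j * np.pi * k * m / npad)
                 for k in range(npad)) for m in range(n)])) / npad
        assert np.allclose(out, oracle, atol=1e-9)

    def test_linearity(self, rng):
        a, b = rng.random((3, 40)), rng.random((3, 40))
        lhs = ramlak_filter(a + b, pitch=0.3)
        rhs = ramlak_filter(a, pitch=0.3) + ramlak_filter(b, pitch=0.3)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestBackprojection:
    def test_single_angle_is_shifted_projection(self, rng):
        geom = AcquisitionGeometry(n_projections=1, arc_deg=15,
                                   detector_shape=(8, 32), pixel_pitch=1.0)
        img = rng.random((1, 8, 32))
        ps = projection_set(img, geom)
        h = 4.0
        vol = backproject(ps, [h], filtered=False)
        expected = shift_lines(img[0], -h * np.tan(np.deg2rad(0.0)))
        assert np.allclose(vol.slices[0], expected, atol=1e-12)

    def test_all_ones_average_identity_interior(self, small_geometry):
        imgs = np.ones((15,) + small_geometry.detector_shape)
        vol = backproject(projection_set(imgs, small_geometry), [2.0],
                          filtered=False)
        interior = vol.slices[0][:, 4:-4]  # max shear shift < 4 px
        assert np.allclose(interior, 1.0, atol=1e-12)

    def test_point_phantom_focus_and_fwhm(self):
        geom = AcquisitionGeometry(n_projections=15, detector_shape=(32, 64),
                                   pixel_pitch=0.14)
        vol = np.zeros((12, 32, 64))
        vol[7, 16, 30] = 1.0
        ph = attenuation_phantom(vol)
        ps = projection_set(np.stack([project(ph, geom, a)
                                      for a in geom.angles_deg]), geom)
        heights = np.arange(12) + 0.5
        recon = backproject(ps, heights, filtered=True)
        plane = in_focus_plane(recon, 7.5)
        assert np.unravel_index(np.argmax(plane), plane.shape) == (16, 30)

        def fwhm(sl):
            line = sl[16]
            above = np.where(line >= line.max() / 2)[0]
            return above[-1] - above[0] + 1

        focus = fwhm(plane)
        for idx in (1, 3, 11):  # planes >= 2 spacings from the point
            assert fwhm(recon.slices[idx]) > focus

    def test_adjoint_consistency(self, rng):
        geom = AcquisitionGeometry(n_projections=5, detector_shape=(16, 32),
                                   pixel_pitch=1.0)
        vol = rng.random((6, 16, 32))
        ph = attenuation_phantom(vol, voxel_size=1.0)
        Ax = np.stack([project(ph, geom, a) for a in geom.angles_deg])
        y = rng.normal(size=Ax.shape)
        heights = (np.arange(6) + 0.5) * 1.0  # voxel centers
        Aty = backproject(projection_set(y, geom), heights, filtered=False,
                          weight="sum").slices
        lhs = np.sum(Ax * y)
        rhs = np.sum(vol * Aty) * 1.0  # times dz
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_fbp_linear_in_projections(self, small_geometry, rng):
        a = rng.random((15,) + small_geometry.detector_shape)
        b = rng.random((15,) + small_geometry.detector_shape)
        h = [3.0]
        va = backproject(projection_set(a, small_geometry), h).slices
        vb = backproject(projection_set(b, small_geometry), h).slices
        vab = backproject(projection_set(a + b, small_geometry), h).slices
        assert np.allclose(vab, va + vb, atol=1e-9)

    def test_geometry_mismatch_rejected(self, small_geometry, rng):
        ps = projection_set(rng.random((15, 32, 64)), small_geometry)
        ps.images = rng.random((15, 16, 16))
        with pytest.raises(ValueError):
            backproject(ps, [1.0])


class TestInFocusPlane:
    def _volume(self, heights):
        geom = AcquisitionGeometry(detector_shape=(4, 4))
        slices = np.stack([np.full((4, 4), float(i))
                           for i in range(len(heights))])
        return ReconVolume(slices=slices, heights=np.asarray(heights),
                           geometry=geom)

    def test_single_plane(self):
        v = self._volume([5.0])
        assert np.all(in_focus_plane(v, 100.0) == 0.0)

    def test_exact_match(self):
        v = self._volume([1.0, 2.0, 3.0])
        assert np.all(in_focus_plane(v, 2.0) == 1.0)

    def test_nearest_and_tie_to_lower(self):
        v = self._volume([1.0, 2.0, 4.0])
        assert np.all(in_focus_plane(v, 3.4) == 2.0)  # nearest plane is 4.0
        assert np.all(in_focus_plane(v, 3.0) == 1.0)  # tie 2.0 vs 4.0 -> lower

    def test_empty_volume_rejected(self):
        geom = AcquisitionGeometry(detector_shape=(4, 4))
        v = ReconVolume(slices=np.zeros((0, 4, 4)), heights=np.zeros(0),
                        geometry=geom)
        with pytest.raises(ValueError):
            in_focus_plane(v, 1.0)


def test_recon_volume_roundtrip(tmp_path, small_geometry, rng):
    vol = ReconVolume(slices=rng.random((3, 32, 64)),
                      heights=np.array([1.0, 2.0, 3.0]),
                      geometry=small_geometry)
    path = vol.save(tmp_path / "vol.tiff")
    back = ReconVolume.load(path)
    assert np.allclose(back.slices, vol.slices, atol=1e-6)
    assert np.array_equal(back.heights, vol.heights)
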