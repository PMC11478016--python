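"""Fan-beam CT: Siddon tracing, forward model, noise, BH correction, FBP."""

import numpy as np
import pytest

import xfetsim as x
import xfetsim.ct as ct
from xfetsim.spectrum import Spectrum
from xfetsim.studies import ct_spectrum


def mono_spectrum(energy=70.0, fluence=1.0):
    edges = np.array([energy - 0.5, energy + 0.5])
    return Spectrum(edges, np.array([fluence]), kvp=energy + 0.5)


def disk_map(nxy=64, pitch=0.5, center=(0.0, 0.0), radius=16.0, value=1.0):
    c = (np.arange(nxy) - (nxy - 1) / 2) * pitch
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return np.where((xx - center[0]) ** 2 + (yy - center[1]) ** 2
                    <= radius ** 2, value, 0.0)[None]


class TestSiddon:
    def test_axis_aligned_ray_crosses_n_voxels_of_pitch_length(self):
        idx, seg = x.siddon_trace((-10.0, 0.25), (10.0, 0.25), (8, 8),
                                  0.5, (-2.0, -2.0))
        assert len(seg) == 8
        np.testing.assert_allclose(seg, 0.5, rtol=1e-12)
        assert set(idx[:, 1]) == {4}

    def test_ray_missing_grid_returns_empty(self):
        idx, seg = x.siddon_trace((-10.0, 50.0), (10.0, 50.0), (8, 8),
                                  0.5, (-2.0, -2.0))
        assert len(seg) == 0

    def test_degenerate_ray_rejected(self):
        with pytest.raises(ValueError):
            x.siddon_trace((1.0, 1.0), (1.0, 1.0), (8, 8), 0.5, (-2.0, -2.0))

    def test_lengths_sum_to_chord(self, rng):
        for _ in range(50):
            ang = rng.uniform(0, 2 * np.pi, 2)
            src = 40 * np.array([np.cos(ang[0]), np.sin(ang[0])])
            dst = 40 * np.array([np.cos(ang[1]), np.sin(ang[1])])
            if np.allclose(src, dst):
                continue
            idx, seg = x.siddon_trace(src, dst, (64, 64), 0.5, (-16.0, -16.0))
            # chord length inside the square, clipped analytically
            chord = _chord_in_square(src, dst, 16.0)
            assert seg.sum() == pytest.approx(chord, abs=1e-9)

    def test_line_integral_matches_crossing_oracle(self, rng):
        # independent evaluation from sorted voxel-boundary crossings
        mu = rng.random((64, 64))
        for _ in range(20):
            src = np.array([-40.0, rng.uniform(-14, 14)])
            dst = np.array([40.0, rng.uniform(-14, 14)])
            idx, seg = x.siddon_trace(src, dst, (64, 64), 0.5, (-16.0, -16.0))
            mine = (mu[idx[:, 0], idx[:, 1]] * seg).sum()
            assert mine == pytest.approx(
                _integral_by_crossings(mu, src, dst, 0.5, -16.0), rel=1e-9)


def _chord_in_square(src, dst, half):
    d = dst - src
    t0, t1 = 0.0, 1.0
    for k in (0, 1):
        if abs(d[k]) < 1e-14:
            if abs(src[k]) >= half:
                return 0.0
        else:
            a, b = sorted([(-half - src[k]) / d[k], (half - src[k]) / d[k]])
            t0, t1 = max(t0, a), min(t1, b)
    return max(0.0, t1 - t0) * np.hypot(*d)


def _integral_by_crossings(mu, src, dst, pitch, origin):
    d = dst - src
    length = np.hypot(*d)
    planes = origin + pitch * np.arange(mu.shape[0] + 1)
    alphas = [0.0, 1.0]
    for k in (0, 1):
        if abs(d[k]) > 1e-14:
            alphas.extend((planes - src[k]) / d[k])
    alphas = np.unique(np.clip(alphas, 0.0, 1.0))
    total = 0.0
    for a0, a1 in zip(alphas[:-1], alphas[1:]):
        if a1 <= a0:
            continue
        mid = src + 0.5 * (a0 + a1) * d
        i = int(np.floor((mid[0] - origin) / pitch))
        j = int(np.floor((mid[1] - origin) / pitch))
        if 0 <= i < mu.shape[0] and 0 <= j < mu.shape[1]:
            total += mu[i, j] * (a1 - a0) * length
    return total


class TestForwardProject:
    def test_empty_phantom_delivers_iproj_exactly(self):
        geom = ct.CTGeometry()
        empty = [(["soft_tissue", "gold"], np.zeros((2, 64, 64)), 32.0,
                  0.5, (-16.0, -16.0))]
        lam, lam_air, _ = ct.forward_project(empty, ct_spectrum(), geom, 100.0)
        np.testing.assert_allclose(lam.sum(axis=2), 3200.0, rtol=1e-9)
        assert lam_air.sum() == pytest.approx(3200.0)

    def test_central_ray_beer_lambert_closed_form(self):
        geom = ct.CTGeometry()
        water = disk_map()
        slab = [(["water"], water, 1.0, 0.5, (-16.0, -16.0))]
        spec = mono_spectrum(70.0)
        lam, _, energies = ct.forward_project(slab, spec, geom, 1000.0)
        mu = x.linear_attenuation(x.MATERIALS["water"], energies[0])
        # the two central channels straddle the center symmetrically
        central = lam[0, 511:513, 0]
        expected = 1000.0 * np.exp(-mu * 32.0)
        np.testing.assert_allclose(central, expected, rtol=1e-3)

    def test_polychromatic_central_ray_matches_per_bin_oracle(self):
        geom = ct.CTGeometry()
        water = disk_map()
        slab = [(["water"], water, 4.0, 0.5, (-16.0, -16.0))]
        spec = ct_spectrum()
        lam, _, energies = ct.forward_project(slab, spec, geom, 2356.0)
        keep = spec.fluence > 0
        shares = spec.fluence[keep] / spec.total
        mu = x.linear_attenuation(x.MATERIALS["water"], energies)
        # independent bin-by-bin evaluation on the traced path length
        srcs, dsts = geom.ray_endpoints()
        indices, lengths = x.siddon_trace(srcs[0, 511], dsts[0, 511],
                                          (64, 64), 0.5, (-16.0, -16.0))
        path = (water[0][indices[:, 0], indices[:, 1]] * lengths).sum()
        expected = 4.0 * 2356.0 * shares * np.exp(-mu * path)
        np.testing.assert_allclose(lam[0, 511], expected, rtol=1e-9)


class TestDetect:
    def test_zero_expectation_zero_signal_both_modes(self):
        lam = np.zeros((3, 4, 5))
        e = np.arange(5) + 60.0
        for mode in ("pcct", "eict"):
            s = ct.detect(lam, e, np.zeros(5), mode, 1)
            assert not s.values.any()

    def test_monoenergetic_eict_equals_energy_times_pcct(self):
        lam = np.full((5, 8, 1), 50.0)
        e = np.array([70.0])
        air = np.array([100.0])
        pc = ct.detect(lam, e, air, "pcct", 99)
        ei = ct.detect(lam, e, air, "eict", 99)
        np.testing.assert_allclose(ei.values, 70.0 * pc.values)

    def test_eict_replicate_variance_matches_compound_poisson(self, rng):
        # Var[sum E k_E] = sum E^2 lambda_E for independent Poisson k_E
        lam = rng.uniform(1.0, 30.0, size=(1, 16, 10))
        e = np.linspace(30, 120, 10)
        draws = np.stack([
            ct.detect(lam, e, lam[0, 0], "eict", int(s)).values[0]
            for s in rng.integers(0, 2 ** 31, 10_000)])
        expected = (e ** 2 * lam[0]).sum(axis=1)
        ratio = draws.var(axis=0, ddof=1) / expected
        assert np.all(np.abs(ratio - 1) < 0.1)
        assert abs(ratio.mean() - 1) < 0.02

    def test_pcct_counts_pass_poisson_dispersion(self, rng):
        lam = np.full((1, 16, 4), 12.5)
        e = np.arange(4) + 60.0
        draws = np.stack([
            ct.detect(lam, e, lam[0, 0], "pcct", int(s)).values[0]
            for s in rng.integers(0, 2 ** 31, 5_000)])
        disp = draws.var(axis=0, ddof=1) / draws.mean(axis=0)
        assert np.all(np.abs(disp - 1) < 0.1)

    def test_noise_free_expectation_when_seed_none(self):
        lam = np.full((2, 3, 2), 7.5)
        e = np.array([60.5, 61.5])
        s = ct.detect(lam, e, lam[0, 0], "pcct", None)
        np.testing.assert_allclose(s.values, 15.0)


class TestBeamHardening:
    def test_zero_thickness_maps_to_zero(self):
        calib = ct.build_water_calibration(ct_spectrum(), "pcct")
        assert calib(np.array([0.0]))[0] == 0.0

    def test_monoenergetic_correction_is_identity(self):
        spec = mono_spectrum(70.0)
        calib = ct.build_water_calibration(spec, "pcct")
        mu = x.linear_attenuation(x.MATERIALS["water"], 70.0)
        # reference energy is the spectrum mean = the single line
        p_raw = mu * np.linspace(0.1, 40.0, 15)
        np.testing.assert_allclose(calib(p_raw), p_raw, rtol=1e-6)

    def test_polychromatic_20mm_water_recovers_reference_path(self):
        spec = ct_spectrum()
        calib = ct.build_water_calibration(spec, "pcct")
        keep = spec.fluence > 0
        shares = spec.fluence[keep] / spec.total
        mu = x.linear_attenuation(x.MATERIALS["water"], spec.centers[keep])
        s20 = (shares * np.exp(-mu * 20.0)).sum()
        corrected = calib(np.array([-np.log(s20)]))[0]
        assert corrected == pytest.approx(calib.mu_ref_per_mm * 20.0, rel=5e-3)

    def test_nonpositive_channels_interpolated(self):
        sino = ct.Sinogram(np.array([[10.0, 0.0, 10.0, 10.0]]), "pcct", 20.0)
        calib = ct.build_water_calibration(ct_spectrum(), "pcct")
        p = ct.beam_hardening_correct(sino, calib)
        assert np.all(np.isfinite(p))


class TestFFBP:
    def test_zero_sinogram_gives_zero_image(self):
        geom = ct.CTGeometry()
        img = ct.ffbp_reconstruct(np.zeros((geom.n_views, geom.n_channels)),
                                  geom, 64, 0.5)
        assert not img.values.any()

    def test_uniform_water_cylinder_recovers_attenuation(self):
        geom = ct.CTGeometry()
        water = disk_map()
        line = ct.project_slice(water, 0.5, (-16.0, -16.0), geom)[:, :, 0]
        mu = x.linear_attenuation(x.MATERIALS["water"], 70.0)
        img = ct.ffbp_reconstruct(line * mu, geom, 64, 0.5)
        central = img.values[28:36, 28:36].mean()
        assert central == pytest.approx(mu, rel=0.02)

    def test_offset_disk_centroid_within_one_voxel(self):
        geom = ct.CTGeometry()
        maps = disk_map(center=(5.0, -3.0), radius=2.0, value=1.0) \
            + disk_map(radius=16.0, value=0.02)
        line = ct.project_slice(maps, 0.5, (-16.0, -16.0), geom)[:, :, 0]
        img = ct.ffbp_reconstruct(line * 0.02, geom, 128, 0.25)
        c = img.centers()
        vals = img.values - np.median(img.values)
        top = vals > 0.5 * vals.max()
        xx, yy = np.meshgrid(c, c, indexing="ij")
        cx = (xx[top] * vals[top]).sum() / vals[top].sum()
        cy = (yy[top] * vals[top]).sum() / vals[top].sum()
        assert abs(cx - 5.0) < 0.25 and abs(cy + 3.0) < 0.25

    def test_grid_beyond_fov_rejected(self):
        geom = ct.CTGeometry()
        with pytest.raises(ValueError):
            ct.ffbp_reconstruct(np.zeros((geom.n_views, geom.n_channels)),
                                geom, 512, 0.5)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ct.CTGeometry(arc_deg=150.0)
        with pytest.raises(ValueError):
            ct.CTGeometry(sid_mm=300.0)


class TestSlabSum:
    def test_identical_slices_scale(self):
        s = ct.Sinogram(np.full((4, 6), 3.0), "pcct", 10.0)
        total = ct.slab_sum([s] * 32)
        np.testing.assert_allclose(total.values, 96.0)
        assert total.air_signal == pytest.approx(320.0)

    def test_permutation_invariance(self, rng):
        sinos = [ct.Sinogram(rng.random((4, 6)), "pcct", 1.0)
                 for _ in range(5)]
        a = ct.slab_sum(sinos).values
        b = ct.slab_sum(sinos[::-1]).values
        np.testing.assert_allclose(a, b)

    def test_air_slab_sums_iproj(self):
        geom = ct.CTGeometry()
        empty = [(["soft_tissue", "gold"], np.zeros((2, 8, 8)), 1.0,
                  0.5, (-2.0, -2.0))]
        lam, lam_air, e = ct.forward_project(empty, ct_spectrum(), geom, 50.0)
        sinos = [ct.detect(lam, e, lam_air, "pcct", None) for _ in range(4)]
        total = ct.slab_sum(sinos)
        np.testing.assert_allclose(total.values, 200.0, rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        a = ct.Sinogram(np.zeros((4, 6)), "pcct", 1.0)
        b = ct.Sinogram(np.zeros((4, 7)), "pcct", 1.0)
        with pytest.raises(ValueError):
            ct.slab_sum([a, b])
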