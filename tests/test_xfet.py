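"""XFET forward model: beam transport, slit optics, expectations, sampling."""

import numpy as np
import pytest

import xfetsim as x
from xfetsim.studies import study_spectrum


def tiny_phantom(gold_map=None, n=5, nz=8, pitch=1.0):
    """Uniform soft-tissue block with optional per-voxel gold fractions."""
    ids = np.ones((n, n, nz), dtype=np.int8)
    gold = np.zeros((n, n, nz), dtype=np.float32)
    if gold_map:
        for idx, w in gold_map.items():
            gold[idx] = w
    origin = (-n * pitch / 2, -n * pitch / 2, 0.0)
    return x.VoxelPhantom(ids, gold, (pitch, pitch, pitch), origin,
                          ["air", "soft_tissue"])


class TestBeamTransport:
    def test_entrance_fluence_is_unattenuated(self):
        ph = tiny_phantom()
        spec = study_spectrum(1e6)
        energies, flu = x.beam_transport(ph, (0.0, 0.0), spec)
        mu = x.linear_attenuation(x.MATERIALS["soft_tissue"], energies)
        # voxel-center fluence times half-voxel attenuation backs out the
        # entrance spectrum exactly
        np.testing.assert_allclose(flu[0] * np.exp(mu * 0.5),
                                   spec.fluence[spec.fluence > 0], rtol=1e-7)

    def test_uniform_medium_is_log_linear_in_depth(self):
        ph = tiny_phantom(nz=30)
        spec = study_spectrum(1e8)
        _, flu = x.beam_transport(ph, (0.0, 0.0), spec)
        logf = np.log(flu[:, 5])
        steps = np.diff(logf)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_matches_cumulative_product_oracle_at_depth(self, contrast_phantom):
        ph, _, _ = contrast_phantom
        spec = study_spectrum(1.25e8)
        energies, flu = x.beam_transport(ph, (0.25, 0.25), spec)
        # independent per-voxel cumulative product along the same column
        ix = int((0.25 - ph.origin[0]) / ph.pitch[0])
        mu_col = np.stack([ph.mu_map(e)[ix, ix, :] for e in energies], axis=1)
        iz = int(54.25 / ph.pitch[2])
        atten = np.exp(-(mu_col[:iz].sum(axis=0) + 0.5 * mu_col[iz])
                       * ph.pitch[2])
        expected = spec.fluence[spec.fluence > 0] * atten
        np.testing.assert_allclose(flu[iz], expected, rtol=1e-10)

    def test_missing_beam_warns_and_returns_zero(self):
        ph = tiny_phantom()
        with pytest.warns(UserWarning):
            _, flu = x.beam_transport(ph, (99.0, 0.0), study_spectrum(1e6))
        assert not flu.any()


class TestSlitOptics:
    def test_center_emission_maps_to_center_column(self):
        col, acc = x.slit_map(0.0)
        assert col == 60
        assert acc > 0

    def test_axial_inversion(self):
        geom = x.XFETGeometry()
        assert x.slit_map(5.0, geom)[0] == 55
        assert x.slit_map(-5.0, geom)[0] == 65

    def test_off_detector_emission_undetected(self):
        col, acc = x.slit_map(75.0)
        assert col == -1 and acc == 0.0

    def test_acceptance_matches_area_sampling_oracle(self):
        # Monte Carlo quadrature over the open slit area from the emission
        # point: sum of cos(theta) dA / (4 pi r^2)
        geom = x.XFETGeometry()
        rng = np.random.default_rng(7)
        for z in (0.0, 10.0, -35.0):
            n = 1_000_000
            u = rng.uniform(-23.0, 23.0, n)          # transverse on the slit
            a = rng.uniform(-0.25, 0.25, n)          # axial within the width
            r2 = geom.d1_mm ** 2 + u ** 2 + (a - z) ** 2
            omega = (geom.d1_mm / np.sqrt(r2) / r2).mean() * (46.0 * 0.5)
            mc = omega / (4 * np.pi)
            assert x.slit_acceptance(z, geom) == pytest.approx(mc, rel=0.01)

    def test_acceptance_decreases_away_from_slit_plane(self):
        z = np.array([0.0, 10.0, 25.0, 45.0])
        acc = x.slit_acceptance(z)
        assert np.all(np.diff(acc) < 0)


class TestExpectedCounts:
    def test_gold_free_phantom_has_no_fluorescence_excess(self):
        ph = tiny_phantom()
        spec = study_spectrum(1e8)
        plan = x.full_fov_plan(ph, 1.0, 1e8)
        cv = x.expected_counts(ph, spec, x.XFETGeometry(), plan,
                               entrance_iso_mm=-2.0)
        ka1 = cv.energy_bin_index(68.8)
        lo, hi = cv.energy_bin_index(67.5), cv.energy_bin_index(69.5)
        fluor = cv.counts[..., ka1]
        scatter = 0.5 * (cv.counts[..., lo] + cv.counts[..., hi])
        # fluorescence bin holds only scatter (within the spectral slope of
        # the neighboring bins)
        assert np.all(fluor <= 1.2 * scatter + 1e-9)

    def test_one_voxel_phantom_matches_product_chain_oracle(self):
        # single gold voxel: expectation = production x acceptance x exit
        # transmission, each factor evaluated independently here
        pitch = 1.0
        ph = tiny_phantom({(2, 2, 3): 0.04}, n=5, nz=8, pitch=pitch)
        spec = study_spectrum(1e9)
        geom = x.XFETGeometry()
        plan = x.RasterPlan(np.array([0.0]), np.array([0.0]), 1e9)
        cv = x.expected_counts(ph, spec, geom, plan, entrance_iso_mm=-2.0)

        energies, flu = x.beam_transport(ph, (0.0, 0.0), spec)
        rho_au = ph.gold_partial_density()[2, 2, 3]
        production = x.fluorescence_production(rho_au, flu[3], energies, pitch)
        z_iso = 3.5 - 2.0
        acc = x.slit_acceptance(z_iso, geom)
        mu_exit = x.linear_attenuation(x.MATERIALS["soft_tissue"], 68.804)
        # transverse exit paths: distance from the grid center to the square
        # boundary along each plane direction, with axial obliquity
        obliq = np.sqrt(1 + (z_iso / geom.d1_mm) ** 2)
        t_exit = 0.0
        for ang in np.deg2rad([0, 60, 120, 180, 240, 300]):
            path = 2.5 / max(abs(np.cos(ang)), abs(np.sin(ang)))
            t_exit += np.exp(-mu_exit * path * obliq)
        expected = production * acc * t_exit

        ka1 = cv.energy_bin_index(68.8)
        got = cv.counts[0, 0, 3, ka1]
        # subtract the scatter floor estimated from the neighboring bins
        scatter = 0.5 * (cv.counts[0, 0, 3, cv.energy_bin_index(67.5)]
                         + cv.counts[0, 0, 3, cv.energy_bin_index(69.5)])
        leak_free = got - scatter
        assert leak_free == pytest.approx(expected, rel=0.02)

    def test_expectation_linear_in_gold_partial_density(self):
        # two equal-depth voxels whose gold partial densities differ 2x
        w1 = 0.005
        rho1 = w1 / ((1 - w1) / 1.06 + w1 / 19.32)
        # choose w2 so the partial density doubles exactly
        from scipy.optimize import brentq
        w2 = brentq(lambda w: w / ((1 - w) / 1.06 + w / 19.32) - 2 * rho1,
                    0.005, 0.05)
        ph = tiny_phantom({(1, 2, 3): w1, (3, 2, 3): w2}, n=5, nz=8)
        ref = tiny_phantom(n=5, nz=8)  # gold-free, same geometry
        spec = study_spectrum(1e9)
        plan = x.RasterPlan(np.array([-1.0, 1.0]), np.array([0.0]), 1e9)
        cv = x.expected_counts(ph, spec, x.XFETGeometry(), plan,
                               entrance_iso_mm=-2.0)
        cv0 = x.expected_counts(ref, spec, x.XFETGeometry(), plan,
                                entrance_iso_mm=-2.0)
        ka1 = cv.energy_bin_index(68.8)
        # gold-free reference removes the common scatter background exactly
        sig = cv.counts[:, 0, 3, ka1] - cv0.counts[:, 0, 3, ka1]
        assert sig[1] == pytest.approx(2 * sig[0], rel=0.01)

    def test_expectation_linear_in_histories(self):
        ph = tiny_phantom({(2, 2, 3): 0.01})
        spec = study_spectrum(1.0)
        geom = x.XFETGeometry()
        plan1 = x.RasterPlan(np.array([0.0]), np.array([0.0]), 1e8)
        plan4 = x.RasterPlan(np.array([0.0]), np.array([0.0]), 4e8)
        c1 = x.expected_counts(ph, spec, geom, plan1, entrance_iso_mm=-2.0)
        c4 = x.expected_counts(ph, spec, geom, plan4, entrance_iso_mm=-2.0)
        np.testing.assert_allclose(c4.counts, 4 * c1.counts, rtol=1e-9)


class TestSampling:
    def test_zero_expectation_zero_counts(self):
        ph = tiny_phantom()
        plan = x.full_fov_plan(ph, 1.0, 0.0)
        cv = x.expected_counts(ph, study_spectrum(1.0), x.XFETGeometry(), plan,
                               entrance_iso_mm=-2.0)
        assert x.sample_counts(cv, 3).counts.sum() == 0

    def test_poisson_mean_and_dispersion(self, rng):
        from dataclasses import replace
        base = x.CountVolume(np.full((1, 1, 1, 1), 5.0), np.array([0.0]),
                             np.array([0.0]), 0.0, 1.0,
                             np.array([68.0, 69.0]), 1.0)
        draws = np.array([x.sample_counts(replace(base), int(s)).counts[0, 0, 0, 0]
                          for s in rng.integers(0, 2 ** 31, 10_000)])
        se = np.sqrt(5.0 / draws.size)
        assert abs(draws.mean() - 5.0) < 3 * se
        assert abs(draws.var(ddof=1) / draws.mean() - 1.0) < 0.05

    def test_same_seed_reproduces_counts(self):
        base = x.CountVolume(np.full((2, 2, 3, 2), 7.0), np.arange(2.0),
                             np.arange(2.0), 0.0, 1.0,
                             np.array([67.0, 68.0, 69.0]), 1.0)
        a = x.sample_counts(base, 42)
        b = x.sample_counts(base, 42)
        assert np.array_equal(a.counts, b.counts)


class TestPartialFOV:
    def test_stated_roi_gives_21x21_positions(self, contrast_phantom):
        ph, _, rois = contrast_phantom
        target = next(r for r in rois if "0.05" in r.label
                      and r.axial_mm == 3.25)
        square = x.ROISpec("square", target.center, 5.25, "gold", "fov")
        plan = x.roi_plan(square, ph, 0.25, 6.41e9)
        assert (len(plan.x_mm), len(plan.y_mm)) == (21, 21)

    def test_histories_ratio_scales_expectation(self, contrast_phantom):
        ph, _, rois = contrast_phantom
        target = next(r for r in rois if "0.05" in r.label
                      and r.axial_mm == 3.25)
        square = x.ROISpec("square", target.center, 5.25, "gold", "fov")
        spec = study_spectrum()
        lo = x.partial_fov_scan(ph, spec, x.XFETGeometry(), square,
                                0.25, 1.25e8)
        hi = x.partial_fov_scan(ph, spec, x.XFETGeometry(), square,
                                0.25, 6.41e9)
        np.testing.assert_allclose(hi.counts, lo.counts * (6.41e9 / 1.25e8),
                                   rtol=1e-9)

    def test_full_fov_roi_reproduces_full_scan(self):
        ph = tiny_phantom({(2, 2, 3): 0.02}, n=4, nz=6, pitch=1.0)
        spec = study_spectrum(1e8)
        geom = x.XFETGeometry()
        full = x.expected_counts(ph, spec, geom,
                                 x.full_fov_plan(ph, 1.0, 1e8),
                                 entrance_iso_mm=-2.0)
        square = x.ROISpec("square", (0.0, 0.0), 4.0, "gold", "all")
        plan = x.roi_plan(square, ph, 1.0, 1e8)
        part = x.expected_counts(ph, spec, geom, plan, entrance_iso_mm=-2.0)
        np.testing.assert_allclose(part.counts, full.counts, rtol=1e-9)

    def test_roi_outside_phantom_rejected(self):
        ph = tiny_phantom()
        roi = x.ROISpec("square", (10.0, 0.0), 5.0, "gold", "bad")
        with pytest.raises(ValueError):
            x.roi_plan(roi, ph)


class TestSerialization:
    def test_count_volume_roundtrip(self, tmp_path):
        cv = x.CountVolume(np.arange(24.0).reshape(2, 2, 3, 2),
                           np.arange(2.0), np.arange(2.0), 0.0, 1.0,
                           np.array([67.0, 68.0, 69.0]), 1.25e8)
        x.save_counts(tmp_path / "scan", cv, {"seed": 1})
        back = x.load_counts(tmp_path / "scan")
        assert np.array_equal(back.counts, cv.counts)
        assert back.histories == cv.histories
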