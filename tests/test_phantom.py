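"""Tissue phantom: chromophores, occlusion trajectories, forward model,
reference images and the synthetic study."""

import numpy as np
import pytest

from msiperf import phantom
from msiperf.phantom import (
    OcclusionProtocol,
    Severity,
    StudyDesign,
    TissueState,
    default_chromophores,
    default_protocol,
    occlusion_timecourse,
    reference_parameters,
    run_synthetic_study,
    simulate_band_reflectance,
)
from msiperf.spectral import band_by_peak, canonical_bands


def uniform_state(thb=0.08, so2_deep=0.6, so2_sup=0.8, shape=(8, 8), **kw):
    return TissueState(
        thb=np.full(shape, thb),
        so2_deep=np.full(shape, so2_deep),
        so2_sup=np.full(shape, so2_sup),
        **kw,
    )


class TestChromophores:
    def test_isosbestic_crossing_near_800nm(self):
        chrom = default_chromophores()
        assert 790 <= chrom.isosbestic_nm() <= 810

    def test_red_range_hhb_dominates_and_nir_hbo2_dominates(self):
        chrom = default_chromophores()
        for nm in (600, 635, 663, 762):
            eo, ed = chrom.eps_at(nm)
            assert ed > eo
        for nm in (811, 863, 957):
            eo, ed = chrom.eps_at(nm)
            assert eo > ed

    def test_out_of_grid_lookup_rejected(self):
        with pytest.raises(ValueError):
            default_chromophores().eps_at(395.0)


class TestProtocol:
    def test_default_phase_boundaries(self):
        proto = default_protocol()
        assert proto.total_min == 16
        assert list(proto.boundaries_min()) == [2, 4, 9, 11, 16]
        assert proto.frames_per_min == 600

    def test_phase_lookup(self):
        proto = default_protocol()
        assert proto.phase_at(0.5) == "baseline"
        assert proto.phase_at(3.0) == "venous"
        assert proto.phase_at(10.0) == "arterial"

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            OcclusionProtocol(phases=(("baseline", -1.0),))


class TestOcclusionTimecourse:
    def test_anchored_at_baseline(self):
        base = uniform_state()
        _, states = occlusion_timecourse(default_protocol(), base, times_min=[0.0])
        np.testing.assert_allclose(states[0].thb, base.thb)
        np.testing.assert_allclose(states[0].so2_deep, base.so2_deep)

    def test_arterial_end_lowers_deep_saturation(self):
        base = uniform_state()
        sev = Severity(arterial_so2_deep=0.5)
        _, states = occlusion_timecourse(default_protocol(), base, sev, times_min=[0.0, 11.0])
        assert states[1].so2_deep.mean() < states[0].so2_deep.mean()

    def test_venous_phase_raises_thb_monotonically(self):
        base = uniform_state()
        ts = np.linspace(2.0, 4.0, 9)
        _, states = occlusion_timecourse(default_protocol(), base, times_min=ts)
        thb = np.array([s.thb.mean() for s in states])
        assert np.corrcoef(ts, thb)[0, 1] > 0
        assert np.all(np.diff(thb) >= 0)

    def test_arterial_phase_holds_thb_while_so2_falls(self):
        base = uniform_state()
        ts = np.linspace(9.0, 11.0, 9)
        _, states = occlusion_timecourse(default_protocol(), base, times_min=ts)
        thb = np.array([s.thb.mean() for s in states])
        so2 = np.array([s.so2_deep.mean() for s in states])
        assert abs(thb[-1] - thb[0]) / thb[0] < 0.05
        assert so2[-1] < so2[0]

    def test_times_outside_protocol_rejected(self):
        with pytest.raises(ValueError):
            occlusion_timecourse(default_protocol(), uniform_state(), times_min=[17.0])


class TestBandReflectance:
    def test_zero_absorbance_gives_unit_reflectance(self):
        state = uniform_state(thb=1e-12, scatter_loss=0.0)
        r = simulate_band_reflectance(state, band_by_peak(663))
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_reflectance_monotone_in_saturation_where_hhb_absorbs_more(self):
        # 663 nm: eps_HbO2 < eps_HHb, so oxygenated tissue reflects more
        hi = uniform_state(so2_deep=1.0)
        lo = uniform_state(so2_deep=0.0)
        band = band_by_peak(663)
        assert simulate_band_reflectance(hi, band).mean() > simulate_band_reflectance(
            lo, band
        ).mean()

    def test_doubling_path_squares_reflectance(self, rng):
        shape = (6, 6)
        state1 = TissueState(
            thb=rng.uniform(0.04, 0.2, shape),
            so2_deep=rng.uniform(0.2, 0.9, shape),
            so2_sup=rng.uniform(0.2, 0.9, shape),
            scatter_loss=0.0,
            path_mm={"sup": 0.6, "deep": 2.5},
        )
        state2 = TissueState(
            thb=state1.thb,
            so2_deep=state1.so2_deep,
            so2_sup=state1.so2_sup,
            scatter_loss=0.0,
            path_mm={"sup": 1.2, "deep": 5.0},
        )
        for peak in (537.0, 811.0):
            band = band_by_peak(peak)
            r1 = simulate_band_reflectance(state1, band)
            r2 = simulate_band_reflectance(state2, band)
            np.testing.assert_allclose(r2, r1**2, rtol=1e-12)

    def test_monotone_decreasing_in_thb_at_every_band(self, rng):
        shape = (5, 5)
        so2d = rng.uniform(0.1, 0.9, shape)
        so2s = rng.uniform(0.1, 0.9, shape)
        for band in canonical_bands():
            lo = TissueState(np.full(shape, 0.05), so2d, so2s)
            hi = TissueState(np.full(shape, 0.15), so2d, so2s)
            assert np.all(
                simulate_band_reflectance(hi, band) < simulate_band_reflectance(lo, band)
            )


class TestReferenceParameters:
    def test_constant_mapping_gives_constant_image(self):
        refs = reference_parameters(
            uniform_state(), mapping={p: phantom.AffineMap(0.0, 0.5) for p in phantom.REFERENCE_PARAMETERS}
        )
        for ref in refs.values():
            assert np.all(ref.values == 0.5)

    def test_values_clipped_to_unit_interval(self):
        refs = reference_parameters(
            uniform_state(thb=5.0), mapping={p: phantom.AffineMap(10.0, 0.0) for p in phantom.REFERENCE_PARAMETERS}
        )
        assert refs["THI"].values.max() <= 1.0

    def test_default_population_within_printed_reference_ranges(self, default_study_scaled):
        limits = {"THI": (0.031, 0.907), "NIR_PI": (0.400, 0.797), "StO2": (0.274, 0.881)}
        for param, (lo, hi) in limits.items():
            vals = np.concatenate(
                [m.reference.values.ravel() for m in default_study_scaled.measurements_for(param)]
            )
            assert vals.min() >= lo and vals.max() <= hi
            assert np.all((vals >= 0) & (vals <= 1))

    def test_superficial_oxygenation_mostly_high(self, default_study_scaled):
        vals = np.concatenate(
            [m.reference.values.ravel() for m in default_study_scaled.measurements_for("StO2")]
        )
        hist, edges = np.histogram(vals, bins=20, range=(0, 1))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert 0.7 <= mode <= 0.9


class TestSyntheticStudy:
    def test_default_design_counts(self, default_study_scaled):
        ds = default_study_scaled
        assert ds.design.n_measurements_per_parameter == 192
        for p in ds.parameters:
            assert len(ds.measurements_for(p)) == 192
        manifest = ds.manifest()
        assert manifest["n_measurements"]["total"] == 576
        assert manifest["protocol"]["frames_per_run"] == 9600

    def test_minimal_design(self):
        ds = run_synthetic_study(
            design=StudyDesign(1, 1, (45.0,)),
            seed=0,
            shape=(16, 16),
            parameters=("THI",),
            snr_frames=0,
        )
        assert len(ds.measurements) == 1

    def test_seeded_determinism(self):
        kw = dict(
            design=StudyDesign(2, 1, (45.0,)), shape=(16, 16), parameters=("NIR_PI",),
            snr_frames=4,
        )
        a = run_synthetic_study(seed=11, **kw)
        b = run_synthetic_study(seed=11, **kw)
        assert a.manifest() == b.manifest()
        for ma, mb in zip(a.measurements, b.measurements):
            np.testing.assert_array_equal(ma.frames[0].pixels, mb.frames[0].pixels)
            np.testing.assert_array_equal(ma.reference.values, mb.reference.values)
        np.testing.assert_array_equal(a.snr_series[537.0], b.snr_series[537.0])

    def test_affine_rr_reference_mode_is_exact(self):
        ds = run_synthetic_study(
            design=StudyDesign(3, 1, (45.0,)),
            seed=5,
            shape=(16, 16),
            parameters=("THI",),
            reference_mode="affine-rr",
            snr_frames=0,
        )
        amap = phantom._AFFINE_RR_MAPPING["THI"]
        for m in ds.measurements:
            np.testing.assert_allclose(m.reference.values, amap(m.rr_truth), atol=1e-12)

    def test_invalid_reference_mode_rejected(self):
        with pytest.raises(ValueError):
            run_synthetic_study(reference_mode="bogus")


class TestStateValidation:
    def test_saturation_bounds_enforced(self):
        with pytest.raises(ValueError):
            uniform_state(so2_deep=1.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TissueState(np.ones((4, 4)), np.full((4, 4), 0.5), np.full((3, 3), 0.5))
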