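"""Phantom painting and count-limited scan emulation."""

import numpy as np
import pytest

from petrestore import (AcquisitionModel, Ellipsoid, GeometryError, PETVolume,
                        PhantomSpec, Sphere, build_duration_series,
                        generate_phantom, random_phantom_spec, simulate_scan)
from petrestore.phantom import FWHM_TO_SIGMA, _membership


class TestGeneratePhantom:
    def test_empty_spec_is_uniform_background(self):
        spec = PhantomSpec(grid_shape=(8, 8, 4), background_activity=1.0)
        pet, ct = generate_phantom(spec)
        assert np.all(pet.data == 1.0)
        assert np.all(ct.data == spec.ct_background_hu)

    def test_lesion_sets_max_activity(self):
        spec = PhantomSpec(grid_shape=(16, 16, 8),
                           lesions=(Sphere((7.5, 7.5, 3.5), 5.0, 8.0, 40.0),),
                           background_activity=1.0)
        pet, _ = generate_phantom(spec)
        assert pet.data.max() == 8.0
        assert pet.data.min() == 1.0

    def test_overlap_last_descriptor_wins_against_voxel_oracle(self):
        a = Ellipsoid((7.0, 7.0, 3.5), (12.0, 10.0, 8.0), 2.0, 50.0)
        b = Ellipsoid((9.0, 9.0, 3.5), (12.0, 10.0, 8.0), 3.0, 70.0)
        spec = PhantomSpec(grid_shape=(20, 20, 8), organs=(a, b),
                           background_activity=0.1)
        pet, ct = generate_phantom(spec)
        # brute-force per-voxel membership oracle, painted in order
        vy, vx, vz = spec.voxel_size_mm
        expected = np.full(spec.grid_shape, 0.1)
        expected_ct = np.full(spec.grid_shape, spec.ct_background_hu)
        for desc in (a, b):
            for i in range(20):
                for j in range(20):
                    for k in range(8):
                        q = (((i - desc.center[0]) * vy / desc.semi_axes_mm[0]) ** 2
                             + ((j - desc.center[1]) * vx / desc.semi_axes_mm[1]) ** 2
                             + ((k - desc.center[2]) * vz / desc.semi_axes_mm[2]) ** 2)
                        if q <= 1.0:
                            expected[i, j, k] = desc.activity
                            expected_ct[i, j, k] = desc.ct_level
        np.testing.assert_array_equal(pet.data, expected)
        np.testing.assert_array_equal(ct.data, expected_ct)
        # the overlap region really exercises the last-wins rule
        overlap = _membership(spec, a) & _membership(spec, b)
        assert overlap.any()
        assert np.all(pet.data[overlap] == 3.0)

    def test_descriptor_outside_grid_rejected(self):
        spec = PhantomSpec(grid_shape=(8, 8, 4),
                           organs=(Ellipsoid((4, 4, 2), (200.0, 5.0, 5.0),
                                             1.0, 0.0),))
        with pytest.raises(GeometryError):
            generate_phantom(spec)

    def test_determinism(self, small_spec):
        p1, c1 = generate_phantom(small_spec)
        p2, c2 = generate_phantom(small_spec)
        np.testing.assert_array_equal(p1.data, p2.data)
        np.testing.assert_array_equal(c1.data, c2.data)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_specs_are_valid(self, seed):
        spec = random_phantom_spec(seed)
        pet, ct = generate_phantom(spec)
        assert pet.data.shape == spec.grid_shape
        assert np.all(pet.data >= 0)


class TestSimulateScan:
    def test_zero_truth_gives_zero_image(self, fast_acq):
        truth = PETVolume(np.zeros((8, 8, 4)))
        out = simulate_scan(truth, fast_acq, 6.0, seed=0)
        assert np.all(out.data == 0.0)

    def test_unbiased_mean_on_uniform_truth(self, fast_acq):
        truth = PETVolume(np.full((64, 64, 32), 4.0))   # >1e5 voxels
        out = simulate_scan(truth, fast_acq, 6.0, seed=3,
                            apply_postfilter=False)
        assert abs(out.data.mean() - 4.0) / 4.0 < 0.01

    def test_variance_scales_inversely_with_duration(self, fast_acq):
        truth = PETVolume(np.full((64, 64, 16), 4.0))
        v6 = simulate_scan(truth, fast_acq, 6.0, seed=5,
                           apply_postfilter=False).data.var()
        v600 = simulate_scan(truth, fast_acq, 600.0, seed=6,
                             apply_postfilter=False).data.var()
        assert v6 / v600 == pytest.approx(100.0, rel=0.1)

    def test_nonpositive_duration_rejected(self, fast_acq):
        truth = PETVolume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            simulate_scan(truth, fast_acq, 0.0, seed=0)

    def test_seed_determinism_bit_identical(self, fast_acq, small_phantom):
        truth, _ = small_phantom
        a = simulate_scan(truth, fast_acq, 15.0, seed=11)
        b = simulate_scan(truth, fast_acq, 15.0, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_postfilter_preserves_mass_for_interior_support(self):
        # activity supported well inside the grid: filtering moves no mass out
        acq = AcquisitionModel()
        data = np.zeros((48, 48, 24))
        data[16:32, 16:32, 8:16] = 5.0
        truth = PETVolume(data)
        out = simulate_scan(truth, acq, 600.0, seed=2)
        pre = simulate_scan(truth, acq, 600.0, seed=2, apply_postfilter=False)
        assert abs(out.data.sum() - pre.data.sum()) / pre.data.sum() < 0.005

    def test_count_thinning_consistency(self, fast_acq):
        # expected total counts at t seconds = (t/600) x the 600-s total
        truth = PETVolume(np.full((32, 32, 8), 2.0))
        c = fast_acq.counts_per_suv_second
        t = 6.0
        lam_t = truth.data.sum() * c * t
        lam_ref = truth.data.sum() * c * 600.0
        assert lam_t / lam_ref == pytest.approx(t / 600.0)
        # and the realized counts agree within Monte-Carlo error
        sim = simulate_scan(truth, fast_acq, t, seed=9, apply_postfilter=False)
        realized = sim.data.sum() * c * t
        assert realized == pytest.approx(lam_t, rel=0.02)


class TestDurationSeries:
    def test_default_durations_keyed(self, small_phantom):
        truth, ct = small_phantom
        series, _ = build_duration_series(truth, ct, AcquisitionModel(), seed=1)
        assert sorted(series) == [6.0, 15.0, 30.0, 60.0, 150.0, 600.0]

    def test_single_duration(self, small_phantom):
        truth, ct = small_phantom
        acq = AcquisitionModel(durations_s=(600.0,))
        series, _ = build_duration_series(truth, ct, acq, seed=1)
        assert list(series) == [600.0]

    def test_reference_member_is_noisy_not_truth(self, small_phantom):
        truth, ct = small_phantom
        series, _ = build_duration_series(truth, ct, AcquisitionModel(), seed=1)
        assert not np.array_equal(series[600.0].data, truth.data)

    def test_members_use_distinct_subseeds(self, small_phantom):
        truth, ct = small_phantom
        acq = AcquisitionModel(durations_s=(6.0, 6.0))
        # same duration twice: distinct sub-seeds give distinct noise
        series, _ = build_duration_series(truth, ct,
                                          AcquisitionModel(durations_s=(6.0, 60.0)),
                                          seed=4)
        assert series[6.0].meta["seed"] != series[60.0].meta["seed"]
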