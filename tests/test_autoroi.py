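"""Automated center finding, the whole-voxel box ROI rule, and alignment."""

import math
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import petcrosscal as pc
from petcrosscal.autoroi import locate_phantom_on_ct, roi_voxel_count
from petcrosscal.errors import AnalysisError, GeometryError, PhantomNotFoundError

T0 = datetime(2013, 4, 1, 12, 0, tzinfo=timezone.utc)


def grid_volume(shape=(60, 60, 40), spacing=(2.7, 2.7, 3.3), values=None):
    vals = np.zeros(shape) if values is None else values
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return pc.ImageVolume(
        values=vals, spacing=spacing, origin=origin, modality="PET",
        value_units="kBq/mL", acquisition_datetime=T0, decay_reference_datetime=T0,
    )


def max_whole_voxels_inside(box_mm: float, pitch_mm: float) -> int:
    """Brute-force oracle: most whole voxels of a 1D grid a box can cover.

    Slides the box over a fine grid of placements relative to the voxel
    lattice and counts voxels wholly inside; the ROI rule must select this
    many along each axis.
    """
    best = 0
    for offset in np.linspace(0.0, pitch_mm, 401):
        lo, hi = offset, offset + box_mm
        i_min = math.ceil((lo + pitch_mm / 2) / pitch_mm - 1e-9)
        i_max = math.floor((hi - pitch_mm / 2) / pitch_mm + 1e-9)
        best = max(best, i_max - i_min + 1)
    return max(best, 0)


class TestWholeVoxelRule:
    @pytest.mark.parametrize(
        "box, spacing, per_axis, total",
        [
            (10.0, (2.7, 2.7, 3.3), (3, 3, 3), 27),
            (15.0, (2.7, 2.7, 3.3), (5, 5, 4), 100),
            (20.0, (2.7, 2.7, 3.3), (7, 7, 6), 294),
            (15.0, (5.5, 5.5, 3.3), (2, 2, 4), 16),
        ],
    )
    def test_box_size_series(self, box, spacing, per_axis, total):
        """The 10/15/20-mm boxes reproduce the published 27/100/294 voxel counts."""
        vol = grid_volume(spacing=spacing)
        center = vol.index_to_physical(np.array(vol.shape) / 2.0)
        roi = pc.whole_voxel_roi(vol, center, box)
        ns = tuple(b - a for a, b in roi)
        assert ns == per_axis
        assert np.prod(ns) == total
        assert roi_voxel_count(spacing, box) == total

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        box=st.floats(4.0, 30.0, allow_nan=False),
        pitch=st.floats(1.0, 8.0, allow_nan=False),
    )
    def test_floor_rule_matches_brute_force_oracle(self, box, pitch):
        ratio = box / pitch
        # stay away from knife-edge ratios where the oracle's finite
        # placement grid and floating point disagree about "exactly fits"
        assume(abs(ratio - round(ratio)) > 1e-3)
        assume(ratio >= 1)
        assert int(math.floor(ratio + 1e-9)) == max_whole_voxels_inside(box, pitch)

    def test_exact_integer_fit_is_kept(self):
        # 13.2 mm box on 3.3 mm pitch holds exactly 4 voxels; floating point
        # must not lose the fourth
        assert roi_voxel_count((3.3, 3.3, 3.3), 13.2) == 64

    def test_too_small_box_rejected(self):
        vol = grid_volume()
        with pytest.raises(GeometryError):
            pc.whole_voxel_roi(vol, (0, 0, 0), 2.0)

    def test_box_outside_volume_rejected(self):
        vol = grid_volume()
        edge = vol.index_to_physical([0, 0, 0])
        with pytest.raises(GeometryError):
            pc.whole_voxel_roi(vol, edge - 10.0, 15.0)

    def test_equidistant_center_takes_lower_indices(self):
        vol = grid_volume(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))
        # center exactly between voxel centers along every axis, even run
        center = vol.index_to_physical([4.5, 4.5, 4.5])
        roi = pc.whole_voxel_roi(vol, center, 5.0)  # 2 voxels per axis
        assert roi == ((4, 6), (4, 6), (4, 6))
        # odd run, still exactly half way: lower run wins
        roi3 = pc.whole_voxel_roi(vol, center, 6.1)  # 3 voxels per axis
        assert roi3 == ((3, 6), (3, 6), (3, 6))


class TestRoiStatistics:
    def test_constant_region(self):
        vol = grid_volume(values=np.full((60, 60, 40), 7.0))
        res = pc.roi_statistics(vol, ((10, 15), (10, 15), (10, 14)))
        assert res.mean == res.max == res.min == 7.0
        assert res.sd == 0.0 and res.u_percent == 0.0
        assert res.n_voxels == 100

    def test_two_voxel_roi(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0], vals[1, 0, 0] = 1.0, 3.0
        vol = grid_volume(shape=(4, 4, 4), values=vals)
        res = pc.roi_statistics(vol, ((0, 2), (0, 1), (0, 1)))
        assert (res.mean, res.min, res.max, res.n_voxels) == (2.0, 1.0, 3.0, 2)
        assert res.sd == pytest.approx(1.0)  # population SD over {1, 3}
        assert res.u_percent == pytest.approx(50.0)

    def test_statistics_ignore_index_ordering(self):
        """The same voxel set gives the same statistics however it is framed."""
        rng = np.random.default_rng(7)
        vol = grid_volume(values=rng.uniform(1, 2, size=(60, 60, 40)))
        roi = ((5, 9), (11, 14), (20, 23))
        res = pc.roi_statistics(vol, roi)
        flat = vol.values[5:9, 11:14, 20:23].ravel()
        rng.shuffle(flat)
        assert res.mean == pytest.approx(flat.mean())
        assert res.sd == pytest.approx(flat.std(ddof=0))

    def test_empty_roi_rejected(self):
        vol = grid_volume()
        with pytest.raises(AnalysisError):
            pc.roi_statistics(vol, ((3, 3), (0, 1), (0, 1)))


class TestLocateActiveCenter:
    def test_centered_noiseless_cylinder(self, pet_vol):
        center = pc.locate_active_center(pet_vol)
        assert np.all(np.abs(center) < np.array(pet_vol.spacing) / 2)

    @pytest.mark.parametrize("shift_y", [10.0, 25.0, 40.0])
    def test_tracks_translations(self, default_scene, shift_y):
        moved = pc.misposition(default_scene, translation_mm=(0.0, shift_y, 0.0))
        pet, _ = pc.simulate_measurement(moved, pc.PsfSpec(), pc.NoiseSpec(model="none"))
        center = pc.locate_active_center(pet)
        err = np.abs(center - np.array([0.0, shift_y, 0.0]))
        assert np.all(err < np.array(pet.spacing) / 2)

    def test_equivariant_under_integer_voxel_shifts(self, default_scene):
        """Shifting the scene by whole voxels shifts the estimate exactly."""
        base_pet, _ = pc.simulate_measurement(
            default_scene, pc.PsfSpec(), pc.NoiseSpec(model="none")
        )
        base = pc.locate_active_center(base_pet)
        shift = (2 * 2.7, -3 * 2.7, 2 * 3.3)
        moved = pc.misposition(default_scene, translation_mm=shift)
        pet, _ = pc.simulate_measurement(moved, pc.PsfSpec(), pc.NoiseSpec(model="none"))
        center = pc.locate_active_center(pet)
        assert np.allclose(center - base, shift, atol=1e-6)

    def test_all_zero_volume_not_found(self):
        vol = grid_volume()
        with pytest.raises(PhantomNotFoundError):
            pc.locate_active_center(vol)

    def test_tiny_component_not_found(self):
        vals = np.zeros((60, 60, 40))
        vals[30, 30, 20] = 100.0  # single hot voxel, far below 5 mL
        vol = grid_volume(values=vals)
        with pytest.raises(PhantomNotFoundError):
            pc.locate_active_center(vol)


class TestPlateauAccuracy:
    def test_interior_roi_mean_matches_plateau(self, pet_vol, default_scene):
        """With the box >= 3 PSF sigmas from edges the ROI mean keeps the
        plateau value to 0.1% (no partial-volume contamination)."""
        center = pc.locate_active_center(pet_vol)
        roi = pc.whole_voxel_roi(pet_vol, center, 15.0)
        res = pc.roi_statistics(pet_vol, roi)
        plateau = default_scene.active_concentration_kbq_ml
        assert abs(res.mean - plateau) / plateau < 1e-3


class TestAlignment:
    def test_identical_geometry_aligned(self, pet_vol, ct_vol):
        offset, misaligned = pc.check_alignment(pet_vol, ct_vol)
        assert np.all(np.abs(offset) < np.array(pet_vol.spacing) / 2)
        assert not misaligned

    def test_axial_ct_shift_detected(self, pet_vol, default_scene):
        shifted = pc.misposition(default_scene, translation_mm=(0.0, 0.0, 7.0))
        _, ct = pc.build_scene(shifted)
        offset, misaligned = pc.check_alignment(pet_vol, ct)
        assert misaligned
        assert abs(offset[2] + 7.0) < pet_vol.spacing[2] / 2  # PET minus CT
        assert np.all(np.abs(offset[:2]) < 2.7 / 2)

    def test_missing_phantom_in_ct(self, pet_vol):
        empty_ct = pc.ImageVolume(
            values=np.full((60, 60, 40), -1000.0), spacing=(2.7, 2.7, 3.3),
            origin=(0, 0, 0), modality="CT", value_units="HU",
        )
        with pytest.raises(PhantomNotFoundError):
            pc.check_alignment(pet_vol, empty_ct)

    def test_ct_localization_uses_hu_window(self, ct_vol):
        center = locate_phantom_on_ct(ct_vol)
        assert np.all(np.abs(center) < np.array(ct_vol.spacing) / 2)
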