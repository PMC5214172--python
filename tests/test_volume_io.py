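"""Volume conversions (concentration, SUV) and series / record round trips."""

import json
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

import petcrosscal as pc
from petcrosscal.errors import (
    ConfigurationError,
    ModalityError,
    RecordMismatchError,
    SeriesReadError,
)

T0 = datetime(2013, 4, 1, 12, 0, tzinfo=timezone.utc)


def make_volume(values, units="kBq/mL", modality="PET", **kwargs):
    values = np.asarray(values, dtype=float)
    defaults = dict(
        spacing=(2.7, 2.7, 3.3),
        origin=(0.0, 0.0, 0.0),
        modality=modality,
        value_units=units,
        acquisition_datetime=T0,
        decay_reference_datetime=T0 if modality == "PET" else None,
    )
    defaults.update(kwargs)
    return pc.ImageVolume(values=values, **defaults)


class TestImageVolume:
    def test_geometry_is_mandatory(self):
        with pytest.raises(ConfigurationError):
            make_volume(np.ones((2, 2, 2)), spacing=(0.0, 1.0, 1.0))
        with pytest.raises(TypeError):
            pc.ImageVolume(values=np.ones((2, 2, 2)))  # no spacing/origin at all

    def test_units_must_match_modality(self):
        with pytest.raises(ConfigurationError):
            make_volume(np.ones((2, 2, 2)), units="HU", modality="PET")
        with pytest.raises(ConfigurationError):
            make_volume(np.ones((2, 2, 2)), units="kBq/mL", modality="CT")

    def test_physical_index_round_trip(self):
        vol = make_volume(np.ones((4, 5, 6)), origin=(-10.0, 0.0, 5.0))
        pt = vol.index_to_physical([1, 2, 3])
        assert np.allclose(vol.physical_to_index(pt), [1, 2, 3])


class TestToConcentration:
    def test_pure_unit_conversion_at_reference(self):
        vol = make_volume(np.full((2, 2, 2), 250000.0), units="Bq/mL")
        conc = pc.to_concentration(vol, pc.GE68, T0)
        assert conc.value_units == "kBq/mL"
        assert np.allclose(conc.values, 250.0)

    def test_decay_halves_after_one_half_life(self):
        vol = make_volume(np.full((2, 2, 2), 100.0))
        conc = pc.to_concentration(vol, pc.GE68, T0 + timedelta(days=270.95))
        assert np.allclose(conc.values, 50.0)

    def test_ct_rejected(self):
        ct = make_volume(np.zeros((2, 2, 2)), units="HU", modality="CT")
        with pytest.raises(ModalityError):
            pc.to_concentration(ct, pc.GE68, T0)


class TestToSuv:
    def test_uniform_distribution_gives_suv_one(self):
        """Tracer spread evenly through a unit-density body has SUV 1 everywhere."""
        for injected_mbq, volume_l in [(370.0, 70.0), (185.0, 55.0)]:
            conc_kbq_ml = injected_mbq * 1000.0 / (volume_l * 1000.0)  # A = I / V
            weight_kg = volume_l  # 1 g/mL body density
            vol = make_volume(np.full((3, 3, 3), conc_kbq_ml))
            suv = pc.to_suv(vol, pc.InjectionRecord(injected_mbq, T0, weight_kg))
            assert suv.value_units == "SUV"
            assert np.allclose(suv.values, 1.0, rtol=1e-12)

    def test_hand_computed_value(self):
        # 2 kBq/mL with 100 MBq into 50 kg: 2 / (100000 kBq / 50000 g) = 1.0 g/mL
        vol = make_volume(np.full((2, 2, 2), 2.0))
        suv = pc.to_suv(vol, pc.InjectionRecord(100.0, T0, 50.0))
        assert np.allclose(suv.values, 1.0)

    def test_linearity_in_injected_activity(self):
        vol = make_volume(np.full((2, 2, 2), 2.0))
        suv1 = pc.to_suv(vol, pc.InjectionRecord(100.0, T0, 50.0))
        suv2 = pc.to_suv(vol, pc.InjectionRecord(200.0, T0, 50.0))
        assert np.allclose(suv2.values, suv1.values / 2.0)

    def test_common_decay_correction_cancels(self):
        """Decaying A and I to any common instant leaves the SUV unchanged."""
        vol = make_volume(np.full((2, 2, 2), 3.5))
        inj = pc.InjectionRecord(150.0, T0, 60.0)
        base = pc.to_suv(vol, inj)
        later = T0 + timedelta(hours=5)
        vol2 = pc.to_concentration(vol, pc.F18, later)
        factor = pc.decay_factor(pc.F18, later - T0)
        inj2 = pc.InjectionRecord(150.0 * factor, T0, 60.0)
        assert np.allclose(pc.to_suv(vol2, inj2).values, base.values, rtol=1e-12)

    def test_invalid_record_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.InjectionRecord(0.0, T0, 50.0)
        with pytest.raises(ConfigurationError):
            pc.InjectionRecord(100.0, T0, 0.0)


class TestSeriesRoundTrip:
    @pytest.mark.parametrize("fmt", ["dicom", "nifti"])
    def test_pet_round_trip(self, pet_vol, tmp_path, fmt):
        pc.render_series(pet_vol, tmp_path / fmt, format=fmt)
        back = pc.read_series(tmp_path / fmt)
        assert back.modality == "PET"
        assert back.spacing == pet_vol.spacing
        assert np.allclose(back.origin, pet_vol.origin)
        assert back.decay_reference_datetime == pet_vol.decay_reference_datetime
        conc = pc.to_concentration(back, pc.GE68, back.decay_reference_datetime)
        # declared write precision: 0.1% of the volume maximum
        tol = 1e-3 * pet_vol.values.max()
        assert np.abs(conc.values - pet_vol.values).max() < tol

    def test_ct_round_trip(self, ct_vol, tmp_path):
        pc.render_series(ct_vol, tmp_path / "ct", format="dicom")
        back = pc.read_series(tmp_path / "ct")
        assert back.modality == "CT" and back.value_units == "HU"
        assert np.abs(back.values - ct_vol.values).max() < 0.51  # 1 HU quantization

    def test_shuffled_slice_files_sort_to_same_volume(self, pet_vol, tmp_path):
        src = tmp_path / "series"
        paths = pc.render_series(pet_vol, src, format="dicom")
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        rng = np.random.default_rng(0)
        for p, j in zip(paths, rng.permutation(len(paths))):
            (shuffled / f"slice_{j:04d}.dcm").write_bytes(p.read_bytes())
        a = pc.read_series(src)
        b = pc.read_series(shuffled)
        assert np.array_equal(a.values, b.values)
        assert a.origin == b.origin

    def test_mixed_series_rejected(self, pet_vol, tmp_path):
        pc.render_series(pet_vol, tmp_path / "a", format="dicom")
        pc.render_series(pet_vol, tmp_path / "b", format="dicom")
        mixed = tmp_path / "mixed"
        mixed.mkdir()
        for sub in ("a", "b"):
            for p in (tmp_path / sub).glob("*.dcm"):
                (mixed / f"{sub}_{p.name}").write_bytes(p.read_bytes())
        with pytest.raises(SeriesReadError, match="series"):
            pc.read_series(mixed)

    def test_nifti_without_sidecar_rejected(self, pet_vol, tmp_path):
        pc.render_series(pet_vol, tmp_path, format="nifti")
        (tmp_path / "volume.json").unlink()
        with pytest.raises(SeriesReadError, match="sidecar"):
            pc.read_series(tmp_path)


def make_record(**overrides):
    kwargs = dict(
        site_id="site-a",
        scanner_id="scanner-1",
        dose_calibrator_id="dc-1",
        measurement_datetime=T0,
        phantom_r=0.95,
        dose_calibrator_r=1.0,
        acf=5.0e7,
        phantom_age_days=100.0,
        roi={"mean": 237.5, "sd": 2.0, "max": 240.0, "min": 233.0, "n_voxels": 100,
             "u_percent": 0.84, "value_units": "kBq/mL", "center_mm": [0, 0, 0],
             "box_mm": 15.0, "index_ranges": [[39, 44], [39, 44], [21, 25]]},
    )
    kwargs.update(overrides)
    return pc.CalibrationRecord(**kwargs)


class TestRecordsIO:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = pc.write_records([], tmp_path / "r.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("site_id,scanner_id,")
        assert pc.read_records(path) == []

    def test_single_record_row(self, tmp_path):
        rec = make_record()
        path = pc.write_records([rec], tmp_path / "r.csv")
        rows = path.read_text().strip().splitlines()
        assert len(rows) == 2
        got = pc.read_records(path)[0]
        assert got.phantom_r == rec.phantom_r
        assert got.suv_bias == pytest.approx(rec.suv_bias)

    def test_round_trip_is_lossless(self, tmp_path):
        recs = [
            make_record(),
            make_record(site_id="site-b", phantom_r=0.92,
                        measurement_datetime=T0 + timedelta(days=30)),
        ]
        path = pc.write_records(recs, tmp_path / "r.csv")
        back = pc.read_records(path)
        assert back == recs

    def test_identical_inputs_give_identical_bytes(self, tmp_path):
        recs = [make_record()]
        p1 = pc.write_records(recs, tmp_path / "a.csv")
        p2 = pc.write_records(recs, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_bias_mismatch_rejected_on_load(self, tmp_path):
        path = pc.write_records([make_record()], tmp_path / "r.csv")
        text = path.read_text().replace("-0.05", "-0.01")
        path.write_text(text)
        with pytest.raises(RecordMismatchError):
            pc.read_records(path)
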