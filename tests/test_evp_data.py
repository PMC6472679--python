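"""Data-model validation and CSV round-trips for the three record kinds."""

import numpy as np
import pandas as pd
import pytest

from sbcc_eval.evp_data import (
    DOSeries,
    INTERNAL,
    ValidationError,
    VelocityField,
    WaveRecord,
    read_do_series,
    read_velocity_field,
    read_wave_records,
    write_do_series,
    write_velocity_field,
    write_wave_records,
)


class TestVelocityField:
    def test_roundtrip_preserves_grid_and_metadata(self, small_field, tmp_path):
        path = tmp_path / "f.csv"
        write_velocity_field(small_field, path)
        back = read_velocity_field(path)
        assert list(back.times) == list(small_field.times)
        np.testing.assert_allclose(back.heights, small_field.heights)
        np.testing.assert_allclose(back.speed, small_field.speed, rtol=1e-9)
        assert back.provenance == small_field.provenance
        assert back.cadence == small_field.cadence
        assert back.water_depth_ref == small_field.water_depth_ref

    def test_blank_cell_becomes_single_missing_mark(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "time,1.0,2.0\n"
            "2016-01-01T00:00:00,0.1,0.2\n"
            "2016-01-01T00:10:00,,0.3\n"
        )
        f = read_velocity_field(path)
        assert f.n_missing == 1
        assert np.isnan(f.speed[1, 0])

    def test_unparseable_speed_becomes_missing(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,1.0\n2016-01-01T00:00:00,abc\n2016-01-01T00:10:00,0.2\n"
        )
        f = read_velocity_field(path)
        assert f.n_missing == 1

    def test_empty_times_writes_header_only(self, tmp_path):
        f = VelocityField(
            times=pd.DatetimeIndex([]), heights=[1.0, 2.0],
            speed=np.empty((0, 2)), cadence=600.0,
        )
        path = tmp_path / "empty.csv"
        write_velocity_field(f, path)
        back = read_velocity_field(path)
        assert len(back.times) == 0
        np.testing.assert_allclose(back.heights, [1.0, 2.0])

    def test_duplicate_timestamp_error_names_timestamp(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "time,1.0\n2016-01-01T00:00:00,0.1\n2016-01-01T00:00:00,0.2\n"
        )
        with pytest.raises(ValidationError, match="2016-01-01T00:00:00"):
            read_velocity_field(path)

    def test_non_monotonic_time_is_hard_error(self, tmp_path):
        path = tmp_path / "rev.csv"
        path.write_text(
            "time,1.0\n2016-01-01T00:10:00,0.1\n2016-01-01T00:00:00,0.2\n"
        )
        with pytest.raises(ValidationError, match="non-monotonic"):
            read_velocity_field(path)

    def test_long_format_dialect(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "Date,z,u\n"
            "2016-01-01T00:00:00,1.0,0.1\n"
            "2016-01-01T00:00:00,2.0,0.2\n"
            "2016-01-01T00:10:00,1.0,0.15\n"
            "2016-01-01T00:10:00,2.0,0.25\n"
        )
        f = read_velocity_field(path, dialect={"time": "Date", "height": "z", "speed": "u"})
        assert f.speed.shape == (2, 2)
        assert f.speed[1, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(heights=[2.0, 1.0], speed=np.zeros((2, 2))), "heights"),
            (dict(heights=[1.0, 2.0], speed=np.zeros((3, 1))), "shape"),
            (dict(heights=[1.0], speed=-np.ones((2, 1))), "speed"),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs, message):
        n = kwargs["speed"].shape[0]
        times = pd.date_range("2016-01-01", periods=n, freq="600s")
        with pytest.raises(ValidationError, match=message):
            VelocityField(times=times, cadence=600.0, **kwargs)

    def test_z_conversion_centralised(self, small_field):
        z = small_field.z_below_surface()
        np.testing.assert_allclose(z, [1.24 - 30.0, 10.0 - 30.0])
        assert (z <= 0).all()

    def test_to_xarray_carries_provenance(self, small_field):
        da = small_field.to_xarray()
        assert da.attrs["provenance"] == "external"
        assert da.shape == (3, 2)


class TestWaveRecords:
    def test_storm_record_roundtrip(self, tmp_path):
        recs = [WaveRecord("2013-03-10T19:36:00", 3.99, 7.4)]
        path = tmp_path / "waves.csv"
        write_wave_records(recs, path)
        back = read_wave_records(path)
        assert len(back) == 1
        assert back[0].H == pytest.approx(3.99)
        assert back[0].T == pytest.approx(7.4)

    def test_zero_height_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,H,T\n2013-03-10T19:36:00,0,7.4\n")
        with pytest.raises(ValidationError, match="row 0"):
            read_wave_records(path)


class TestDOSeries:
    def test_roundtrip_with_temperature(self, tmp_path):
        s = DOSeries(
            times=pd.date_range("2016-01-01", periods=3, freq="7D"),
            concentration=[8.98, 9.5, 10.1],
            temperature=[15.9, np.nan, 12.0],
        )
        path = tmp_path / "do.csv"
        write_do_series(s, path)
        back = read_do_series(path)
        np.testing.assert_allclose(back.concentration, s.concentration)
        np.testing.assert_allclose(back.temperature, s.temperature)

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ValidationError, match="row 1"):
            DOSeries(
                times=pd.date_range("2016-01-01", periods=2, freq="D"),
                concentration=[9.0, -1.0],
            )


def test_internal_provenance_survives_roundtrip(small_field, tmp_path):
    internal = VelocityField(
        times=small_field.times, heights=small_field.heights,
        speed=small_field.speed, cadence=600.0, provenance=INTERNAL,
    )
    path = tmp_path / "ivp.csv"
    write_velocity_field(internal, path)
    assert read_velocity_field(path).provenance == INTERNAL
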