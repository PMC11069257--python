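import numpy as np
import pytest

from affinichrom import (
    Chromatogram,
    ChromatogramMeta,
    ColumnSystem,
    capacity_factor,
    detect_apex_peak,
    peak_area,
    read_chromatogram,
    remove_baseline,
    write_chromatogram,
)
from affinichrom.chromatograms import ChromatogramError, read_metadata


def _write_csv(path, rows, header=None):
    lines = ([header] if header else []) + [f"{t},{y}" for t, y in rows]
    path.write_text("\n".join(lines))


class TestReadChromatogram:
    def test_short_file_rejected(self, tmp_path):
        f = tmp_path / "short.csv"
        _write_csv(f, [(0, 0), (1, 1), (2, 0)])
        with pytest.raises(ChromatogramError, match="fewer than 8"):
            read_chromatogram(f)

    def test_duplicate_time_rejected(self, tmp_path):
        f = tmp_path / "dup.csv"
        rows = [(t, 0.0) for t in [0, 1, 1, 2, 3, 4, 5, 6, 7]]
        _write_csv(f, rows)
        with pytest.raises(ChromatogramError, match="duplicate time"):
            read_chromatogram(f)

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("time_min,signal\n0,0\n1,oops\n2,0\n")
        with pytest.raises(ChromatogramError, match="bad.csv:3"):
            read_chromatogram(f)

    def test_rows_sorted_by_time(self, tmp_path):
        f = tmp_path / "unsorted.csv"
        rows = [(t, float(t)) for t in [3, 1, 0, 2, 4, 5, 6, 7]]
        _write_csv(f, rows, header="time_min,signal")
        chrom = read_chromatogram(f)
        assert np.all(np.diff(chrom.time) > 0)
        np.testing.assert_allclose(chrom.signal, chrom.time)

    def test_round_trip_full_precision(self, tmp_path, simulated_chromatogram):
        f = tmp_path / "peak.csv"
        write_chromatogram(simulated_chromatogram, f)
        back = read_chromatogram(f)
        np.testing.assert_array_equal(back.time, simulated_chromatogram.time)
        np.testing.assert_array_equal(back.signal, simulated_chromatogram.signal)

    def test_sidecar_metadata(self, tmp_path):
        f = tmp_path / "meta.txt"
        f.write_text("analyte=atropine\nconcentration=4e-4\nflow_rate=0.2\n")
        meta = read_metadata(f)
        assert meta.analyte == "atropine"
        assert meta.concentration == pytest.approx(4e-4)
        j = tmp_path / "meta.json"
        j.write_text('{"analyte": "x", "injection_volume": 1e-5}')
        assert read_metadata(j).injection_volume == pytest.approx(1e-5)


class TestCapacityFactor:
    @pytest.mark.parametrize(
        "tR,t0,expected",
        [(1.9, 1.9, 0.0), (10.0, 1.9, 4.2632), (2.2, 1.9, 0.1579)],
    )
    def test_values(self, tR, t0, expected):
        assert capacity_factor(tR, t0) == pytest.approx(expected, abs=5e-5)

    def test_negative_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="precedes the void"):
            k = capacity_factor(1.0, 2.0)
        assert k == pytest.approx(-0.5)

    def test_invalid_void_time(self):
        with pytest.raises(ValueError):
            capacity_factor(1.0, 0.0)

    def test_strictly_increasing_in_tR(self):
        tRs = np.linspace(2.0, 20.0, 50)
        ks = [capacity_factor(t, 1.9) for t in tRs]
        assert np.all(np.diff(ks) > 0)


class TestBaseline:
    def test_exact_linear_removal(self, simulated_chromatogram):
        chrom = simulated_chromatogram
        drifted = chrom.copy_with(chrom.signal + 2.0 + 0.1 * chrom.time)
        cleaned = remove_baseline(drifted, window_frac=0.05)
        np.testing.assert_allclose(cleaned.signal, chrom.signal, atol=1e-9)

    def test_zero_baseline_is_identity(self, simulated_chromatogram):
        cleaned = remove_baseline(simulated_chromatogram, window_frac=0.05)
        np.testing.assert_allclose(cleaned.signal, simulated_chromatogram.signal, atol=1e-12)

    def test_apex_in_window_falls_back(self):
        t = np.linspace(0, 1, 100)
        y = np.exp(-0.5 * ((t - 0.02) / 0.01) ** 2) + 1.0  # apex at the left edge
        with pytest.warns(UserWarning, match="baseline window"):
            cleaned = remove_baseline(Chromatogram(t, y), window_frac=0.3)
        assert cleaned.signal.min() == pytest.approx(0.0)

    def test_drift_changes_area_under_two_percent(self, moderate_params):
        from affinichrom import simulate_peak

        rng = np.random.default_rng(11)
        chrom = simulate_peak(moderate_params, t0_min=1.9)
        noise = rng.normal(0, 0.005 * chrom.signal.max(), len(chrom))
        drift = 0.02 * chrom.time + 0.5
        noisy = chrom.copy_with(chrom.signal + noise + drift)
        cleaned = remove_baseline(noisy, window_frac=0.05)
        lo, hi = chrom.t_span
        a_clean = peak_area(cleaned, lo, hi)
        a_ref = peak_area(chrom, lo, hi)
        assert abs(a_clean - a_ref) / a_ref < 0.02


class TestDetectApexPeak:
    def test_single_simulated_peak(self, simulated_chromatogram, moderate_params):
        peaks = detect_apex_peak(simulated_chromatogram, 0.05)
        assert len(peaks) == 1
        # apex within one grid step of the true profile maximizer
        dt = simulated_chromatogram.time[1] - simulated_chromatogram.time[0]
        from affinichrom import thomas_profile

        xfine = np.arange(0.001, 12, 0.0005)
        x_star = xfine[np.argmax(thomas_profile(xfine, moderate_params))]
        assert abs(peaks[0].retention_time - 1.9 * x_star) <= dt

    def test_two_gaussians_in_order(self):
        t = np.linspace(0, 10, 2000)
        y = np.exp(-0.5 * ((t - 3) / 0.2) ** 2) + 0.8 * np.exp(-0.5 * ((t - 7) / 0.3) ** 2)
        peaks = detect_apex_peak(Chromatogram(t, y), 0.1)
        assert len(peaks) == 2
        assert peaks[0].retention_time < peaks[1].retention_time
        assert peaks[0].retention_time == pytest.approx(3.0, abs=0.01)
        assert peaks[1].retention_time == pytest.approx(7.0, abs=0.01)

    def test_flat_signal_empty(self):
        t = np.linspace(0, 1, 50)
        assert detect_apex_peak(Chromatogram(t, np.zeros_like(t)), 0.1) == []
        assert detect_apex_peak(Chromatogram(t, np.ones_like(t)), 0.1) == []

    def test_capacity_factor_attached(self):
        t = np.linspace(0, 10, 2000)
        y = np.exp(-0.5 * ((t - 5.7) / 0.2) ** 2)
        system = ColumnSystem(t0=1.9)
        (peak,) = detect_apex_peak(Chromatogram(t, y), 0.1, system)
        assert peak.capacity_factor == pytest.approx(2.0, abs=0.01)


class TestPeakArea:
    def test_unit_rectangle(self):
        t = np.linspace(0, 3, 301)
        y = np.where((t >= 1.0) & (t <= 2.0), 1.0, 0.0)
        assert peak_area(Chromatogram(t, y), 1.0, 2.0) == pytest.approx(1.0)

    def test_triangle(self):
        # height 2, base 1 -> area 1
        t = np.linspace(0, 1, 1001)
        y = 2.0 * (1.0 - np.abs(2.0 * t - 1.0))
        assert peak_area(Chromatogram(t, y), 0.0, 1.0) == pytest.approx(1.0, rel=1e-5)

    def test_window_outside_grid(self, simulated_chromatogram):
        with pytest.raises(ValueError, match="outside"):
            peak_area(simulated_chromatogram, -1.0, 2.0)

    def test_matches_quadrature_oracle(self, simulated_chromatogram, moderate_params):
        from scipy.integrate import quad

        from affinichrom import thomas_profile

        lo, hi = simulated_chromatogram.t_span
        area = peak_area(simulated_chromatogram, lo, hi)
        oracle, _ = quad(
            lambda t: thomas_profile(np.atleast_1d(t / 1.9), moderate_params)[0],
            lo, hi, limit=300,
        )
        assert area == pytest.approx(oracle, rel=0.005)


class TestColumnSystem:
    def test_default_pipeline_volume_is_void_volume(self):
        sys_ = ColumnSystem(t0=1.9, flow_rate=0.2)
        assert sys_.pipeline_volume == pytest.approx(3.8e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ColumnSystem(t0=-1.0)
        with pytest.raises(ValueError):
            ColumnSystem(t0=1.9, flow_rate=0.0)
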