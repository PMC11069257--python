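import numpy as np
import pytest

from affinichrom import (
    ColumnSystem,
    ZonalBindingModel,
    ZonalPoint,
    fit_zonal_line,
    make_zonal_points,
    split_regimes,
)
from affinichrom.synthetic import ZonalTruth, generate_zonal_dataset

SYSTEM = ColumnSystem(t0=1.9, flow_rate=0.2)  # Vm = 3.8e-4 L (void volume)


def points_on_line(intercept: float, slope_mag: float, X: np.ndarray) -> list[ZonalPoint]:
    """Exact points on Y = intercept - slope_mag * X, with self-consistent
    k', n_b back-computed from the coordinates."""
    pts = []
    for Xi in X:
        Yi = intercept - slope_mag * Xi
        k = Xi / SYSTEM.pipeline_volume
        n_b = Yi * (1 + k) / k
        pts.append(ZonalPoint(concentration=n_b / 10e-6, k_prime=k, n_b=n_b, X=Xi, Y=Yi))
    return pts


class TestMakeZonalPoints:
    def test_injected_moles(self):
        records = [(1e-3, 10.0), (2e-3, 9.0), (3e-3, 8.0)]
        pts = make_zonal_points(records, SYSTEM, injection_volume=10e-6)
        assert pts[0].n_b == pytest.approx(1e-8)

    def test_void_coeluting_record_excluded(self):
        records = [(1e-3, 10.0), (2e-3, 9.0), (3e-3, 1.9)]
        with pytest.warns(UserWarning, match="excluded"):
            pts = make_zonal_points(records, SYSTEM)
        assert len(pts) == 2

    def test_requires_increasing_concentrations(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_zonal_points([(1e-3, 10.0), (1e-3, 9.0), (2e-3, 8.0)], SYSTEM)

    def test_generated_points_follow_negative_slope(self):
        truth = ZonalTruth(K_A=8e4, n_t=2.42e-8,
                           concentrations=tuple(np.linspace(2.5e-4, 1e-3, 6)))
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        X = np.array([p.X for p in pts])
        Y = np.array([p.Y for p in pts])
        assert np.all(np.diff(Y[np.argsort(X)]) < 0)


class TestFitZonalLine:
    @pytest.mark.parametrize(
        "intercept,slope_mag,expected_KA",
        [
            # printed regressions of the reference drugs: K_A = 1/slope
            (2.42e-8, 1.25e-5, 8.00e4),     # atropine, low range
            (1.41e-7, 1.02e-4, 0.98e4),     # atropine, high range
            (3.75e-9, 3.84e-6, 26.04e4),    # pirenzepine, low range
            (3.14e-8, 4.27e-5, 2.34e4),     # pirenzepine, high range
            (2.76e-8, 1.29e-5, 7.75e4),     # darifenacin
            (4.40e-8, 8.33e-6, 12.01e4),    # solifenacin
        ],
    )
    def test_printed_regressions_recovered(self, intercept, slope_mag, expected_KA):
        X = np.linspace(0.2, 1.5, 6) * intercept / slope_mag
        fit = fit_zonal_line(points_on_line(intercept, slope_mag, X))
        assert fit.K_A == pytest.approx(expected_KA, rel=1e-3)
        assert fit.n_t == pytest.approx(intercept, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_horizontal_line_has_no_K_A(self):
        pts = points_on_line(1e-8, 0.0, np.linspace(1e-4, 5e-4, 5))
        fit = fit_zonal_line(pts)
        assert fit.K_A is None
        assert "K_A undefined" in fit.diagnostic

    def test_noiseless_recovery_sub_permille(self):
        truth = ZonalTruth(K_A=7.75e4, n_t=2.76e-8,
                           concentrations=tuple(np.linspace(5e-4, 2e-3, 7)))
        records, _ = generate_zonal_dataset(truth)
        model = ZonalBindingModel.from_records(records, SYSTEM)
        fit = model.fit()
        assert fit.K_A == pytest.approx(truth.K_A, rel=1e-3)
        assert fit.n_t == pytest.approx(truth.n_t, rel=1e-3)

    def test_leave_one_out_stability(self):
        truth = ZonalTruth(K_A=12e4, n_t=4.4e-8, tR_noise_sd=0.002, seed=5,
                           concentrations=tuple(np.linspace(2e-4, 1e-3, 8)))
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        full = fit_zonal_line(pts)
        for i in range(len(pts)):
            sub = fit_zonal_line(pts[:i] + pts[i + 1:])
            assert abs(sub.K_A - full.K_A) < 3 * full.K_A_se


class TestSplitRegimes:
    def test_biphasic_auto_split_finds_breakpoint(self):
        truth = ZonalTruth(
            K_A=26e4, n_t=3.75e-9, K_A2=2.3e4, n_t2=3.14e-8, breakpoint=1.5e-4,
            concentrations=(1e-5, 2e-5, 4e-5, 8e-5, 1.5e-4, 3e-4, 6e-4, 1.2e-3, 1.8e-3),
        )
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        result = split_regimes(pts, "auto")
        assert isinstance(result, tuple)
        lo, hi = result
        assert lo.concentration_range[1] <= 1.5e-4 < hi.concentration_range[0]
        assert lo.K_A == pytest.approx(26e4, rel=0.02)
        assert hi.K_A == pytest.approx(2.3e4, rel=0.02)

    def test_single_site_stays_single(self):
        truth = ZonalTruth(K_A=7.75e4, n_t=2.76e-8,
                           concentrations=tuple(np.linspace(1e-4, 2e-3, 8)))
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        result = split_regimes(pts, "auto")
        assert not isinstance(result, tuple)
        assert result.regime == "single"

    def test_explicit_breakpoint(self):
        truth = ZonalTruth(
            K_A=8e4, n_t=2.42e-9, K_A2=0.98e4, n_t2=1.41e-7, breakpoint=1e-3,
            concentrations=(2.5e-4, 5e-4, 7.5e-4, 1e-3, 1.25e-3, 2e-3, 3e-3, 4e-3),
        )
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        lo, hi = split_regimes(pts, 1e-3)
        assert lo.regime == "low" and hi.regime == "high"
        assert lo.K_A == pytest.approx(8e4, rel=0.01)
        assert hi.K_A == pytest.approx(0.98e4, rel=0.01)

    def test_too_few_points_falls_back(self):
        truth = ZonalTruth(K_A=8e4, n_t=2.42e-8,
                           concentrations=(2.5e-4, 5e-4, 7.5e-4, 1e-3))
        records, _ = generate_zonal_dataset(truth)
        pts = make_zonal_points(records, SYSTEM)
        with pytest.warns(UserWarning, match="single regime"):
            result = split_regimes(pts, "auto")
        assert not isinstance(result, tuple)

    def test_two_point_input_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_zonal_line(points_on_line(1e-8, 1e-5, np.array([1e-4, 2e-4])))


class TestCrossMethodAgreement:
    def test_zonal_and_kinetic_K_A_same_order(self):
        """The saturation-line K_A and the peak-shape K_A describe the same
        equilibrium and must land at a similar level on data generated
        from one truth.  Apex-based zonal readout under overload inflates
        K_A relative to the peak-shape estimate (the reference drug
        measurements show the same spread, up to ~6x), so the check is
        one order of magnitude."""
        from affinichrom import fit_peak_series
        from affinichrom.chromatograms import detect_apex_peak
        from affinichrom.synthetic import SyntheticTruth, generate_peak_series

        truth = SyntheticTruth(
            K_A=1.28e4, k_d=63.0, k_prime=4.26,
            concentrations=(2.5e-4, 5e-4, 1e-3, 2e-3, 3e-3), noise_sd=0.0,
        )
        chroms, _ = generate_peak_series(truth)
        ctxs = [truth.context(c) for c in truth.concentrations]
        fits = fit_peak_series(chroms, ctxs)
        K_A_kinetic = np.median([r.binding_constants.K_A for _, r in fits])

        records = []
        for conc, chrom in zip(truth.concentrations, chroms):
            (peak,) = detect_apex_peak(chrom, 0.05)
            records.append((conc, peak.retention_time))
        pts = make_zonal_points(records, SYSTEM)
        fit = fit_zonal_line(pts)
        assert 0.1 < fit.K_A / K_A_kinetic < 10.0
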