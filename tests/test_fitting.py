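"""Normalization and nonlinear least-squares g2(0) retrieval."""

import numpy as np
import pytest

from antibunch import (
    CorrelationHistogram,
    EmitterSpec,
    HistogramFormat,
    ScanConfig,
    ThreeLevelParams,
    fit_g2,
    fit_scan,
    g2_three_level,
    mixed_g2,
    normalize_histogram,
    simulate_scan,
)
from antibunch.simulate import expected_histogram, pixel_signal_rates


def _hist_from_curve(params, fmt, baseline=1e6):
    """Integer histogram proportional to the exact model curve."""
    curve = g2_three_level(params, fmt.tau)
    counts = np.round(baseline * curve).astype(np.int64)
    return CorrelationHistogram(counts=counts, format=fmt, acquisition_time=1.0)


class TestNormalize:
    def test_flat_histogram_normalizes_to_ones(self, fmt):
        h = CorrelationHistogram(counts=np.full(215, 7), format=fmt)
        y, baseline = normalize_histogram(h)
        assert baseline == 7.0
        np.testing.assert_allclose(y, 1.0)

    def test_ideal_emitter_center_zero_edges_one(self, fmt, ideal_params):
        h = _hist_from_curve(ideal_params, fmt)
        y, _ = normalize_histogram(h)
        assert y[fmt.zero_bin_index] == pytest.approx(0.0, abs=1e-5)
        assert y[0] == pytest.approx(1.0, rel=1e-2)

    def test_baseline_is_outer_bin_mean(self):
        fmt = HistogramFormat(n_bins=20, span=100.0, zero_bin_index=10)
        pattern = np.tile([4, 6, 5, 5], 5)
        h = CorrelationHistogram(counts=pattern, format=fmt)
        _, baseline = normalize_histogram(h)
        assert baseline == 5.0  # outer 20% = 4 bins per side, mean of {4,6,5,5}

    def test_zero_baseline_rejected(self, fmt):
        counts = np.zeros(215, dtype=int)
        counts[107] = 3
        h = CorrelationHistogram(counts=counts, format=fmt)
        with pytest.raises(ValueError):
            normalize_histogram(h)


class TestFitG2:
    def test_recovers_exact_model_curve(self, fmt):
        """Fitting the noiseless model output returns the generating
        parameters (oracle equivalence in the noiseless limit)."""
        truth = ThreeLevelParams(a1=0.9, a2=0.2, t1=25.0, t2=120.0)
        res = fit_g2(_hist_from_curve(truth, fmt))
        assert res.converged
        assert res.g2_zero == pytest.approx(0.3, abs=1e-4)
        assert res.params.a1 == pytest.approx(truth.a1, abs=1e-3)
        assert res.params.t1 == pytest.approx(truth.t1, rel=1e-2)

    def test_g2_zero_identity_holds(self, fmt):
        truth = ThreeLevelParams(a1=0.8, a2=0.1, t1=35.0, t2=150.0)
        res = fit_g2(_hist_from_curve(truth, fmt))
        assert res.g2_zero == pytest.approx(1.0 - res.params.a1 + res.params.a2, abs=1e-9)

    def test_dense_histogram_within_uncertainty_envelope(self, fmt, rng):
        """~300 events/bin: the estimate lands within +-0.05 of truth."""
        truth = ThreeLevelParams(a1=0.75, a2=0.05, t1=30.0, t2=150.0)
        curve = g2_three_level(truth, fmt.tau)
        counts = rng.poisson(300.0 * curve)
        h = CorrelationHistogram(counts=counts, format=fmt)
        res = fit_g2(h)
        assert res.converged
        assert abs(res.g2_zero - truth.g2_zero) <= 0.05
        assert res.uncertainty < 0.05

    def test_exactly_flat_histogram_reads_one(self, fmt):
        res = fit_g2(CorrelationHistogram(counts=np.full(215, 200), format=fmt))
        assert res.g2_zero == pytest.approx(1.0, abs=1e-6)
        assert res.params.a1 == pytest.approx(0.0, abs=1e-6)

    def test_flat_poissonian_histogram_reads_one(self, fmt, rng):
        """Noisy flat data: g2(0) comes back near 1; the residual spread
        reflects the a1/a2 degeneracy of a featureless histogram."""
        vals = []
        for rep in range(5):
            counts = np.random.default_rng(rep).poisson(200.0, size=215)
            vals.append(fit_g2(CorrelationHistogram(counts=counts, format=fmt)).g2_zero)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_invariant_to_uniform_rescaling(self, fmt, rng):
        truth = ThreeLevelParams(a1=0.9, a2=0.1, t1=25.0, t2=120.0)
        counts = rng.poisson(150.0 * g2_three_level(truth, fmt.tau))
        h1 = CorrelationHistogram(counts=counts, format=fmt)
        h2 = CorrelationHistogram(counts=counts * 9, format=fmt)
        assert fit_g2(h1).g2_zero == pytest.approx(fit_g2(h2).g2_zero, abs=1e-6)

    def test_sparse_histogram_is_flagged(self, fmt):
        counts = np.zeros(215, dtype=int)
        counts[50] = 2
        res = fit_g2(CorrelationHistogram(counts=counts, format=fmt))
        assert not res.converged
        assert res.g2_zero == 1.0
        assert np.isinf(res.uncertainty)

    def test_error_shrinks_with_acquisition_time(self, fmt):
        """Median |error| decreases monotonically over T in {5, 60, 600} s
        at a fixed per-second rate (estimator consistency)."""
        truth = ThreeLevelParams(a1=0.85, a2=0.05, t1=30.0, t2=150.0)
        curve = g2_three_level(truth, fmt.tau)
        per_s = 1.5  # expected events per bin per second
        med = []
        for T in (5.0, 60.0, 600.0):
            errs = []
            for rep in range(12):
                rng = np.random.default_rng(1000 + rep)
                counts = rng.poisson(per_s * T * curve)
                res = fit_g2(CorrelationHistogram(counts=counts, format=fmt))
                errs.append(abs(res.g2_zero - truth.g2_zero) if res.converged else 1.0)
            med.append(np.median(errs))
        assert med[2] < med[1] < med[0]


class TestFitScan:
    def test_background_only_scan_maps_to_one(self):
        cfg = ScanConfig(grid=(3, 3), slices_per_pixel=2, background_rate=2000.0, seed=1)
        scan = simulate_scan(cfg, [])
        g2map, results = fit_scan(scan, 2.0)
        assert np.allclose(g2map.values, 1.0, atol=0.25)
        assert all(not r.converged for row in results for r in row)

    def test_dense_pixel_reproduces_mixed_g2(self):
        """Long-dwell scan: the fitted focal pixel matches the pixel's
        signal/background mixture within the reported uncertainty."""
        cfg = ScanConfig(grid=(3, 3), slices_per_pixel=2, increment=400.0,
                         background_rate=1000.0, seed=7, region=(150.0, 150.0))
        em = EmitterSpec(x=75.0, y=75.0, brightness=15_000.0,
                         params=ThreeLevelParams(a1=1.0, a2=0.05, t1=30.0, t2=150.0))
        scan = simulate_scan(cfg, [em])
        g2map, results = fit_scan(scan, 800.0)
        r, c = 1, 1
        s = pixel_signal_rates([em], cfg.pixel_center(r, c), cfg)[0]
        expected = mixed_g2(s, 1000.0, em.params.g2_zero)
        res = results[r][c]
        assert res.converged
        assert abs(res.g2_zero - expected) < max(3.0 * res.uncertainty, 0.03)

    def test_overlong_request_rejected(self):
        cfg = ScanConfig(grid=(2, 2), slices_per_pixel=3, background_rate=1000.0)
        scan = simulate_scan(cfg, [])
        with pytest.raises(ValueError):
            fit_scan(scan, 4.0)

    def test_non_multiple_time_rejected(self):
        cfg = ScanConfig(grid=(2, 2), slices_per_pixel=3, background_rate=1000.0)
        scan = simulate_scan(cfg, [])
        with pytest.raises(ValueError):
            fit_scan(scan, 2.5)
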