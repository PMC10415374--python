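"""Coincidence expectation model, Poisson sampling and scan simulation."""

import numpy as np
import pytest

from antibunch import (
    EmitterSpec,
    HistogramFormat,
    ScanConfig,
    ThreeLevelParams,
    expected_histogram,
    mixed_g2,
    sample_histogram,
    simulate_scan,
)
from antibunch.simulate import exact_g2_map, pixel_signal_rates
from oracles import stream_pair_counts


def _poissonian_emitter(brightness, x=387.5, y=387.5):
    # a1 = a2 = 0: flat correlation, i.e. a classical source
    return EmitterSpec(x=x, y=y, brightness=brightness,
                       params=ThreeLevelParams(a1=0.0, a2=0.0, t1=25.0, t2=100.0))


class TestExpectedHistogram:
    def test_flat_total_matches_closed_form(self, fmt):
        """With g2 = 1 the expected total is r1*r2*span*T to machine precision."""
        cfg = ScanConfig(background_rate=0.0)
        em = _poissonian_emitter(10_000.0)
        e = expected_histogram([em], (387.5, 387.5), cfg, 1.0)
        r = 10_000.0 / 2.0
        assert e.sum() == pytest.approx(r * r * 500e-9 * 1.0, rel=1e-12)
        # per-bin: r^2 * dtau * T, ~0.058 for r = 5 kcps -> 1 s totals ~12.5,
        # inside the measured 1.2-61 events/s envelope
        assert e[0] == pytest.approx(r * r * (500 / 215) * 1e-9, rel=1e-12)

    def test_linear_in_acquisition_time(self, fmt):
        cfg = ScanConfig(background_rate=300.0)
        em = EmitterSpec(x=300.0, y=400.0, brightness=20_000.0)
        e1 = expected_histogram([em], (380.0, 380.0), cfg, 1.0)
        e2 = expected_histogram([em], (380.0, 380.0), cfg, 2.0)
        np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-12)

    def test_far_pixel_is_background_only(self):
        cfg = ScanConfig(background_rate=0.0)
        em = EmitterSpec(x=0.0, y=0.0, brightness=1e5)
        e = expected_histogram([em], (0.0 + 10 * 131.65, 0.0), cfg, 1.0)
        assert np.all(e < 1e-12)

    def test_zero_rate_rejected(self):
        cfg = ScanConfig(background_rate=0.0)
        with pytest.raises(ValueError):
            expected_histogram([], (0.0, 0.0), cfg, 1.0)

    def test_antibunching_dip_at_zero_bin(self, fmt):
        cfg = ScanConfig(background_rate=0.0)
        em = EmitterSpec(x=387.5, y=387.5, brightness=15_000.0,
                         params=ThreeLevelParams(a1=1.0, a2=0.0, t1=30.0, t2=100.0))
        e = expected_histogram([em], (387.5, 387.5), cfg, 1.0)
        assert e[fmt.zero_bin_index] == pytest.approx(0.0, abs=1e-12)
        assert e[0] > 0

    def test_matches_stream_oracle_on_toy_format(self, toy_fmt, rng):
        """Factorized expectation against direct start-stop pair counting on
        a discretized two-detector Bernoulli stream (3-bin toy format)."""
        dt_ns = toy_fmt.bin_width  # 10 ns per step
        p = 0.08  # photon probability per step (both detectors together)
        steps = 400_000
        # an emitter whose antibunching time is far below the bin width acts
        # memoryless at +-1 bin but can never produce a zero-delay pair
        em = EmitterSpec(x=0.0, y=0.0, brightness=p / (dt_ns * 1e-9),
                         params=ThreeLevelParams(a1=1.0, a2=0.0, t1=1e-3, t2=1.0))
        cfg = ScanConfig(psf_sigma=131.65, background_rate=0.0,
                         histogram_format=toy_fmt)
        T = steps * dt_ns * 1e-9
        expected = expected_histogram([em], (0.0, 0.0), cfg, T)
        observed = stream_pair_counts([p], steps, max_delay=1, rng=rng)
        # Monte-Carlo agreement within ~4 standard errors per bin
        for k in range(3):
            se = max(np.sqrt(expected[k]), 1.0)
            assert abs(observed[k] - expected[k]) < 4.0 * se


class TestSampleHistogram:
    def test_zero_expectation_gives_empty_histogram(self, toy_fmt):
        h = sample_histogram(np.zeros(3), 0, toy_fmt)
        assert h.n_events == 0

    def test_negative_expectation_rejected(self, toy_fmt):
        with pytest.raises(ValueError):
            sample_histogram(np.array([1.0, -0.1, 0.0]), 0, toy_fmt)

    def test_fixed_seed_is_bit_identical(self, fmt):
        e = np.linspace(0.1, 3.0, 215)
        a = sample_histogram(e, 77, fmt)
        b = sample_histogram(e, 77, fmt)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_mean_converges_to_expectation(self, toy_fmt):
        """Mean over 10^4 replicate draws matches the expectation within 4
        standard errors in every bin."""
        e = np.array([0.5, 2.0, 5.0])
        rng = np.random.default_rng(5)
        draws = np.stack([sample_histogram(e, rng, toy_fmt).counts for _ in range(10_000)])
        mean = draws.mean(axis=0)
        se = np.sqrt(e / 10_000)
        assert np.all(np.abs(mean - e) < 4.0 * se)


class TestSimulateScan:
    def _single_emitter_cfg(self, **kw):
        kw.setdefault("grid", (8, 8))
        kw.setdefault("slices_per_pixel", 2)
        kw.setdefault("background_rate", 500.0)
        return ScanConfig(**kw)

    def test_noiseless_pl_peaks_at_emitter(self):
        cfg = self._single_emitter_cfg()
        em = EmitterSpec(x=387.5, y=387.5, brightness=20_000.0)
        scan = simulate_scan(cfg, [em], noiseless=True)
        r, c = np.unravel_index(np.argmax(scan.pl_map), scan.pl_map.shape)
        assert (r, c) in {(3, 3), (3, 4), (4, 3), (4, 4)}

    def test_background_only_scan_is_flat_in_expectation(self):
        cfg = self._single_emitter_cfg(background_rate=2000.0)
        scan = simulate_scan(cfg, [], noiseless=True)
        assert np.all(scan.pl_map == scan.pl_map[0, 0])
        first = scan.histograms[0, 0, 0]
        assert first.max() - first.min() <= 1  # flat up to integer rounding

    def test_seed_reproducibility(self):
        cfg = self._single_emitter_cfg(seed=9)
        em = EmitterSpec(x=387.5, y=387.5, brightness=20_000.0)
        a = simulate_scan(cfg, [em])
        b = simulate_scan(cfg, [em])
        np.testing.assert_array_equal(a.histograms, b.histograms)
        np.testing.assert_array_equal(a.pl_map, b.pl_map)

    def test_bright_and_dark_pixel_event_regimes(self):
        """Focused pixels accumulate tens of events over 5 s while corner
        pixels stay below the dark threshold of 4 events."""
        cfg = ScanConfig(grid=(16, 16), slices_per_pixel=5, background_rate=500.0, seed=3)
        em = EmitterSpec(x=387.5, y=387.5, brightness=20_000.0)
        scan = simulate_scan(cfg, [em])
        bright = scan.histograms[8, 8].sum()
        dark = scan.histograms[0, 0].sum()
        assert bright > 20
        assert dark < 4

    def test_out_of_region_emitter_warns(self):
        cfg = self._single_emitter_cfg()
        far = EmitterSpec(x=5000.0, y=5000.0, brightness=1e4)
        with pytest.warns(UserWarning):
            simulate_scan(cfg, [far], noiseless=True)

    def test_exact_g2_map_matches_mixed_formula(self):
        cfg = self._single_emitter_cfg(background_rate=800.0)
        em = EmitterSpec(x=387.5, y=387.5, brightness=20_000.0,
                         params=ThreeLevelParams(a1=1.0, a2=0.1, t1=30.0, t2=150.0))
        g2 = exact_g2_map(cfg, [em])
        r, c = 4, 4
        s = pixel_signal_rates([em], cfg.pixel_center(r, c), cfg)[0]
        assert g2[r, c] == pytest.approx(mixed_g2(s, 800.0, em.params.g2_zero))

    def test_augmentation_commutes_with_expectation(self):
        """expected_histogram at k*T equals k times the T expectation."""
        cfg = ScanConfig(background_rate=100.0)
        em = EmitterSpec(x=387.5, y=387.5, brightness=1e4)
        e1 = expected_histogram([em], (400.0, 400.0), cfg, 1.0)
        e7 = expected_histogram([em], (400.0, 400.0), cfg, 7.0)
        np.testing.assert_allclose(e7, 7.0 * e1, rtol=1e-12)
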