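"""Reference experiments: simulated twins of the benchmark measurements.

Each function builds its own inputs from the package's study conditions
(no external data), runs the method end to end and returns the measured
quantities:

* a noiseless single-emitter confocal scan (310 nm PSF) whose exact-g2
  reconstruction shows the sqrt(2) FWHM narrowing,
* the same scan with sparse 7 s histograms estimated by the CNN,
* two emitters 600 nm apart under a 465 nm PSF, resolved by the
  CNN-based reconstruction,
* the CNN accuracy benchmark (MAPE / r2 on held-out 5-7 s items,
  paired against the curve-fitting baseline),
* the dense-histogram accuracy contract of the fitting baseline.

Scan emitters are drawn from the same brightness/background family as
the training ensemble (~2e4 cps signal at focus over a ~1 kcps
background) so the regression network operates inside the envelope it
was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import (
    ScenarioBank,
    Scenario,
    _n1s_of_label,
    build_training_corpus,
    compare_estimators,
    corpus_arrays,
    draw_scenarios,
    evaluate,
    focal_expected_histogram,
    simulate_eval_items,
    split_by_scenario,
)
from .emitter import EmitterSpec, ThreeLevelParams, mixed_g2
from .fitting import G2Map, fit_g2
from .histogram import CorrelationHistogram, HistogramFormat
from .nn.model import G2Regressor, ModelSpec, TrainConfig
from .pipeline import cnn_scan_map
from .reconstruct import cross_section, fit_profile, reconstruct
from .simulate import ScanConfig, exact_g2_map, simulate_scan

__all__ = [
    "SINGLE_EMITTER_PSF_SIGMA",
    "TWO_EMITTER_PSF_SIGMA",
    "train_reference_model",
    "single_emitter_noiseless",
    "single_emitter_cnn",
    "two_emitter_cnn",
    "cnn_accuracy_benchmark",
    "lm_dense_accuracy",
]

#: PSF sigma of the single-emitter scan: 310 nm FWHM / (2 sqrt(2 ln 2))
SINGLE_EMITTER_PSF_SIGMA = 131.65
#: PSF sigma of the two-emitter scan: 465 nm FWHM / (2 sqrt(2 ln 2))
TWO_EMITTER_PSF_SIGMA = 197.5

# scan emitter: a bright single NV over the standard background
_SCAN_BRIGHTNESS = 20_000.0  # cps at focus, both detectors
_SCAN_BACKGROUND = 1_000.0  # cps
_SCAN_PARAMS = ThreeLevelParams(a1=1.08, a2=0.1, t1=30.0, t2=150.0)  # g2_em = 0.02


def _single_emitter_setup(seed: int = 0) -> tuple[ScanConfig, list[EmitterSpec]]:
    cfg = ScanConfig(
        region=(775.0, 775.0),
        grid=(32, 32),
        psf_sigma=SINGLE_EMITTER_PSF_SIGMA,
        background_rate=_SCAN_BACKGROUND,
        slices_per_pixel=7,
        seed=seed,
    )
    em = EmitterSpec(x=387.5, y=387.5, brightness=_SCAN_BRIGHTNESS, params=_SCAN_PARAMS)
    return cfg, [em]


def single_emitter_noiseless(seed: int = 0) -> dict:
    """Noiseless 32x32 scan of one centred emitter.

    Returns the Gaussian-fitted FWHM of the photoluminescence
    cross-section and of the reconstruction built from the exact
    per-pixel mixed g2(0) (expected values, no Poisson sampling).
    """
    cfg, emitters = _single_emitter_setup(seed)
    scan = simulate_scan(cfg, emitters, noiseless=True)
    pitch = cfg.pixel_pitch[1]
    x_pl, pl_line = cross_section(scan.pl_map, pixel_pitch=pitch)
    pl_fwhm = fit_profile(x_pl, pl_line)[0].fwhm
    g2 = exact_g2_map(cfg, emitters)
    sr = reconstruct(scan.pl_map, G2Map(values=g2), pixel_pitch=pitch)
    x_sr, sr_line = cross_section(sr)
    sr_fwhm = fit_profile(x_sr, sr_line)[0].fwhm
    return {"pl_fwhm_nm": pl_fwhm, "sr_fwhm_nm": sr_fwhm, "gain": pl_fwhm / sr_fwhm}


def single_emitter_cnn(model: G2Regressor, seed: int = 0, total_time: float = 7.0) -> dict:
    """Sparse single-emitter scan reconstructed from CNN g2 estimates."""
    cfg, emitters = _single_emitter_setup(seed)
    scan = simulate_scan(cfg, emitters)
    pitch = cfg.pixel_pitch[1]
    g2map = cnn_scan_map(model, scan, total_time)
    sr = reconstruct(scan.pl_map, g2map, pixel_pitch=pitch)
    x_sr, sr_line = cross_section(sr)
    sr_fwhm = fit_profile(x_sr, sr_line)[0].fwhm
    x_pl, pl_line = cross_section(scan.pl_map, pixel_pitch=pitch)
    pl_fwhm = fit_profile(x_pl, pl_line)[0].fwhm
    return {"pl_fwhm_nm": pl_fwhm, "sr_fwhm_nm": sr_fwhm, "gain": pl_fwhm / sr_fwhm}


def two_emitter_cnn(model: G2Regressor, seed: int = 0, total_time: float = 7.0) -> dict:
    """Two equal emitters 600 nm apart under a 465 nm FWHM PSF.

    The scan is reconstructed from CNN g2(0) estimates of 7 s sparse
    histograms; the cross-section through both centres is fitted with a
    two-Gaussian model and both lobe FWHMs are reported.
    """
    cfg = ScanConfig(
        region=(2000.0, 2000.0),
        grid=(32, 32),
        psf_sigma=TWO_EMITTER_PSF_SIGMA,
        background_rate=_SCAN_BACKGROUND,
        slices_per_pixel=int(round(total_time)),
        seed=seed,
    )
    emitters = [
        EmitterSpec(x=700.0, y=1000.0, brightness=_SCAN_BRIGHTNESS, params=_SCAN_PARAMS),
        EmitterSpec(x=1300.0, y=1000.0, brightness=_SCAN_BRIGHTNESS, params=_SCAN_PARAMS),
    ]
    scan = simulate_scan(cfg, emitters)
    pitch = cfg.pixel_pitch[1]
    g2map = cnn_scan_map(model, scan, total_time)
    sr = reconstruct(scan.pl_map, g2map, pixel_pitch=pitch)
    x_sr, sr_line = cross_section(sr)
    sr_fits = fit_profile(x_sr, sr_line, n_peaks=2)
    x_pl, pl_line = cross_section(scan.pl_map, pixel_pitch=pitch)
    pl_fits = fit_profile(x_pl, pl_line, n_peaks=2)
    sr_vals = sr.values
    # two-point discrimination: valley-to-peak ratio along the lobe axis
    def valley_ratio(img):
        row = img[np.unravel_index(np.argmax(img), img.shape)[0]]
        i1 = int(round(700.0 / pitch - 0.5))
        i2 = int(round(1300.0 / pitch - 0.5))
        mid = row[(i1 + i2) // 2]
        return float(mid / max(row[i1], row[i2]))

    return {
        "pl_lobe_fwhm_nm": [f.fwhm for f in pl_fits],
        "sr_lobe_fwhm_nm": [f.fwhm for f in sr_fits],
        "sr_lobe_fwhm_mean_nm": float(np.mean([f.fwhm for f in sr_fits])),
        "pl_valley_ratio": valley_ratio(scan.pl_map),
        "sr_valley_ratio": valley_ratio(sr_vals),
    }


def train_reference_model(
    seed: int = 1,
    epochs: int = 100,
    verbose: bool = False,
) -> tuple[G2Regressor, ScenarioBank, tuple[list[Scenario], list[Scenario], list[Scenario]]]:
    """Build the study corpus and train the reference regression model.

    Returns (model, scenario bank, (train, validation, test) scenarios).
    The split is by emitter; the test scenarios feed the accuracy
    benchmark.
    """
    bank = draw_scenarios(seed=seed)
    items = build_training_corpus(bank, seed=seed)
    train, val, test = split_by_scenario(bank)
    bins, n_events, labels, sids = corpus_arrays(items)
    train_mask = np.isin(sids, [s.scenario_id for s in train])
    val_mask = np.isin(sids, [s.scenario_id for s in val])
    model = G2Regressor(ModelSpec(), seed=seed)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    model.fit(
        bins[train_mask], n_events[train_mask], labels[train_mask], cfg,
        val=(bins[val_mask], n_events[val_mask], labels[val_mask]),
        verbose=verbose,
    )
    return model, bank, (train, val, test)


def cnn_accuracy_benchmark(
    model: G2Regressor,
    test_scenarios: list[Scenario],
    seed: int = 1,
    items_per_scenario: int = 25,
) -> dict:
    """Held-out accuracy of the CNN at 5/6/7 s plus the L-M pairing at 5 s."""
    out: dict = {}
    for t in (5.0, 6.0, 7.0):
        items = simulate_eval_items(test_scenarios, t, items_per_scenario, seed=seed + 10)
        out[f"{int(t)}s"] = evaluate(model, items)
    items5 = simulate_eval_items(test_scenarios, 5.0, items_per_scenario, seed=seed + 10)
    paired = compare_estimators(items5, model)
    out["lm_5s"] = paired["lm"]
    out["per_scenario_5s"] = paired["per_scenario"]
    return out


def lm_dense_accuracy(
    seed: int = 1,
    g2_values: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7),
    replicates: int = 20,
    events_per_bin: float = 300.0,
) -> dict:
    """|fitted - true| g2(0) on histograms accumulated to ~300 events/bin.

    For each true mixed g2(0), an emitter from the study family is
    measured until the mean count per bin reaches the target, fitted,
    and the median absolute error over seeded replicates reported.
    """
    fmt = HistogramFormat()
    medians: dict[float, float] = {}
    for m in g2_values:
        n1s = float(_n1s_of_label(m))
        total_rate = 2.0 * np.sqrt(n1s / (fmt.span * 1e-9))
        g2_em = 0.55 * m  # midpoint of the ensemble's intrinsic-g2 band
        rho = float(np.sqrt((1.0 - m) / (1.0 - g2_em)))
        sc = Scenario(
            scenario_id=0,
            signal_rate=rho * total_rate,
            background_rate=(1.0 - rho) * total_rate,
            params=ThreeLevelParams(a1=1.0 - g2_em, a2=0.0, t1=30.0, t2=150.0),
            label=m,
        )
        t_needed = events_per_bin * fmt.n_bins / n1s
        expected = focal_expected_histogram(sc, fmt, t_needed)
        errs = []
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, 0xDE, int(m * 1000), rep))
            )
            h = CorrelationHistogram(
                counts=rng.poisson(expected), format=fmt, acquisition_time=t_needed
            )
            res = fit_g2(h)
            errs.append(abs(res.g2_zero - m) if res.converged else np.inf)
        medians[m] = float(np.median(errs))
    return {"median_abs_error": medians, "worst_median": max(medians.values())}
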