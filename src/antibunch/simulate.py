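"""Monte-Carlo simulation of confocal HBT scans.

The simulator emulates a scanning confocal microscope with a symmetric
Hanbury-Brown-Twiss detection arm.  At every pixel the detected signal
of each emitter is its focal brightness attenuated by an isotropic 2-D
Gaussian point-spread function evaluated at the pixel centre.  Each
detector receives half the total rate through the 50:50 beam splitter.

In the low-rate regime (rates <= 1e5 counts/s over a 500 ns span, so
pair pile-up is negligible) the expected coincidence count in delay bin
k over acquisition time T factorizes into

    E[counts_k] = r1 * r2 * dtau * T * g2_tot(tau_k)

with r1 = r2 = (sum_i S_i + B) / 2 and g2_tot the multi-emitter mixture
correlation of :func:`antibunch.emitter.multi_emitter_g2` evaluated with
each emitter's three-level curve at the bin-centre delay.  Shot noise is
an independent Poisson draw per bin.  Detector jitter (30 ps), correlator
jitter (4 ps), dead time and afterpulsing are far below the 2.33 ns bin
width and are not modelled.

All randomness flows from a single root seed; each (pixel, slice) child
stream is derived deterministically so partial re-runs reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np

from .emitter import EmitterSpec, g2_three_level, multi_emitter_g2
from .histogram import CorrelationHistogram, HistogramFormat

__all__ = [
    "ScanConfig",
    "ScanDataset",
    "psf_attenuation",
    "pixel_signal_rates",
    "expected_g2_curve",
    "expected_histogram",
    "sample_histogram",
    "simulate_scan",
    "exact_g2_map",
]


@dataclass(frozen=True)
class ScanConfig:
    """Geometry and acquisition parameters of a confocal scan.

    Defaults mirror the standard acquisition: a 775 x 775 nm region split
    into 32 x 32 pixels, 1 s increments, and a PSF sigma of 131.65 nm
    (310 nm FWHM).
    """

    region: tuple[float, float] = (775.0, 775.0)
    grid: tuple[int, int] = (32, 32)
    psf_sigma: float = 131.65
    background_rate: float = 0.0
    increment: float = 1.0
    slices_per_pixel: int = 7
    seed: int = 0
    histogram_format: HistogramFormat = field(default_factory=HistogramFormat)

    def __post_init__(self) -> None:
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.grid}")
        if self.psf_sigma <= 0:
            raise ValueError(f"psf_sigma must be positive, got {self.psf_sigma}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.increment <= 0 or self.slices_per_pixel < 1:
            raise ValueError("need increment > 0 and slices_per_pixel >= 1")

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        """(pitch_y, pitch_x) in nm: region / grid per axis."""
        return (self.region[1] / self.grid[0], self.region[0] / self.grid[1])

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) position of a pixel centre in nm."""
        py, px = self.pixel_pitch
        return ((col + 0.5) * px, (row + 0.5) * py)

    def to_dict(self) -> dict:
        return {
            "region_nm": list(self.region),
            "grid": list(self.grid),
            "psf_sigma_nm": self.psf_sigma,
            "background_rate_cps": self.background_rate,
            "increment_s": self.increment,
            "slices_per_pixel": self.slices_per_pixel,
            "seed": self.seed,
            "histogram": {
                "n_bins": self.histogram_format.n_bins,
                "span_ns": self.histogram_format.span,
                "zero_bin_index": self.histogram_format.zero_bin_index,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        h = d.get("histogram", {})
        return cls(
            region=tuple(d["region_nm"]),
            grid=tuple(d["grid"]),
            psf_sigma=d["psf_sigma_nm"],
            background_rate=d["background_rate_cps"],
            increment=d["increment_s"],
            slices_per_pixel=d["slices_per_pixel"],
            seed=d["seed"],
            histogram_format=HistogramFormat(
                n_bins=h.get("n_bins", 215),
                span=h.get("span_ns", 500.0),
                zero_bin_index=h.get("zero_bin_index", 107),
            ),
        )


@dataclass
class ScanDataset:
    """A simulated scan: photon-count map plus per-pixel increment histograms.

    ``pl_map`` holds detected photon counts per pixel over the full dwell
    (slices_per_pixel x increment).  ``histograms`` has shape
    (rows, cols, slices, n_bins), integer counts.
    """

    config: ScanConfig
    emitters: list[EmitterSpec]
    pl_map: np.ndarray
    histograms: np.ndarray

    def __post_init__(self) -> None:
        rows, cols = self.config.grid
        if self.pl_map.shape != (rows, cols):
            raise ValueError(
                f"pl_map shape {self.pl_map.shape} does not match grid {self.config.grid}"
            )
        expect = (rows, cols, self.config.slices_per_pixel, self.config.histogram_format.n_bins)
        if self.histograms.shape != expect:
            raise ValueError(
                f"histograms shape {self.histograms.shape}, expected {expect}"
            )

    def pixel_histograms(self, row: int, col: int) -> list[CorrelationHistogram]:
        """The increment histograms of one pixel as container objects."""
        return [
            CorrelationHistogram(
                counts=self.histograms[row, col, s],
                format=self.config.histogram_format,
                acquisition_time=self.config.increment,
                pixel=(row, col),
            )
            for s in range(self.config.slices_per_pixel)
        ]


def psf_attenuation(emitter: EmitterSpec, x: float, y: float, sigma: float) -> float:
    """Gaussian PSF factor exp(-d^2 / (2 sigma^2)) at distance d from the emitter."""
    d2 = (emitter.x - x) ** 2 + (emitter.y - y) ** 2
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def pixel_signal_rates(
    emitters: Sequence[EmitterSpec], pixel_center: tuple[float, float], config: ScanConfig
) -> np.ndarray:
    """Detected signal rate of every emitter at one pixel (counts/s)."""
    x, y = pixel_center
    return np.array(
        [e.brightness * psf_attenuation(e, x, y, config.psf_sigma) for e in emitters]
    )


def expected_g2_curve(
    emitters: Sequence[EmitterSpec],
    pixel_center: tuple[float, float],
    config: ScanConfig,
) -> np.ndarray:
    """Mixture g2(tau_k) over the histogram bin centres at one pixel."""
    tau = config.histogram_format.tau
    rates = pixel_signal_rates(emitters, pixel_center, config)
    total = rates.sum() + config.background_rate
    if total == 0:
        raise ValueError("zero total rate: no emitters in range and no background")
    curves = [g2_three_level(e.params, tau) for e in emitters]
    if len(emitters) == 0:
        return np.ones_like(tau)
    return multi_emitter_g2(rates, curves, config.background_rate)


def expected_histogram(
    emitters: Sequence[EmitterSpec],
    pixel_center: tuple[float, float],
    config: ScanConfig,
    acquisition_time: float,
) -> np.ndarray:
    """Expected (real-valued) coincidence counts per bin at one pixel."""
    if acquisition_time <= 0:
        raise ValueError("acquisition_time must be positive")
    rates = pixel_signal_rates(emitters, pixel_center, config)
    total = float(rates.sum()) + config.background_rate
    if total == 0:
        raise ValueError("zero total rate: no emitters in range and no background")
    r = total / 2.0  # per-detector rate behind the 50:50 splitter
    dtau_s = config.histogram_format.bin_width * 1e-9
    if len(emitters) == 0:
        g2_tot = np.ones(config.histogram_format.n_bins)
    else:
        g2_tot = expected_g2_curve(emitters, pixel_center, config)
    return r * r * dtau_s * acquisition_time * g2_tot


def sample_histogram(
    expected: np.ndarray,
    rng_seed: int | np.random.Generator,
    format: Optional[HistogramFormat] = None,
    acquisition_time: float = 1.0,
    pixel: Optional[tuple[int, int]] = None,
) -> CorrelationHistogram:
    """Poisson draw of a histogram from per-bin expectations (seeded)."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fmt = format if format is not None else HistogramFormat(n_bins=len(expected))
    counts = rng.poisson(expected)
    return CorrelationHistogram(
        counts=counts, format=fmt, acquisition_time=acquisition_time, pixel=pixel
    )


def exact_g2_map(config: ScanConfig, emitters: Sequence[EmitterSpec]) -> np.ndarray:
    """Per-pixel mixed g2(0) computed exactly from the simulator's rates.

    This is the ground truth the estimators try to recover: the
    multi-emitter mixture of the emitters' zero-delay values with the
    configured background, evaluated at every pixel centre.
    """
    rows, cols = config.grid
    out = np.ones((rows, cols))
    zeros = [e.params.g2_zero for e in emitters]
    for row in range(rows):
        for col in range(cols):
            rates = pixel_signal_rates(emitters, config.pixel_center(row, col), config)
            total = float(rates.sum()) + config.background_rate
            if total == 0:
                out[row, col] = 1.0
                continue
            out[row, col] = multi_emitter_g2(rates, zeros, config.background_rate)
    return out


def _pixel_rng(seed: int, row: int, col: int, sl: int) -> np.random.Generator:
    """Deterministic child stream for one (pixel, slice)."""
    return np.random.default_rng(np.random.SeedSequence((seed, row, col, sl)))


def simulate_scan(
    config: ScanConfig,
    emitters: Sequence[EmitterSpec],
    noiseless: bool = False,
) -> ScanDataset:
    """Simulate a full confocal scan.

    Every pixel gets ``slices_per_pixel`` independently sampled increment
    histograms and a photoluminescence count drawn with mean
    (sum_i S_i + B) * T_total.  With ``noiseless=True`` the expected
    values are stored instead of Poisson draws (histograms are rounded to
    integers only in the container; the pl_map keeps the exact mean).
    """
    emitters = list(emitters)
    w, h = config.region
    margin = 3.0 * config.psf_sigma
    for e in emitters:
        if not (-margin <= e.x <= w + margin and -margin <= e.y <= h + margin):
            warnings.warn(
                f"emitter at ({e.x:.0f}, {e.y:.0f}) nm lies outside the scan "
                f"region plus a 3-sigma guard margin",
                stacklevel=2,
            )
    rows, cols = config.grid
    n_bins = config.histogram_format.n_bins
    t_total = config.increment * config.slices_per_pixel
    pl = np.zeros((rows, cols))
    hists = np.zeros((rows, cols, config.slices_per_pixel, n_bins), dtype=np.int64)
    for row in range(rows):
        for col in range(cols):
            center = config.pixel_center(row, col)
            rates = pixel_signal_rates(emitters, center, config)
            total_rate = float(rates.sum()) + config.background_rate
            mean_counts = total_rate * t_total
            exp_inc = expected_histogram(emitters, center, config, config.increment)
            if noiseless:
                pl[row, col] = mean_counts
                for s in range(config.slices_per_pixel):
                    hists[row, col, s] = np.round(exp_inc).astype(np.int64)
            else:
                pl_rng = _pixel_rng(config.seed, row, col, config.slices_per_pixel)
                pl[row, col] = pl_rng.poisson(mean_counts)
                for s in range(config.slices_per_pixel):
                    rng = _pixel_rng(config.seed, row, col, s)
                    hists[row, col, s] = rng.poisson(exp_inc)
    return ScanDataset(config=config, emitters=emitters, pl_map=pl, histograms=hists)
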