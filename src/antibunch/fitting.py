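"""Nonlinear least-squares retrieval of g2(0) from coincidence histograms.

This is the conventional baseline: normalize the raw counts to the
long-delay Poissonian level, then fit the three-level curve

    g2(tau) = 1 - a1 exp(-|tau|/t1) + a2 exp(-|tau|/t2)

by bounded nonlinear least squares (Levenberg-Marquardt-style; the
bounded problem is solved with scipy's trust-region-reflective
algorithm, which reduces to L-M away from the bounds).  The zero-delay
bin position is known from the histogram format.  The reported
uncertainty on g2(0) = 1 - a1 + a2 follows from linear error
propagation over the (a1, a2) covariance block.

Sparse histograms (a few seconds of acquisition) do not constrain the
fit; such pixels come back flagged with the dark-pixel convention
g2(0) = 1, which removes them from the reconstructed image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .emitter import ThreeLevelParams
from .histogram import CorrelationHistogram
from .simulate import ScanDataset
from .histogram import augment_sum

__all__ = [
    "FitResult",
    "G2Map",
    "normalize_histogram",
    "fit_g2",
    "fit_scan",
]

#: histograms with fewer events than this cannot be normalized meaningfully
SPARSE_EVENT_FLOOR = 4

#: fraction of bins on each side used for the baseline estimate
BASELINE_FRACTION = 0.2

# fit bounds: amplitudes in [0, 1.5], time constants in [1, 500] ns, plus a
# free normalization scale (the outer-bin baseline is biased when the
# bunching tail has not fully decayed at the span edge)
_LO = np.array([0.0, 0.0, 1.0, 1.0, 0.5])
_HI = np.array([1.5, 1.5, 500.0, 500.0, 2.0])


@dataclass
class FitResult:
    """Outcome of one histogram fit."""

    params: Optional[ThreeLevelParams]
    g2_zero: float
    uncertainty: float
    converged: bool
    residual_norm: float

    @classmethod
    def flagged(cls, g2_zero: float = 1.0) -> "FitResult":
        """Non-converged / degenerate result (dark-pixel convention)."""
        return cls(
            params=None,
            g2_zero=g2_zero,
            uncertainty=np.inf,
            converged=False,
            residual_norm=np.nan,
        )


@dataclass
class G2Map:
    """Per-pixel g2(0) estimates with provenance ``"fit"`` or ``"cnn"``."""

    values: np.ndarray
    uncertainties: Optional[np.ndarray] = None
    provenance: str = "fit"

    def clamped(self, lo: float = 0.0, hi: float = 1.5) -> np.ndarray:
        return np.clip(self.values, lo, hi)


def normalize_histogram(hist: CorrelationHistogram) -> tuple[np.ndarray, float]:
    """Scale counts to the long-delay Poissonian level.

    The baseline is the mean count over the outer 20% of bins on each
    side of the delay axis (largest |tau|).  Returns (counts / baseline,
    baseline).  Raises if the baseline is zero (the caller may fall back
    to an expected-rate normalization when the rates are known).
    """
    n = hist.format.n_bins
    edge = max(1, int(round(BASELINE_FRACTION * n)))
    outer = np.concatenate([hist.counts[:edge], hist.counts[-edge:]])
    baseline = float(outer.mean())
    if baseline <= 0:
        raise ValueError("zero baseline: histogram is not normalizable")
    return hist.counts / baseline, baseline


def _model(tau, a1: float, a2: float, t1: float, t2: float, scale: float = 1.0) -> np.ndarray:
    at = np.abs(tau)
    return scale * (1.0 - a1 * np.exp(-at / t1) + a2 * np.exp(-at / t2))


def fit_g2(
    hist: CorrelationHistogram,
    initial: Optional[ThreeLevelParams] = None,
) -> FitResult:
    """Fit the three-level curve to one normalized histogram.

    Unweighted least squares over (a1, a2, t1, t2) with bounds
    a1, a2 in [0, 1.5] and t1, t2 in [1, 500] ns.  Non-convergence
    triggers one restart from a perturbed initial point; histograms
    below the sparse-event floor come back flagged immediately.
    """
    if hist.n_events < SPARSE_EVENT_FLOOR:
        return FitResult.flagged()
    try:
        y, _ = normalize_histogram(hist)
    except ValueError:
        return FitResult.flagged()
    tau = hist.format.tau

    if initial is not None:
        p0 = np.array([initial.a1, initial.a2, initial.t1, initial.t2, 1.0])
    else:
        a1_0 = float(np.clip(1.0 - y.min(), 0.0, 1.5))
        a2_0 = float(np.clip(y.max() - 1.0, 0.0, 1.5))
        p0 = np.array([a1_0, a2_0, 25.0, 100.0, 1.0])
    p0 = np.clip(p0, _LO + 1e-9, _HI - 1e-9)

    for attempt in range(2):
        try:
            popt, pcov = curve_fit(
                _model, tau, y, p0=p0, bounds=(_LO, _HI), maxfev=20000
            )
        except (RuntimeError, ValueError):
            popt, pcov = None, None
        if popt is not None and np.all(np.isfinite(popt)):
            break
        # single restart with a perturbed initial point
        p0 = np.clip(p0 * [0.8, 1.2, 2.0, 0.5, 1.0] + 0.05, _LO + 1e-9, _HI - 1e-9)
    if popt is None:
        return FitResult.flagged()

    a1, a2, t1, t2, scale = popt
    # clamp to the physical region g2(0) >= 0 (sparse fits can overshoot)
    a1 = min(max(a1, 0.0), 1.0 + a2)
    a2 = max(a2, 0.0)
    params = ThreeLevelParams(a1=a1, a2=a2, t1=t1, t2=t2)
    resid = _model(tau, *popt) - y
    # sigma^2(g2_zero) = var(a1) + var(a2) - 2 cov(a1, a2), with the
    # covariance evaluated at frozen scale: the (scale, a2, t2) direction
    # is near-degenerate when t2 approaches the histogram half-span and
    # would otherwise inflate the propagated error by an order of magnitude
    try:
        _, pcov4 = curve_fit(
            lambda t, b1, b2, u1, u2: _model(t, b1, b2, u1, u2, scale),
            tau, y, p0=popt[:4], bounds=(_LO[:4], _HI[:4]), maxfev=4000,
        )
    except (RuntimeError, ValueError):
        pcov4 = pcov[:4, :4] if pcov is not None else None
    if pcov4 is not None and np.all(np.isfinite(pcov4)):
        var = pcov4[0, 0] + pcov4[1, 1] - 2.0 * pcov4[0, 1]
        unc = float(np.sqrt(var)) if var > 0 else 0.0
    else:
        unc = np.inf
    return FitResult(
        params=params,
        g2_zero=float(1.0 - a1 + a2),
        uncertainty=unc,
        converged=True,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
    )


def fit_scan(scan: ScanDataset, total_time: float) -> tuple[G2Map, list[list[FitResult]]]:
    """Fit every pixel of a scan using composites of the requested length.

    ``total_time`` must be a multiple of the increment and not exceed
    the acquired dwell; the first k increments of each pixel are summed.
    Pixels that fail normalization carry g2(0) = 1, flagged.
    """
    cfg = scan.config
    k = int(round(total_time / cfg.increment))
    if not np.isclose(k * cfg.increment, total_time):
        raise ValueError(
            f"total_time {total_time} is not a multiple of the {cfg.increment} s increment"
        )
    if k < 1 or k > cfg.slices_per_pixel:
        raise ValueError(
            f"requested {total_time} s but only {cfg.slices_per_pixel} x "
            f"{cfg.increment} s increments are available"
        )
    rows, cols = cfg.grid
    values = np.ones((rows, cols))
    uncs = np.full((rows, cols), np.inf)
    results: list[list[FitResult]] = []
    for row in range(rows):
        row_results = []
        for col in range(cols):
            composite = augment_sum(scan.pixel_histograms(row, col)[:k])
            res = fit_g2(composite)
            values[row, col] = res.g2_zero
            uncs[row, col] = res.uncertainty
            row_results.append(res)
        results.append(row_results)
    return G2Map(values=values, uncertainties=uncs, provenance="fit"), results
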