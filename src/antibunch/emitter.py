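"""Photon statistics of single and multiple quantum emitters.

A room-temperature single-photon emitter (e.g. an NV centre in a
nanodiamond) pumped off-resonantly behaves as an effective three-level
system.  Its normalized second-order intensity autocorrelation is

    g2(tau) = 1 - a1 * exp(-|tau| / t1) + a2 * exp(-|tau| / t2)

where ``a1`` is the antibunching amplitude (a1 = 1 for an ideal single
emitter without background), ``a2`` the bunching amplitude produced by
shelving into a metastable state, and ``t1``/``t2`` the corresponding
time constants in nanoseconds.  The zero-delay value g2(0) = 1 - a1 + a2
quantifies the residual multi-photon emission probability.

Real measurements mix the emitter signal with Poissonian background
(fluorescence of the substrate, detector dark counts).  With signal rate
``S`` and background rate ``B`` the measured correlation is diluted by
the squared signal fraction rho = S / (S + B):

    g2_meas(tau) = 1 + rho**2 * (g2_emitter(tau) - 1)

so that background-dominated pixels read g2 = 1.  Several independent
emitters inside the collection volume combine the same way through the
pair-rate algebra implemented in :func:`multi_emitter_g2`; n identical
ideal emitters give the textbook g2(0) = 1 - 1/n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThreeLevelParams",
    "EmitterSpec",
    "g2_three_level",
    "g2_zero",
    "mixed_g2",
    "multi_emitter_g2",
]


@dataclass(frozen=True)
class ThreeLevelParams:
    """Parameters of the three-level autocorrelation curve.

    Attributes
    ----------
    a1 : float
        Antibunching amplitude (dimensionless, >= 0).
    a2 : float
        Bunching amplitude (dimensionless, >= 0).
    t1 : float
        Antibunching time constant in ns (> 0).
    t2 : float
        Bunching time constant in ns (> 0).
    """

    a1: float
    a2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(
                f"time constants must be positive, got t1={self.t1}, t2={self.t2}"
            )
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError(
                f"amplitudes must be non-negative, got a1={self.a1}, a2={self.a2}"
            )
        if 1.0 - self.a1 + self.a2 < -1e-12:
            raise ValueError(
                f"g2(0) = 1 - a1 + a2 = {1.0 - self.a1 + self.a2:.4f} is negative"
            )

    @property
    def g2_zero(self) -> float:
        """Zero-delay correlation value 1 - a1 + a2."""
        return 1.0 - self.a1 + self.a2

    def to_dict(self) -> dict:
        return {"a1": self.a1, "a2": self.a2, "t1_ns": self.t1, "t2_ns": self.t2}

    @classmethod
    def from_dict(cls, d: dict) -> "ThreeLevelParams":
        return cls(a1=d["a1"], a2=d["a2"], t1=d["t1_ns"], t2=d["t2_ns"])


@dataclass(frozen=True)
class EmitterSpec:
    """A point emitter placed in the scan plane.

    ``brightness`` is the detected signal count rate at focus summed over
    both detectors of the HBT interferometer (counts/s); each detector
    receives half of it through the 50:50 beam splitter.
    """

    x: float
    y: float
    brightness: float
    params: ThreeLevelParams = field(
        default_factory=lambda: ThreeLevelParams(a1=1.0, a2=0.0, t1=25.0, t2=100.0)
    )

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError(f"brightness must be positive, got {self.brightness}")

    def to_dict(self) -> dict:
        d = {"x_nm": self.x, "y_nm": self.y, "brightness_cps": self.brightness}
        d.update(self.params.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmitterSpec":
        return cls(
            x=d["x_nm"],
            y=d["y_nm"],
            brightness=d["brightness_cps"],
            params=ThreeLevelParams.from_dict(d),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EmitterSpec":
        return cls.from_dict(json.loads(s))


def g2_three_level(params: ThreeLevelParams, tau) -> np.ndarray | float:
    """Evaluate the three-level correlation curve at delay ``tau`` (ns).

    The curve is symmetric: it is evaluated at |tau|.  Returns
    ``1 - a1*exp(-|tau|/t1) + a2*exp(-|tau|/t2)``, which tends to
    ``1 - a1 + a2`` at tau = 0 and to 1 as |tau| -> inf.
    """
    at = np.abs(np.asarray(tau, dtype=float))
    out = 1.0 - params.a1 * np.exp(-at / params.t1) + params.a2 * np.exp(-at / params.t2)
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(out)
    return out


def g2_zero(params: ThreeLevelParams) -> float:
    """Zero-delay correlation 1 - a1 + a2."""
    return params.g2_zero


def mixed_g2(signal_rate: float, background_rate: float, g2_emitter) -> float | np.ndarray:
    """Dilute an emitter correlation with Poissonian background.

    With rho = S / (S + B), the measured value is
    ``1 + rho**2 * (g2_emitter - 1)``: the identity at B = 0 and exactly 1
    for a pure-background pixel.  ``g2_emitter`` may be scalar (zero-delay
    value) or an array (a full curve).
    """
    if signal_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    total = signal_rate + background_rate
    if total == 0:
        raise ValueError("undefined mixture: signal and background rates are both zero")
    rho = signal_rate / total
    g2 = np.asarray(g2_emitter, dtype=float)
    out = 1.0 + rho * rho * (g2 - 1.0)
    if np.ndim(g2_emitter) == 0:
        return float(out)
    return out


def multi_emitter_g2(
    emitter_rates: Sequence[float],
    emitter_g2_values,
    background_rate: float = 0.0,
):
    """Combine independent emitters plus background into one g2 value.

    For independent sources with detected rates S_i and correlations
    g2_i, plus Poissonian background B, the pair rate divided by the
    squared singles rate gives

        g2 = [sum_i S_i^2 g2_i + sum_{i != j} S_i S_j
              + 2 B sum_i S_i + B^2] / (sum_i S_i + B)^2

    All cross terms are uncorrelated (flat, = 1); only the self terms
    carry the emitter correlations.  ``emitter_g2_values`` entries may be
    scalars or arrays of a common shape (full curves); the result then
    has that shape.  Reduces to :func:`mixed_g2` for a single emitter.
    """
    rates = np.asarray(emitter_rates, dtype=float)
    g2s = [np.asarray(g, dtype=float) for g in emitter_g2_values]
    if len(rates) != len(g2s):
        raise ValueError(
            f"got {len(rates)} rates but {len(g2s)} g2 values; lengths must match"
        )
    if np.any(rates < 0) or background_rate < 0:
        raise ValueError("rates must be non-negative")
    s_tot = float(rates.sum())
    total = s_tot + background_rate
    if total == 0:
        raise ValueError("all rates are zero")
    num = 0.0
    for s, g in zip(rates, g2s):
        num = num + s * s * g
    # off-diagonal emitter pairs and emitter-background / background-background
    # cross terms are all Poissonian (flat = 1)
    cross = s_tot * s_tot - float((rates * rates).sum())
    num = num + cross + 2.0 * background_rate * s_tot + background_rate * background_rate
    out = num / (total * total)
    if np.ndim(out) == 0:
        return float(out)
    return out
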