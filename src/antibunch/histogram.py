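"""Coincidence-histogram containers and augmentation.

A start-stop correlator records the delay between a click on detector 1
and a click on detector 2 and accumulates the delays into a fixed grid
of time bins.  The default format matches the acquisition used
throughout this package: 215 bins spanning 500 ns of two-sided delay,
so the bin width is 500/215 ~ 2.33 ns and the tau = 0 bin sits at index
107 (0-based centre).

Histograms acquired in 1 s increments are additive: summing them bin by
bin emulates a longer acquisition (emission has no memory beyond the
increment length).  :func:`build_composites` turns a pool of increments
into k-second composites, the data-augmentation step used to build the
CNN training corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HistogramFormat",
    "CorrelationHistogram",
    "augment_sum",
    "build_composites",
]


@dataclass(frozen=True)
class HistogramFormat:
    """Bin layout of a coincidence histogram.

    ``span`` is the total two-sided delay range in ns; delays run over
    ``[-span/2, span/2)`` with the tau = 0 bin at ``zero_bin_index``.
    """

    n_bins: int = 215
    span: float = 500.0
    zero_bin_index: int = 107

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError(f"n_bins must be >= 3, got {self.n_bins}")
        if self.span <= 0:
            raise ValueError(f"span must be positive, got {self.span}")
        if not (0 <= self.zero_bin_index < self.n_bins):
            raise ValueError(
                f"zero_bin_index {self.zero_bin_index} outside [0, {self.n_bins})"
            )

    @property
    def bin_width(self) -> float:
        """Bin width in ns (span / n_bins)."""
        return self.span / self.n_bins

    @property
    def tau(self) -> np.ndarray:
        """Bin-centre delays in ns, zero at ``zero_bin_index``."""
        return (np.arange(self.n_bins) - self.zero_bin_index) * self.bin_width


@dataclass
class CorrelationHistogram:
    """Integer coincidence counts over a delay grid.

    ``n_events`` is always recomputed from the counts; a value stored in
    a file is never trusted.
    """

    counts: np.ndarray
    format: HistogramFormat = field(default_factory=HistogramFormat)
    acquisition_time: float = 1.0
    pixel: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.shape[0] != self.format.n_bins:
            raise ValueError(
                f"counts must be 1-D with {self.format.n_bins} bins, got shape {c.shape}"
            )
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        self.counts = c.astype(np.int64, copy=False)
        if self.acquisition_time <= 0:
            raise ValueError(
                f"acquisition_time must be positive, got {self.acquisition_time}"
            )

    @property
    def n_events(self) -> int:
        """Total number of co-detection events (sum of counts)."""
        return int(self.counts.sum())


def augment_sum(histograms: Sequence[CorrelationHistogram]) -> CorrelationHistogram:
    """Bin-wise sum of histograms sharing one format.

    The acquisition times add; the identity holds for a single input.
    """
    if len(histograms) == 0:
        raise ValueError("need at least one histogram")
    fmt = histograms[0].format
    for h in histograms[1:]:
        if h.format != fmt:
            raise ValueError(f"format mismatch: {h.format} != {fmt}")
    counts = np.sum([h.counts for h in histograms], axis=0)
    time = float(sum(h.acquisition_time for h in histograms))
    return CorrelationHistogram(
        counts=counts,
        format=fmt,
        acquisition_time=time,
        pixel=histograms[0].pixel,
    )


def build_composites(
    increments: Sequence[CorrelationHistogram],
    min_k: int = 1,
    max_k: int = 10,
    max_per_k: Optional[int] = None,
    rng_seed: int | np.random.Generator = 0,
) -> list[CorrelationHistogram]:
    """Form k-increment composites for every k in [min_k, max_k].

    When the number of k-subsets of the pool exceeds ``max_per_k``,
    ``max_per_k`` distinct subsets are drawn at random (seeded);
    otherwise all subsets are enumerated.  Each composite carries
    an acquisition time of k increments.
    """
    n = len(increments)
    if not (1 <= min_k <= max_k):
        raise ValueError(f"need 1 <= min_k <= max_k, got [{min_k}, {max_k}]")
    if max_k > n:
        raise ValueError(f"max_k={max_k} exceeds the {n} available increments")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out: list[CorrelationHistogram] = []
    for k in range(min_k, max_k + 1):
        total = comb(n, k)
        if max_per_k is None or total <= max_per_k:
            subsets = list(combinations(range(n), k))
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < max_per_k:
                idx = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
                chosen.add(idx)
            subsets = sorted(chosen)
        for idx in subsets:
            out.append(augment_sum([increments[i] for i in idx]))
    return out
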