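"""Independent brute-force oracles used by the tests.

These simulate discretized photon streams click by click and count
detector-pair delays directly, with no reference to the package's
factorized coincidence model, so they can serve as an independent check
of the analytic photon-statistics formulas.
"""

from __future__ import annotations

import numpy as np


def stream_pair_counts(
    emit_probs: list[float],
    n_steps: int,
    max_delay: int,
    rng: np.random.Generator,
    background_prob: float = 0.0,
) -> np.ndarray:
    """Count detector-1/detector-2 pairs per delay on a Bernoulli stream.

    Each emitter emits at most one photon per time step (probability
    ``emit_probs[i]``); every photon is routed to detector 1 or 2 with
    probability 1/2.  Background adds independent Poissonian photons.
    Returns counts of (t2 - t1) delays for t1 clicks on D1 and t2 on D2,
    for delays in [-max_delay, +max_delay] (length 2*max_delay + 1).
    """
    d1 = np.zeros(n_steps, dtype=np.int64)
    d2 = np.zeros(n_steps, dtype=np.int64)
    for p in emit_probs:
        photons = rng.random(n_steps) < p
        route = rng.random(n_steps) < 0.5
        d1 += photons & route
        d2 += photons & ~route
    if background_prob > 0:
        for det in (d1, d2):
            photons = rng.random(n_steps) < background_prob
            det += photons
    counts = np.zeros(2 * max_delay + 1, dtype=np.int64)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            counts[d + max_delay] = int(np.sum(d1[: n_steps - d] * d2[d:]))
        else:
            counts[d + max_delay] = int(np.sum(d1[-d:] * d2[: n_steps + d]))
    return counts


def stream_g2_zero(
    emit_probs: list[float],
    n_steps: int,
    rng: np.random.Generator,
) -> float:
    """Zero-delay g2 estimate from direct pair counting.

    Ratio of zero-delay coincidences to the long-delay (uncorrelated)
    pair rate, the observable a start-stop correlator measures.
    """
    counts = stream_pair_counts(emit_probs, n_steps, max_delay=5, rng=rng)
    zero = counts[5]
    baseline = (counts[0] + counts[1] + counts[9] + counts[10]) / 4.0
    return float(zero / baseline)
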