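"""Retrieve g2(0) by curve fitting: dense histograms work, sparse fail.

The three-level curve is fitted by bounded nonlinear least squares after
normalizing to the long-delay baseline.  With ~300 events per bin the
estimate lands within the +-0.01..0.05 uncertainty envelope; with a few
seconds of data the fit is unusable — which is what motivates the
regression network.

Run:  python examples/03_fit_histogram.py
"""

import numpy as np

from antibunch import CorrelationHistogram, HistogramFormat, ThreeLevelParams, fit_g2
from antibunch.emitter import g2_three_level, mixed_g2

fmt = HistogramFormat()
truth = ThreeLevelParams(a1=1.0, a2=0.1, t1=30.0, t2=150.0)
s, b = 18_000.0, 1_500.0
true_g2 = mixed_g2(s, b, truth.g2_zero)
curve = mixed_g2(s, b, g2_three_level(truth, fmt.tau))
rate = ((s + b) / 2) ** 2 * fmt.bin_width * 1e-9  # expected counts/bin/s

rng = np.random.default_rng(3)
print(f"true measured g2(0) = {true_g2:.3f}  (emitter {truth.g2_zero:.2f} "
      f"diluted by {b:.0f} cps background)\n")
for t_acq, label in ((3600.0, "dense, 1 h"), (7.0, "sparse, 7 s")):
    counts = rng.poisson(rate * t_acq * curve)
    hist = CorrelationHistogram(counts=counts, format=fmt, acquisition_time=t_acq)
    res = fit_g2(hist)
    status = "converged" if res.converged else "FLAGGED (too sparse)"
    print(f"{label:12s}  ~{counts.mean():6.1f} events/bin   "
          f"g2(0) = {res.g2_zero:.3f} +- {res.uncertainty:.3f}   [{status}]")
print("\nthe dense fit recovers the truth; the sparse fit does not "
      "constrain the dip at all")
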