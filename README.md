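# antibunch

Antibunching super-resolution microscopy in simulation: per-pixel
Hanbury-Brown–Twiss (HBT) coincidence histograms of single quantum
emitters, g²(0) estimation by three-level curve fitting and by a 1-D
convolutional regression network, and reconstruction of the
super-resolved image that narrows the point-spread function by √2.

## Who this is for

Quantum-optics and bio-imaging groups running confocal scans of
single-photon emitters (NV centres, quantum dots, molecular markers)
who want to prototype antibunching-based super-resolution — in
particular the machine-learning shortcut that replaces minutes-long
per-pixel autocorrelation fitting with millisecond inference on sparse
(seconds-long) histograms — without hardware in the loop.

## The method

A single emitter cannot emit two photons at once: its second-order
autocorrelation

g²(τ) = 1 − a₁·e^(−|τ|/t₁) + a₂·e^(−|τ|/t₂),  g²(0) = 1 − a₁ + a₂ < 1,

is measured per scan pixel with an HBT interferometer (50:50 splitter,
two detectors, start-stop correlator, 215 bins over 500 ns).  The
super-resolved image is assembled pixel-wise as

G²(x, y) ∝ ⟨Ñ(x, y)⟩² · (1 − g²(x, y, 0)),

which squares the Gaussian spot (σ → σ/√2) and deletes Poissonian
background (g² = 1).  The bottleneck is estimating g²(0): least-squares
fitting needs ~300 events per bin (minutes per pixel), while the
regression network — three convolutional layers of 260 kernel-4
filters, max-pooling, dropout, three dense layers, with the histogram's
total event count N_events concatenated after feature learning — reads
it off 5–7 s histograms.  The network is trained with Adamax on a mean
absolute-percentage-error loss for 100 epochs on simulated composites
(bin-wise sums of 1 s acquisitions, items under 4 events labelled
g² = 1), split by emitter so no source leaks between training and
evaluation.

## Worked example

`python examples/05_super_resolution.py` simulates a noiseless 32×32
scan (775×775 nm²) of one emitter under a 310 nm FWHM PSF and
reconstructs it with exact per-pixel g² values:

```
diffraction-limited PL spot:   FWHM =  310.0 nm
reconstructed G2 image:        FWHM =  219.2 nm
resolution gain: 1.4142  (sqrt(2) = 1.4142)
clamped pixels (g2 > 1): 0
```

310.0 nm is the fitted width of the confocal spot; squaring the
Gaussian in the reconstruction divides σ by √2, giving 219.2 nm; the
gain matches √2 to four decimals because the scan is noiseless and the
g² map exact.  The other examples walk the remaining capabilities:
photon-statistics building blocks (`01`), scan simulation and the
dark-pixel regime (`02`), dense-versus-sparse curve fitting (`03`), and
training the regression network on a reduced corpus (`04`).

A thin CLI covers the same pipeline from the shell:

```
antibunch simulate --config scenario.json --out scan/ --seed 1
antibunch fit      --scan scan/ --time 7 --out g2map.csv
antibunch reconstruct --scan scan/ --g2map g2map.csv --out sr.csv
antibunch analyze  --image sr.csv --peaks 1 --out fits.json
```

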