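# nanopulse

Feature extraction for nanopore resistive-pulse current traces, built around
three pillars:

1. **Physics-based trace simulator** — open-pore current from a cylindrical
   pore + access-resistance model, steric-blockade pulse amplitudes,
   asymmetric-triangle pulse waveforms, colored Gaussian background noise
   synthesized from a four-component power spectral density (flicker,
   electrode, white, dielectric), and baseline perturbations (sudden jumps
   plus an eight-term sinusoidal drift). Every trace carries its exact event
   table (start, end, duration, amplitude), and noise power is calibrated per
   condition so that amplitude / (6 x noise RMS) hits a target SNR.
2. **Traditional threshold detector** — prominence-based peak calling on the
   inverted, median-detrended trace with the threshold expressed as n x noise
   RMS (n swept 4–25), amplitude/duration/frequency extraction, and tidy
   sweep tables.
3. **Bi-path residual network** — two independent 18-weighted-layer 1D
   residual regressors (numpy backend with manual backprop; group
   normalization, two-layer perceptron heads). Path 1 predicts the pulse
   count of a 0.5 s window; path 2 predicts mean amplitude and duration with
   the count injected into its head (ground truth while training, path 1's
   output at inference). Training uses smooth-L1 loss, SGD with step-decayed
   learning rates, per-epoch validation model selection, and the gating rule:
   a rounded path-1 count of zero short-circuits the prediction to (0, 0, 0).

Evaluation implements the relative-error and relative-percent-difference
metrics, the zero-count-window rules (correct empty window = 0% error, false
positive window = 100% error on all features), and the three-stage
aggregation: per (concentration, diameter, duration) cell, per duration,
then total.

## CLI

```bash
nanopulse simulate --c-values 0.05,0.2,1.0 --d-values 9,13 --durations 1,3 \
    --snr 4 --train 64 --val 32 --test 32 --seed 1 --out data/
nanopulse detect data/test_0000.h5 --n-values 4,8,15,25
nanopulse train --data data/ --snr 4 --epochs 15 --width 16 --out ckpts/
nanopulse evaluate --data data/ --ckpt1 ckpts/path1.npz --ckpt2 ckpts/path2.npz
nanopulse fixture --seed 0 --out fixture/
```

Trace bundles are HDF5 files (noisy + clean arrays, sampling rate, condition
metadata, seed) with a sibling tab-delimited ground-truth event table.

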