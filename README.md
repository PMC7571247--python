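# wavemap

Recommendation maps for wavelet-denoising settings on biomedical signals and
images.

Wavelet shrinkage is a standard first step when cleaning CT/MR images or EMG
recordings, but its result depends heavily on four choices: the mother-wavelet
family (Daubechies, Symlet, Coiflet), its order *n*, the decomposition level
*k*, and how much noise the data actually carries. `wavemap` answers "which
settings should I use?" empirically: it sweeps the full grid
family × order (1–5) × level (1–5) × noise intensity η over a bank of
gold-standard records, scores every setting against the clean reference, and
assembles the scores into response maps from which the best settings are read
off.

**Who it is for.** Engineers and researchers preparing denoising pipelines
for biomedical data who want a data-driven recommendation instead of folklore
defaults, plus a statistical statement of how robust each wavelet family is
across datasets.

## Method

Each record is degraded by a composite noise model at intensity η:

- 1D signals — additive white Gaussian noise at SNR = η dB (noise power
  measured against the signal's mean square) plus symmetric impulse noise of
  variance 1/η; η sweeps 0.05 … 10 in steps of 0.05.
- 2D images — additive Gaussian noise (swept parameter = mean, variance
  0.01), multiplicative speckle `J = I + n·I` with `n` uniform, zero-mean,
  variance 0.05 (held constant), and salt-and-pepper noise of density η;
  η sweeps 0, 0.1, …, 1.0.

Each degraded record is denoised at every grid point with the classical
global-threshold recipe: DWT to level *k*, noise scale
σ̂ = median(|finest details|)/0.6745, universal threshold
T = σ̂·√(2 ln N), soft shrinkage of all detail bands, inverse DWT. The
restored record is compared against the gold standard with four metrics:

- MSE — mean squared error,
- Corr — Pearson correlation over all elements,
- ED — Euclidean distance (ED² = m·n·MSE),
- PSNR = 10·log₁₀(peak²/MSE), peak = 1 for normalized images.

A *spatial response map* WAV<sub>k,n</sub> is the 5×5 matrix of one metric
over (level, order) for one degraded record; stacking maps over η and input
items gives the 4D *volumetric response* per family and metric. From these the
package extracts per-η best settings, max-achievable curves, per-family
summaries, and Mann–Whitney comparisons of family robustness between two
datasets (with chi-squared normality screening first).

Because clinical data cannot be redistributed, a synthetic module generates
structurally analogous gold standards: piecewise-constant high-contrast
phantoms (CT-like), smooth textured phantoms (MR-like), and burst-modulated
broadband signals (EMG-like).

## Worked example

```python
import wavemap as wm

bank = [wm.make_phantom_image(64, "piecewise", seed=100)]
schedule = wm.default_schedule("schedule_2d")           # eta = 0, 0.1, ..., 1.0
vr = wm.volumetric_response(bank, "daubechies", schedule, "corr", master_seed=0)

print(wm.best_settings(vr).table[["eta", "level", "order", "best_value"]].head(4))
print("max-achievable corr:", wm.max_achievable_curve(vr)[:4].round(3))
```

prints

```
   eta  level  order  best_value
0  0.0      1      5    0.964254
1  0.1      2      5    0.936770
2  0.2      2      5    0.913001
3  0.3      3      4    0.893156
```

and

```
max-achievable corr: [0.964 0.937 0.913 0.893]
```

Reading: with no swept noise (η = 0, only the constant speckle and the
variance-0.01 Gaussian floor) a level-1 order-5 Daubechies transform already restores the
phantom to correlation 0.964 with the clean image; as η grows the best
achievable correlation falls and the winning decomposition level climbs —
heavier noise rewards deeper decompositions.

The same sweep from the shell:

```sh
wavemap simulate --n-images 2 --out fixtures
wavemap sweep --config demo.json --out run
wavemap recommend run/response_daubechies_corr.h5
wavemap compare --dir-a runA --dir-b runB      # Mann-Whitney family table
wavemap plot run/response_daubechies_corr.h5 --out map.png
```

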