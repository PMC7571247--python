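# Methods

## The procedure

`wavemap` treats wavelet-denoising configuration as an empirical response-
surface problem. For a bank of gold-standard records it executes a nested
sweep

```
for family in {daubechies, symlet, coiflet}:
  for η in noise schedule:            # degrade
    for level k in 1..5:
      for order n in 1..5:            # denoise + score
        cell(k, n) = metric(denoise(degraded; family, n, k), clean)
```

and stacks the resulting 5×5 spatial maps into a 4D volumetric response
`tensor[k, n, η-index, item]` per (family, metric). Recommendations are the
per-η extrema of that tensor (max for Corr/PSNR, min for MSE/ED), family
robustness summaries are means over the per-η-per-item best values, and the
statistical layer compares those best-value populations between two datasets.

## Noise model

**1D.** AWGN specified as an SNR in dB against the *measured* mean square of
the input: noise variance = P_signal / 10^(snr/10). Impulse noise adds ±A
spikes at i.i.d. Bernoulli(p) positions; the only quantity the protocol pins
down is the impulse variance v (coupled to the sweep as v = 1/η), so the
(p, A) split is a design choice: p = 0.05 fixed and A = √(v/p), which meets
the variance contract exactly with a single exposed parameter. η ranges over
0.05…10 dB in 200 steps; small η therefore means *heavy* noise (low SNR and
large impulse variance) and the response tensors are read accordingly.

**2D.** Three components applied in the order Gaussian → speckle →
salt-and-pepper, so the extreme salt/pepper pixels reach the denoiser
unmodified. The swept Gaussian parameter is the noise *mean* with variance
fixed at 0.01 — the behaviour of the classical one-argument image-noise
routine this sweep mirrors; a `variance` interpretation (mean 0, variance =
η) is exposed as a config switch because the protocol wording supports both
readings. Note a consequence of the default reading: at η = 0 the Gaussian
term still contributes its variance-0.01 floor; only the salt-and-pepper
term vanishes. Speckle is multiplicative, `J = I + n·I`, with `n` i.i.d.
uniform on [−√(3v), +√(3v)] (mean 0, variance v = 0.05 by default, constant
along the schedule); the uniform support is derived from the variance since
only mean and variance are prescribed. Every 2D degradation is clipped to
[0, 1], the intensity convention of all image I/O in the package.

## Denoising

Orthogonal families only, orders 1–5 (the grid is capped at 5 because the
Coiflet family tops out at order 5, keeping the sweep square), levels 1–5.
Symlet order 1 is the Haar wavelet and maps to db1. The shrinkage recipe is
the classical global universal threshold:

- σ̂ = median(|finest detail band|)/0.6745 (MAD estimator; for images the
  finest *diagonal* subband is used, the standard choice because it carries
  the least structure),
- T = σ̂·√(2 ln N) with N the record's total element count — one global T
  for all detail levels,
- soft shrinkage c → sign(c)·max(|c|−T, 0) by default; hard
  (c → c·1[|c|>T], strict inequality) available per config.

Boundary handling is symmetric (half-sample) extension for denoising —
standard for images; a periodization mode is available, under which the
transform is exactly orthonormal (energy-conservation is tested there). A
(level, filter-length) combination a record cannot support (level >
⌊log₂(size/(filter_len−1))⌋) is *skipped*, surfacing as a NaN cell: the
sweep grid stays rectangular and infeasibility is never conflated with poor
performance.

The optional post-denoise intensity adjustment linearly maps [low_in, 1]
onto [0, 1] with clipping (defaults: 0.45 for CT-like, 0.40 for MR-like,
0.50 otherwise). It exists to restore contrast on dark clinical images after
additive-noise brightening. It is applied in the 2D sweep pipeline when
enabled in the run config, but the package's own efficacy checks score
correlation on unadjusted output: Pearson correlation is invariant to the
affine part of the map, so on full-range synthetic phantoms the only effect
of the adjustment is the information lost to clipping.

## Metrics and aggregation

MSE, Pearson correlation over all elements, Euclidean distance and PSNR
(peak 1.0 for normalized data). Correlation of a constant array is
mathematically undefined and is recorded as NaN — never as 0 — and excluded
from extrema and means downstream. "Max-achievable" curves take the per-item
optimum over the (level, order) grid first, then average items
(arithmetic mean; median exposed); family summaries report each family's
mean best value and its difference from the best family's mean, so the
winner scores 0.

Ties at an extremum are broken toward the lowest decomposition level, then
the lowest order (cheapest equivalent setting), then family enumeration
order.

## Statistical layer

Chi-squared normality screening: equal-probability bins under N(μ̂, σ̂²),
k = ⌈1 + 3.322·log₁₀ n⌉ (Sturges) bins, statistic Σ(O−E)²/E referred to χ²
with k−3 degrees of freedom (two estimated parameters); n ≥ 20 required. The
dof convention is the textbook grouped-data default; it is approximate for
parameters estimated from ungrouped data, and the suite verifies its type-I
error empirically (it lands within the binomial 95% band of α = 0.05 at the
sample sizes used).

Mann–Whitney U from rank sums with midranks for ties; p-values are exact by
full enumeration when both samples have ≤ 8 observations and no ties, else
the normal approximation with tie and continuity corrections. Dataset
comparisons pool, per family and metric, the per-η-per-item best values of
each dataset — the population a practitioner cares about (the best each
setting family could do at each noise level), with the all-cells alternative
accessible through the tensor API. No multiple-testing correction is applied;
the table is descriptive.

## Synthetic gold standards

The generators emulate the *structure* wavelet denoising responds to, not
imaging physics:

- `piecewise` phantoms: dark background plus 3–8 constant-intensity
  ellipses, every plateau ≥ 0.2 above background — the high-contrast,
  sharp-edge regime of CT;
- `smooth_textured` phantoms: an oriented low-frequency cosine ramp plus
  heavily low-passed noise texture of amplitude ≤ 0.15 — the smooth-gradient
  regime of MR soft tissue;
- EMG-like signals: white-ish broadband carrier × envelope with a 0.02
  baseline and raised-cosine (Hann) burst windows — interference-pattern
  activity between quiet intervals. Hann was chosen for the envelope because
  it is smooth, band-limited and parameter-free.

Per-record seeds are hashed from (bank seed, record index), so banks are
reproducible and collision-free. What passing tests on these phantoms shows:
the pipeline ranks settings correctly when the structural assumptions
(edges/smoothness/bursts, stationary synthetic noise) hold. What it does not
show: performance on Rician MR noise, correlated CT reconstruction noise,
physiological EMG statistics, or any claim about a specific clinical dataset.

## Numerical choices and problem sizes

- All sweeps are single-process and deterministic; per-(η, item) noise
  generators are spawned from `SeedSequence([master_seed, η_index, item])`,
  making tensors independent of loop order and byte-reproducible.
- Summary CSVs are written with a fixed `%.12g` float format so reruns are
  byte-identical.
- Perfect reconstruction and shrinkage identities are asserted at 1e-10;
  "zero detail on constant input" is asserted at 1e-9, the float64 error
  floor of the published filter coefficients.
- The test and demo problem sizes — 64–128 px phantoms, 1024–4096-sample
  signals, 11-level 2D schedules, 20–50 seed replicates — were chosen as the
  smallest sizes at which the checked effects (reconstruction error floors,
  monotone degradation trends, Monte-Carlo moment bounds) are stable.

## Known limitations

- The impulse-noise (p, A) split and the Gaussian mean-vs-variance reading
  are interpretations of an underspecified protocol; both are exposed in
  config rather than hidden.
- The universal threshold with a record-level N over-smooths at deep levels
  on small records; level-dependent or SURE thresholds are out of scope.
- Family robustness conclusions transfer to real data only to the extent the
  phantom structure matches it; the package ships no clinical data.
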