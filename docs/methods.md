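# Methods

## The quantity being estimated

The *noise color* of a stochastic series is the exponent `a` of a power-law
fit to its power spectral density, `P(f) ∝ f^(−a)`. It summarizes the
temporal autocorrelation structure of the stochastic component of flow:
`a ≈ 0` is white (uncorrelated) variation, `a ≈ 1` pink, `a ≈ 2` red
(strongly persistent), `a > 2.5` black, and `a < −0.5` blue
(anti-persistent, variance concentrated at high frequencies).

Given a detrended series `f_t` of length `T`, the estimator is

    F_k = T^(−1/2) Σ_{t=0}^{T−1} f_t e^(i 2π t k / T)
    P_k = |F_k|²                        k = 1 .. ⌊T/2⌋
    log10 P_k = −a · log10(k/T) + b     (ordinary least squares)

The periodogram is raw: no taper, no Welch averaging, no log-binning. The
DC bin is excluded (residuals are mean-zero; log of zero frequency is
undefined). Under this normalization the two-sided periodogram sums to
`Σ f_t²` (Parseval), which the tests verify to 1e-8 relative. Log base 10
is used throughout; the slope is base-invariant. Zero-power bins cannot
enter the log fit; they are dropped and flagged (they occur only for
degenerate inputs). Fits need at least 3 positive-power bins; fewer yields
a flagged NaN estimate rather than an error.

Classification follows the conventional five-category scheme:
white `[−0.5, 0.5]`, blue `[−1.5, −0.5)`, pink `(0.5, 1.5]`,
red `(1.5, 2.5]`, black `(2.5, ∞)`. The two boundary values ±0.5 are
assigned to white (the white interval is the one conventionally printed
closed on both ends); values below −1.5 are labelled blue with an
out-of-range flag rather than given a sixth category.

## Frequency bands

The *global* daily color is fitted over periods from 2 days (Nyquist) to
the record length. *Local* slopes are fitted on restricted bands:
sub-monthly (7–30 d), seasonal (30–180 d), intra-annual (7–365 d) and
supra-annual (> 365 d). A band maps period range `[p_min, p_max]` to
frequencies `1/p_max ≤ k/T ≤ 1/p_min`, boundaries inclusive. For annual
series the same machinery applies with years as the sample unit.

Whether one log-log line is adequate over a band is judged by augmenting
the regression with a quadratic term in `log10 f`: the band is declared
nonlinear when the quadratic coefficient is significant at α = 0.01 *and*
the implied change of local slope across the band exceeds 0.5 units. The
guard matters: on long series, significance alone flags curvature far too
small to affect any conclusion.

## Record selection, gap filling, aggregation

A gage qualifies when some span of at least 15 consecutive calendar years
inside 1960–2019 has a missing-day fraction below 5% (days not covered by
the record count as missing). The longest qualifying span (ties: earliest)
defines the analysis extent. Remaining gaps are filled by linear
interpolation between the nearest observed neighbors; leading/trailing
missing values are trimmed first since interpolation cannot extrapolate.
Sub-daily records are reduced to the arithmetic mean per calendar day.
Provisional/estimated qualification codes in USGS RDB files are retained
as values.

Annual series take the mean, minimum and maximum of daily flow per
complete year (incomplete boundary years dropped). The year convention
defaults to calendar years; water years (Oct 1 – Sep 30, labelled by the
ending year) are available. Annual colors are computed only for records
with at least 30 complete years by default (slope fits on fewer than ~15
Fourier bins are unstable); 50 years is the faithful preset mirroring the
source selection for annual analyses.

## Detrending

Three variants, applied to discharge on its original scale:

* `raw` — mean removal only;
* `linear` — OLS line against the day index;
* `stl` — seasonal-trend decomposition by loess (statsmodels `STL`),
  period 365, non-robust, with an effectively periodic seasonal component
  (seasonal window 3651) and the classic default trend window (≈ 549 d).
  Loess evaluations are subsampled (`seasonal/trend/low_pass_jump = 37`)
  for a ~30× speedup; on an exactly periodic signal the remainder variance
  ratio is ~1e-28 with or without jumps, and on noisy series the residual
  spectra agree to four significant figures.

Leap days (Feb 29) are dropped before decomposition so every year
contributes exactly 365 samples and the seasonal period is an integer;
this removes < 0.3% of samples. This is not cosmetic: when the analyzed
length is *not* an integer multiple of 365, the STL seasonal/trend
filtering smears across Fourier bins and flattens reddened spectra by as
much as ~0.2 units; at integer multiples the effect is far smaller.

Annual series are detrended by linear trend removal only (no sub-annual
seasonality exists at annual resolution); `raw` is exposed as an option.

### Known limitation: STL flattens strongly reddened spectra

On *trend-free* colored noise the `linear` variant is near-neutral (mean
color shift ≈ −0.01), but `stl` systematically lowers the fitted color:
≈ −0.01 at `a = 0.5` growing to ≈ −0.10 at `a = 2.0` (about −0.07
averaged over a pink-to-red network), because the loess trend component
absorbs genuine supra-annual stochastic power and those low-frequency bins
carry high leverage in the log-log fit. This was cross-checked against R's
reference `stl(…, s.window = "periodic")` on identical input, which shows
the same offset — it is a property of loess seasonal-trend detrending, not
of this implementation. Between-method *correlations* of the fitted colors
remain ≥ 0.997, so rankings and spatial patterns are insensitive to the
detrending choice even where the small mean offset is not.

## Synthetic data: what it emulates and what it does not

`gen_colored_noise` uses spectral synthesis: Fourier coefficients with
deterministic amplitude `(k/T)^(−a/2)` and independent uniform phases
(Nyquist coefficient real, DC zero), inverse-transformed and standardized
to zero mean and a chosen standard deviation. Because the amplitudes are
deterministic, the periodogram follows the target power law *exactly* on
the discrete grid, so exponent-recovery tests are sharp (machine-precision
recovery) rather than statistical. Fractional differencing was not used:
it controls the asymptotic slope, not the slope on the finite grid.

`gen_ar1` provides the stochastic counterpart with a closed-form spectrum
`S(f) = σ² / (1 + φ² − 2φ cos 2πf)`, matching the `T^(−1/2)` periodogram
normalization (at φ = 0 both equal σ² at every frequency). It is the
independent analytic oracle for spectrum and banded-slope agreement.

`gen_streamflow_like` composes `exp(baseline + trend·d + A·sin(2π p_d/365
+ φ) + η_d)` with colored noise η in log-discharge, guaranteeing
positivity; the slope estimator is scale-invariant, so the exp transform
does not bias recovery at moderate noise scales (recovery tests confirm
mean recovered color within ±0.15 of the injected exponent at 20-year
records). The seasonal phase clock maps Feb 29 to Feb 28, so after the
pipeline's leap-day drop the seasonal component is exactly 365-periodic.
The composite form is a test harness, not a hydrologic model: it emulates
trend + annual cycle + 1/f noise but none of rating curves, snowmelt
physics, flow intermittency, or spatial correlation between gages.
Passing tests therefore demonstrate correctness of the estimation
machinery under the model's assumptions, not hydrologic realism.

`gen_driver_table` draws 13 covariates i.i.d. uniform on [0, 1] (three
geographic, four hydroclimatic, three land-use, three water-management
variables by default; names configurable) and builds the response as a sum
of known per-covariate effect functions plus Gaussian noise — the ground
truth for importance-recovery, partial-dependence and null-model tests.

All generators take explicit integer seeds; there is no global random
state, and identical spec + seed reproduces output bit for bit.

## Driver attribution

A random-forest regression links per-gage noise color to the 13
covariates. The table is split 80/20 train/test; the forest (300 trees by
default, `max_features = p/3`, `min_samples_leaf = 5` — the canonical
regression-forest defaults) reports out-of-bag MSE on the training split
and Pearson r, percent bias and MSE on the held-out split. Optional
10-fold cross-validation on the training split tunes `max_features` and
`min_samples_leaf` over a small grid; it is off by default so that
repeated-seed studies stay tractable.

Relative importance defaults to permutation importance computed on the
held-out split (less biased than impurity importance for mixed-scale
covariates; impurity is available as an option); negative permutation
values are clipped at zero and the vector normalized to sum to 100%, with
per-category sums for the grouped view. Partial dependence pins one
covariate to each point of a min–max-normalized [0, 1] grid and averages
model predictions over the modeling rows.

Prediction on new reaches is restricted to the calibration range: a reach
is predicted only when every covariate lies inside the [min, max] observed
among the modeling gages, otherwise it is masked with the violating
covariates named. Masking depends only on covariate values and ranges —
never on the forest's seed. Group contrasts (e.g. regulated vs
free-flowing) use the two-sample Kolmogorov–Smirnov test with asymptotic
p-values, reported with both group means.

## Numerical choices and problem sizes

* Exponent-recovery studies use `T = 16384` and ≤ 100 seeds per level;
  AR(1) agreement uses `T = 32768`, 200 replicates, with the mean
  periodogram compared to the closed form in log-spaced frequency bins
  (bins holding fewer than 16 Fourier frequencies are skipped — the mean
  of ~200 exponential-tailed ordinates per lone frequency has ~7% sampling
  error, which would test noise, not agreement).
* The detrending-sensitivity study uses 100 trend-free colored-noise gages
  with exponents evenly spaced over 0.5–2.0 (the pink-to-red range that
  dominates observed daily flow colors) and 15 whole calendar years — the
  selection-rule minimum record length.
* Annual-whitening studies use 50-year iid lognormal daily series. With 50
  annual values the slope fit rests on 25 Fourier bins and has sampling sd
  ≈ 0.3, so even an exactly white annual series classifies white only
  ~90–93% of the time; linear detrending additionally shifts the
  annual-max color by ≈ −0.13 (heavy-tailed annual maxima tilt the fitted
  line). Annual colors from ≤ 50-year records are therefore usefully
  interpreted at the category level, not as precise exponents.
* Driver-recovery studies use 200 gages, a dominant effect of 2·x on one
  covariate against residual sd 0.1, and 100-tree forests.

Ties and degenerate inputs: constant series produce zero-power periodograms
and flagged degenerate fits; constant responses flag the driver model and
leave correlations NaN rather than fabricating 1.0; identical series in
the sensitivity comparison are reported as degenerate pairs for the same
reason.
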