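# Methods

This note documents the models, parameter choices and numerical decisions
behind `oisiwc`, and what the synthetic-data tests do and do not establish
about real recordings.

## Experimental template

The analysis assumes the acquisition protocol of a rodent OISi
whisker-stimulation experiment: 100 fps, 16-bit reflectance imaging of both
hemispheres; stimulation trials of 9 epochs (1 s pre-stimulus baseline,
1 s stimulation, 13 s post) with a 21 s control epoch between consecutive
stimulation epochs (total 9·15 + 8·21 = 303 s); resting trials of 300 s.
Protocol descriptions sometimes quote ~315 s for the stimulation trial;
the generator follows the epoch arithmetic (303 s) and treats the round
figure as approximate. All peri-stimulus analysis is expressed relative to
stimulus onset, so the exact trial length is immaterial downstream.

## Preprocessing

Stages run strictly in order (each output is tagged and out-of-order input
is refused): rigid registration → fractional reflectance → spatial
Gaussian → temporal averaging → repetition averaging → block segmentation.

- **Registration** is rigid (translation + rotation), mean-squared
  intensity metric, two-level multi-resolution regular-step gradient
  descent (SimpleITK). On synthetic stacks with a smooth ±3 px random-walk
  drift the recovered shifts agree with the injected motion to
  ≲0.2 px RMS; frames where the optimizer fails keep the identity
  transform and are listed in the output metadata.
- **Fractional value.** ΔR/R against the per-pixel mean of the pre-stimulus
  baseline frames. For stimulation trials the default baseline is the
  pre-first-stimulus second; per-epoch baselines arise naturally in the
  epoch-averaged response metrics, which re-reference each epoch to its
  own 1 s pre-stimulus window.
- **Gaussian filter.** "Kernel size 5" is read as a truncated kernel of
  width 5 px with σ = 5/4, reflective boundaries (σ configurable).
  Reflective boundaries with a symmetric normalized kernel preserve frame
  means exactly.
- **Temporal averaging.** Non-overlapping 10-frame means (100 → 10 Hz);
  trailing partial windows are dropped, not padded.
- **Blocks.** 10×10 px, anchored at the image origin, row-major indexing;
  the `twelve_regions` layout is the 3×4 block division of one cortex used
  by the wavelet stage. Each block corresponds to 100×100 µm² of cortex.

## Evoked responses

The intrinsic signal is tri-phasic: initial dip, positive rebound, late
undershoot. Amplitude is |min| of the epoch-averaged, baseline-subtracted
response inside the first 6 s after onset; latency is the time of that
extremum. A 0.5 s moving average is applied before the extremum search so
residual physiological oscillations do not displace it; with the default
synthetic noise this removes most of the noise-induced bias in shallow
(stroke-side) dips. Latency is reported as NaN for flat blocks.

The "expected response" template is the epoch-averaged waveform of the
block whose temporal features (dip latency/amplitude, rebound time/
amplitude, undershoot time/amplitude) converge best to user-supplied
reference specifications; convergence = 1/(1 + d) with d the Euclidean
distance between feature vectors scaled feature-wise. Time features are
scaled by their reference value (≥1 s) and all amplitude features by the
reference dip amplitude: scaling sub-dip phases by their own (tiny)
reference amplitudes would make the distance hyper-sensitive to noise. A
feature-vector Pearson alternative is available (`method="pearson"`).
Ties break to the lowest block index everywhere.

The pattern-detection algorithm correlates each block's epoch average with
the template; blocks with r ≥ 0.7 are activated, and the activated area is
the block count × 100×100 µm². The threshold can be re-calibrated by
correlating binarized similarity maps with a seed-based FC map over the
candidate set {0.5, 0.6, 0.7, 0.8, 0.9}.

## Correlation FC

tCompCor-style nuisance regression (principal components of the block
series above the 0.98 temporal-variance quantile; 5 components by default —
the method's source literature leaves both free), zero-phase order-3
Butterworth band-pass 0.009–0.08 Hz, Pearson correlation between all block
pairs. Fisher z uses |r| clipped to 1 − 1e-12; the published normalization
"between 0 and 1" is implemented as min–max rescaling of the z matrix. FC
strength is the mean off-diagonal raw r (z- and normalized-based strengths
are reported alongside, since the averaging scale is ambiguous).

## Wavelet coherence

Morlet wavelet with ω₀ = 6; Fourier frequency of scale s is
(ω₀ + √(2 + ω₀²))/(4πs) ≈ 0.968/s Hz. The dyadic grid (δj = 1/12) spans
0.05–4.5 Hz (79 scales at 10 Hz sampling). The CWT is computed in the
Fourier domain on series that are detrended and standardized, zero-padded
to a power of two with at least five e-foldings of the largest scale as
margin (wrap-around ≲4e-6 at the outermost scale; the FFT route matches
direct time-domain convolution to <1e-8 on interior scales). The cone of
influence is the √2·s e-folding distance from either edge.

Smoothing is a Gaussian of width s in time (applied as the frequency-domain
multiplier e^{−(sω)²/2}) followed by a 0.6/δj-bin boxcar across scales with
fractional end weights. The time smoothing is edge-normalized by the
smoothed indicator function, which preserves constant fields exactly and
cancels identically in the coherence ratio, so R² equals the conventional
estimate. Because all smoothing weights are non-negative, Cauchy–Schwarz
guarantees R² ∈ [0, 1] up to rounding; zero-power cells are masked to 0.

The cross-spectrum phase arg(W^M W^{N*}) is +π/2 when the first series
leads by a quarter period (verified against a lagged-sinusoid oracle), so
phase arrows are drawn at the negated phase angle: right = in-phase,
left = anti-phase, down = first series leads by 90°.

**Monte-Carlo significance.** AR(1) coefficients are fitted to both inputs
by lag-1 autocorrelation (|φ̂| clipped to 0.99); 300 independent surrogate
pairs (the level and count are package defaults — the analysis they
reproduce states neither) yield a per-scale 95th-percentile coherence
threshold from in-COI cells, sub-sampled in time (coherence is heavily
autocorrelated, so ~64 columns per surrogate suffice). On independent
AR(1) pairs (φ = 0.7, N = 3000) the flagged fraction inside the COI is
5.4% ± 0.4% (mean ± SE over 10 seeds) at the 5% level.

## Band × interval statistics

Bands I–IV (2–4.5, 0.4–2, 0.15–0.4, 0.05–0.15 Hz; cardiac, respiratory,
myogenic, neurogenic) are half-open at the upper edge except band I,
closed at 4.5 Hz; membership is by the scale's Fourier frequency.
Intervals Δt1–Δt4 (1 s pre, 1 s stim, first/second 6.5 s post) partition
each 15 s epoch. Coherence is computed on the full stimulation-trial
series and epoch-relative windows are then pooled across epochs: band IV
periods (up to 20 s) cannot be estimated inside a single 15 s epoch, so
per-epoch transforms would be impossible. COI-excluded cells are dropped
by default (`coi_filter=False` reproduces naive averaging).

The two-way ANOVA behind the 12×12 statistical matrices uses factors group
(healthy/stroke) and replicate with no interaction, one observation per
cell — a reconstruction, since the protocol names the test but not the
factor structure. It is computed in closed form (balanced design),
vectorized over all 16 domains × 144 cells, and verified against
`statsmodels.anova_lm` in the test suite. P-value color classes: red
<0.001, orange <0.01, yellow <0.05, blue ≥0.05, white diagonal. No
multiplicity correction is applied across matrix cells, matching the
source analysis; Bonferroni adjustment is available for post-hoc
comparisons. Normality uses the Lilliefors-corrected Kolmogorov–Smirnov
test (estimated parameters; an uncorrected KS against fitted parameters
would be far from nominal size). The replicate unit (animals or seeds) is
taken as given by the caller and recorded in the output.

## Synthetic data

The generator is the package's verification instrument; its defaults are
the study conditions.

- **Evoked waveform**: difference of gamma-density kernels — dip peaking
  exactly at the configured latency (shape 4), a positive rebound (35% of
  dip, +3.5 s) and a late undershoot (15%, +8 s) that start at the dip
  extremum so they cannot displace it. Defaults: healthy amplitude
  4e-3 ΔR/R at 1.5 s; stroke 2e-3 at 2.0 s — typical intrinsic-signal
  magnitudes with the degradations of interest (ratio 0.5, shift +0.5 s).
- **Oscillators**: unit-variance AR(2) stochastic resonators at 0.12,
  0.34, 1.67 and 4.35 Hz, amplitude 5e-4 each, fractional linewidth 0.15.
  A Morlet at frequency f only resolves a bandwidth of roughly f/ω₀, so
  independent *pure* tones would look perfectly phase-locked inside the
  smoothing window and the injected coupling could never be recovered;
  the 15% linewidth makes coherence increase monotonically with coupling.
  Narrow lines (bandwidth 0.02) are used for spectral-line recovery tests,
  where sharp peaks, not coherence, are the point.
- **Coupling**: per band, block series mix a shared and a private
  resonator as √c·shared + √(1−c)·private (healthy c = 0.8, stroke 0.3),
  giving theoretical magnitude-squared coherence c². The AR(1) background
  (φ = 0.7 at 100 Hz, SD 2e-4) is shared with the same fractions
  (`noise_coupling`), providing the sub-0.08 Hz coupled fluctuations that
  the correlation-FC contrast requires — mirroring the reported weakening
  of low-frequency FC after stroke. Active blocks: all 12 healthy, 6
  stroke.
- **Pixels**: blocks are painted onto 30×40 px hemispheres over a static
  smooth reflectance texture (±5%, needed for registration gradients) at
  10000 counts baseline, with Gaussian shot noise of SD √counts, optional
  smooth rigid motion (translation up to `motion_amplitude` px plus small
  rotation), optional 2× supersampling with 2×2 binning, and uint16
  quantization. Motion defaults to 0 so that registration is exercised
  explicitly rather than silently required everywhere.

Everything is drawn from one `numpy` Generator seeded by `rng_seed`, so
outputs are bit-identical for a fixed configuration.

**What passing tests show.** Parameter recovery on this generator
demonstrates that the pipeline's estimators are unbiased and correctly
ordered under the modeled physiology: stationary narrowband oscillators,
linear mixing, additive AR(1)+shot noise, rigid motion. Real cortical
data add vascular anatomy, non-stationary state changes, pulsation and
non-rigid deformation, none of which are emulated; results on real
recordings therefore inherit only the algorithmic, not the physiological,
guarantees.

## Problem sizes in the test suite

The acceptance tests run the full-length protocol (303 s trials, 12
blocks) for parameter recovery, N = 3000 with 300 surrogates for the
Monte-Carlo calibration, and 2-epoch trials with 5 replicates per group
for the null calibration of the group statistics — sizes chosen so the
whole suite completes in a few minutes on one core while keeping every
estimate at the operating point the analysis uses.

## Known limitations

- The two-way ANOVA assumes a balanced design; unbalanced replicate sets
  are not supported.
- `nuisance_regression` operates on block series (the analysis' unit),
  not on pixel time series.
- The significance threshold is pointwise per scale; no area-wise or
  cluster correction is provided.
- Non-rigid motion and hemoglobin spectral unmixing are out of scope.
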