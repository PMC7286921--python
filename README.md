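# oisiwc

Frequency-specific functional connectivity for optical intrinsic signal
imaging (OISi), built around smoothed Morlet **wavelet coherence**.

OISi records the minute reflectance changes of an illuminated cortex that
track blood flow, blood volume and hemoglobin oxygenation. Classical
functional-connectivity (FC) analyses of such data correlate regional time
series below 0.08 Hz and therefore cannot see the faster hemodynamic
rhythms — cardiac, respiratory, myogenic and neurogenic oscillations.
`oisiwc` implements an analysis that measures FC in time and frequency
simultaneously up to 4.5 Hz, designed for the comparison of a healthy and
an ischemic (stroke) hemisphere in rodent whisker-stimulation experiments.
Because such datasets are rarely public, the package ships a ground-truthed
synthetic generator that emulates the full experiment, so every stage of
the analysis is verifiable end to end.

## The method

Reflectance stacks (100 fps, 16-bit) are rigidly registered, converted to
fractional reflectance ΔR/R = (Rᵢ − R_B)/R_B against the pre-stimulus
baseline, smoothed with a 5-pixel Gaussian, temporally averaged 100 → 10 Hz,
averaged over repeated trials and reduced to 10×10-pixel block time series.

From these blocks the package computes:

- **Evoked-response metrics** — amplitude and latency of the initial dip of
  the tri-phasic intrinsic signal, and the activated cortical area via a
  pattern-detection algorithm (Pearson similarity of each block to an
  "expected response" template, activation threshold 0.7).
- **Correlation FC** — tCompCor-style nuisance regression, 0.009–0.08 Hz
  band-pass, Pearson correlation between all block pairs, Fisher
  z-transform, and the scalar FC strength (mean off-diagonal r).
- **Wavelet FC** — the continuous Morlet wavelet transform (ω₀ = 6,
  computed in the Fourier domain),

      Wₙ(s) = Σₖ M̂ₖ ψ̂*(s ωₖ) e^{i ωₖ n δt},

  the cross-wavelet transform W^{MN} = W^M W^{N*}, and the smoothed
  wavelet coherence

      Rₙ²(s) = |S(s⁻¹ Wₙ^{MN})|² / ( S(s⁻¹ |W^M|²) · S(s⁻¹ |W^N|²) ),

  where S smooths with a Gaussian of width s in time and a 0.6/δj boxcar
  across scales. Significance is assessed pointwise against Monte-Carlo
  surrogate AR(1) pairs with matched lag-1 autocorrelation; phase arrows
  follow the standard convention (right = in-phase, left = anti-phase,
  down = first series leads by 90°).
- **Band × interval statistics** — coherence averaged over four frequency
  bands (I 2–4.5 Hz cardiac, II 0.4–2 Hz respiratory, III 0.15–0.4 Hz
  myogenic, IV 0.05–0.15 Hz neurogenic) and four peri-stimulus intervals
  (1 s pre, 1 s stim, two 6.5 s post windows), compared between hemispheres
  with two-way ANOVA per block pair (12×12 statistical matrices with
  P-value color classes), one-way ANOVA per domain, t-tests per band, plus
  normality/variance-homogeneity checks and Bonferroni post-hocs.

## Worked example

```python
import numpy as np
from oisiwc import preproc, response, corrfc
from oisiwc.synthdata import SynthConfig, generate_block_dataset

cfg = SynthConfig(rng_seed=1)                 # healthy vs stroke hemispheres
healthy, stroke, sched, truth = generate_block_dataset(cfg)

for name, bs in (("healthy", healthy), ("stroke", stroke)):
    b10 = preproc.temporal_average(bs, 10)    # 100 Hz -> 10 Hz
    m = response.signal_metrics(b10, sched)
    specs = response.reference_specs_from_waveform(
        cfg.response_amp[name], cfg.response_latency[name])
    expected = response.select_expected_response(b10, specs, sched)
    sim = response.pattern_detection(b10, expected, sched, threshold=0.7)
    fc = corrfc.fc_pipeline(b10)
    act = list(truth.active_blocks[name])
    print(f"{name}: amplitude={m.amplitude[act].mean():.5f}  "
          f"latency={np.nanmean(m.latency[act]):.2f} s  "
          f"activated_area={sim.activated_area_um2:.0f} um^2  "
          f"FC strength={fc.strength:.3f}")
```

prints

```
healthy: amplitude=0.00404  latency=1.55 s  activated_area=120000 um^2  FC strength=0.571
stroke: amplitude=0.00220  latency=1.85 s  activated_area=60000 um^2  FC strength=0.115
```

i.e. the pipeline recovers the injected stroke degradations: roughly half
the dip amplitude (0.0022 vs 0.0040 ΔR/R), a latency delayed by ~0.3–0.5 s,
half the activated area (6 vs 12 blocks of 100×100 µm²), and a clearly
weaker low-frequency FC. Continuing with the wavelet stage,

```python
from oisiwc import wavelet, bandstats
grid = wavelet.build_scale_grid(10.0)         # 0.05 - 4.5 Hz, omega0 = 6
b10 = preproc.temporal_average(healthy, 10)
cmap = wavelet.wavelet_coherence(b10.values[0], b10.values[1], grid)
print(bandstats.band_interval_average(cmap, sched).to_frame().round(3))
```

gives the 4-band × 4-interval coherence grid for one block pair
(healthy hemisphere, seed 1):

```
       dt1    dt2    dt3    dt4
I    0.765  0.736  0.756  0.740
II   0.811  0.801  0.801  0.749
III  0.919  0.933  0.939  0.863
IV   0.931  0.931  0.929  0.925
```

with the stroke hemisphere substantially lower in every domain (e.g. band
II ≈ 0.38–0.46). The same stages are scriptable from the shell:

```sh
oisiwc all --config cfg.yaml --out run1/ --seed 1
```

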