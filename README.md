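# nirsdecode

Single-trial decoding of motor execution versus rest from functional
near-infrared spectroscopy (fNIRS) and autonomic biosignals.

Brain–computer interfaces for motor rehabilitation need to detect, trial by
trial, whether a user is executing (or attempting) a movement.  This package
implements a complete offline decoder for that problem: cortical
hemodynamics recorded over primary motor cortex (M1) and ventral premotor
cortex (PMv) with a two-wavelength, four-path fNIRS probe per site, fused
with the autonomic response to effort — heart rate (HR), breathing rate
(BR), mean blood pressure (BP) and skin conductance response (SCR).  It is
aimed at researchers in neurophysiological signal processing who want a
tested, reproducible reference pipeline, including a synthetic-recording
simulator so every stage can be exercised without human data.

## Method

* **Optics** — raw intensities → incremental optical density
  ΔOD = −ln(I(t_{k+1})/I(t_k)) → modified Beer–Lambert inversion
  (ΔO2Hb, ΔHHb)ᵀ = (1/l_p)·E⁻¹·diag(1/DPF)·ΔOD → cumulative hemoglobin
  courses at 5 Hz, session-normalized, band-limited (Chebyshev-II low-pass,
  DCT high-pass at 1/54 Hz).  Motion artifacts are flagged by an inverse
  z-score ratio in sliding windows and affected trials excluded.
* **Biosignals** — adaptive-threshold beat/breath detection on squared
  derivatives, ECG+BP heart-rate fusion, piecewise-linear SCR detrending;
  four normalized 5 Hz feature series.
* **Features** — per probe, 8 hemoglobin channels are collapsed by weights
  β = argmin‖M·β − y‖² fitted on training trials (y = 1 active / 0 rest);
  observations are 15 s windows (75 samples), shifted 5 s past period
  onsets, of dimension 2 (fNIRS-only) or 6 (combined).
* **Classifier** — one left-to-right Gaussian-mixture HMM per class;
  10 random restarts per class; each (active, rest) candidate pair scored by
  the likelihood-weighted training accuracy
  κ = Σ_correct|D|/Σ|D| with D = LL_active − LL_rest; the κ-best pair
  labels test trials by the sign of D.
* **Assessment** — pairwise 4-fold cross-validation repeated 7 times over a
  10-cell topology grid (states 1–5 × mixtures 1–2), exact Clopper–Pearson
  chance tests, paired t-tests and relative gains between the fNIRS-only
  and combined decoders.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import nirsdecode as nd

timeline = nd.generate_timeline(seed=11)                  # 2 sessions, 30 pinch trials
recording = nd.simulate_recording(timeline, nd.SimulationConfig(seed=11))
report = nd.run_experiment(
    recording,
    grid=[nd.Topology(1, 1), nd.Topology(2, 1)],          # reduced grid
    n_repeats=3, seed=11)
print(report.table())
```

Output:

```
fnirs_only: Acc  98.3 ±  0.1 %  Sens 100.0 ±  0.0 %  Spec  96.6 ±  0.3 %  (Ns=1, Nm=1, N=60, CI [91.0, 100.0])
  combined: Acc 100.0 ±  0.0 %  Sens 100.0 ±  0.0 %  Spec 100.0 ±  0.0 %  (Ns=1, Nm=1, N=60, CI [94.0, 100.0])
```

Reading: on this synthetic subject (0.5 µM task-locked oxygenation
response plus realistic pulsation, respiration, Mayer waves and noise), the
fNIRS-only decoder classifies the 60 test trials with 98% cross-validated
accuracy, well above the 70% bound usually quoted for usable BCI control;
adding the four autonomic channels closes the remaining gap.  `N` counts included
test trials (motion-artifact-affected pairs are dropped); the bracketed
interval is the exact 95% binomial CI of the accuracy, and `Ns`/`Nm` are
the selected HMM topology.  A chance-level control is one flag away:
`nd.SimulationConfig(seed=..., null_mode=True)` zeroes every task-locked
effect, and the resulting CI straddles 50%.

The same pipeline is scriptable from a shell:

```sh
nirsdecode simulate subj01/ --seed 11
nirsdecode run subj01/ report.json --grid 1,2x1 --repeats 3
nirsdecode report report.json
```

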