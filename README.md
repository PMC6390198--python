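# entophys

Analysis pipeline for slice electrophysiology of the
entorhinal–hippocampal circuit: whole-cell current-clamp feature
extraction for Layer II fan and stellate cells, quantification of
voltage-sensitive dye imaging (VSDI) movies of dentate-gyrus network
responses, and nested linear mixed models for cells-within-animals
designs — together with a synthetic-data module that generates
protocol-complete recordings, VSDI movies and multi-animal cohorts with
known ground truth, so every stage of the pipeline is testable end to
end.

It is written for electrophysiologists and imaging labs who record
current-clamp protocols (step families, rheobase ramps, ZAP chirps,
spontaneous sweeps) and evoked VSDI responses, and who analyze them with
repeated-measures mixed models.

## What it computes

**Single cells.** Input resistance by the quadratic fit
ΔV = R_N0·ΔI + c_AR·ΔI² over subthreshold steps; the membrane time
constant as the larger component of a double-exponential fit to the
−300 pA onset; sag ratio (V_b − V_ss)/(V_b − V_min), rebound, resting
potential; rheobase from a 10-pA ramp; AP threshold at the maximum of the
second derivative of the voltage (local-polynomial fit), amplitude,
half-width, fAHP and DAP; per-AP amplitude/width/ISI, ISI₁/ISI₂ and the
adaptation ratio ISI_first/ISI_last; F–I curves with f0 and f_ss and the
post-step AHP; subthreshold resonance from the smoothed spectral
impedance of a 0–20 Hz ZAP; and the standard inclusion rules
(V_m ≤ −57 mV, AP amplitude ≥ 75 mV, bridge balance ≤ 22 MΩ). A
generalized Henderson calculator gives the liquid junction potential of
the recording solutions.

**VSDI.** Trial averaging, ΔF/F against a 50-frame optical baseline with
the dye's depolarization-positive sign convention, spatial box + cubic
temporal filtering, per-ROI response integrals (%·ms), activated area
above 0.05 % ΔF/F, paired-pulse ratios at 25 ms per DG blade, and stripe
profiles versus distance from the stimulation electrode.

**Statistics.** REML linear mixed models with a random intercept per
animal, repeated-measures covariance structures (diagonal, compound
symmetry, unstructured) selected by information criteria, Wald F tests
with containment degrees of freedom, estimated marginal means, and the
ΔΔCt relative-quantification arithmetic (2^(−ΔΔCt)) used for qPCR
genotyping.

The model and its assumptions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate one fan cell with the full protocol, extract its features, and
compute the junction potential of the recording solutions:

```python
from entophys.features import extract_cell_features
from entophys.junction import recording_junction_potential
from entophys.synth import fan_cell, generate_model_cell

rec = generate_model_cell(fan_cell(), seed=0, cell_id="fan-000")
f = extract_cell_features(rec)
print(f"R_N0 {f.input_resistance:.1f} MOhm  tau {f.tau:.1f} ms  "
      f"sag {f.sag_ratio:.3f}  V_m {f.v_m:.1f} mV  "
      f"rheobase {f.rheobase:.0f} pA")
print(f"AP: threshold {f.ap.threshold:.1f} mV  "
      f"amplitude {f.ap.amplitude:.1f} mV  "
      f"half-width {f.ap.half_width:.2f} ms  included: {f.qc.included}")
print(f"LJP {recording_junction_potential():.1f} mV")
```

prints

```
R_N0 138.4 MOhm  tau 28.7 ms  sag 0.805  V_m -69.3 mV  rheobase 80 pA
AP: threshold -43.5 mV  amplitude 90.3 mV  half-width 1.08 ms  included: True
LJP 14.5 mV
```

The extracted values sit on the fan-cell preset's generating targets
(R 138 MΩ, τ 28.9 ms, sag 0.803, V_m −69.3 mV, true rheobase 71 pA read
out at the 10 pA protocol granularity); the junction potential is the
Henderson value for a 120 mM K-gluconate internal against NaCl-based
ACSF. The same round trip over 50 seeds per phenotype — plus the VSDI
blade-asymmetry, paired-pulse and activated-area recoveries and the
coverage/type-I calibration of the mixed-model stage — runs as part of
the test suite (`tests/test_acceptance.py`).

The command-line interface exposes the same stages:

```bash
entophys simulate cell --preset stellate --seed 1 --out out/cell
entophys features extract --manifest out/cell/manifest.json --out out/feat
entophys features ljp
entophys simulate vsdi --ppr-scale 0.86 --out out/vsdi
entophys vsdi quantify --movie out/vsdi/trial00.tiff ... --rois out/vsdi/rois.json --out out/q
entophys stats fit --table cohort.csv --model model.json --out out/fit
entophys run --seed 1 --out out/demo     # simulate -> extract -> fit
```

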