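# Methods

This note documents the models, conventions and numerical choices behind
`entophys`: what each stage computes, which parameters matter, what the
synthetic generators do and do not emulate, and where design decisions
were genuinely open.

## Current-clamp feature extraction

**Spike detection.** An action potential starts where dV/dt first exceeds
20 V/s; its peak is the local voltage maximum within the following 5 ms
and must exceed −10 mV. Peaks closer than 2 ms to an accepted peak are
merged into it. All three criteria are configurable (`SpikeConfig`); the
defaults are robust at sampling rates of 10–50 kHz.

**AP threshold.** The operational threshold is the voltage at the maximum
of the second derivative of V(t) in the 5 ms preceding the peak. The
derivative is taken analytically from a local cubic (Savitzky–Golay) fit
over a 0.6 ms window rather than from finite differences, which keeps the
estimate stable against sampling noise. Amplitude is peak minus
threshold; half-width is measured at 50 % of that amplitude with linear
interpolation between samples, so it is sample-rate independent. The fAHP
is the minimum in the 5 ms after the peak (MEC cells only), the DAP the
post-fAHP maximum within 20 ms relative to the fAHP, reported absent when
a second spike falls inside that window.

**Input resistance.** ΔV = R_N0·ΔI + c_AR·ΔI² is fitted without
intercept over the steady-state responses of all subthreshold steps
(sweeps with detected spikes are excluded). R_N0 is the
voltage-independent input resistance, c_AR the anomalous-rectification
coefficient. Steady state is the mean over the last 200 ms of the step,
baseline the mean over the 100 ms before onset; both windows are
configurable and serialized with every output.

**Membrane time constant.** A double exponential is fitted to the onset
of the −300 pA response, from stimulus onset to the voltage minimum, and
the larger time constant is reported. Repeated −300 pA sweeps are
averaged pointwise before fitting. The fit uses variable projection (the
offset and amplitudes are solved exactly for any pair of time constants,
so only the two taus are optimized, from a log-spaced multistart grid
with taus bounded in [0.1, 200] ms), with two safeguards that matter on
noisy data:

* a small scale-free ridge (10⁻³) on the amplitudes, which removes the
  classic degeneracy of two nearly equal taus with huge cancelling
  amplitudes — without it, correlated recording noise occasionally drove
  the slower tau to the fit bound;
* a significance rule for "the larger value": a component only qualifies
  if it moves the trace by at least 5 % of the step deflection *inside
  the fitted window* (|a|·(1−e^(−T/τ))). A drift term chasing noise, or a
  relaxation too slow to evolve before the window ends, is not a measured
  response component. On a pure single exponential this rule reproduces
  the single-exponential answer, which is the sensible degenerate limit.

**Sag, rebound, resting potential.** Sag ratio is
(V_baseline − V_ss)/(V_baseline − V_min) on the −300 pA step; values of 1
mean no sag. Rebound is the post-offset maximum minus baseline within a
500 ms window, reported missing when a rebound spike falls in that window
(rebound spikes do occur in strongly sagging cells). The resting
potential is the mean of a 10 s spontaneous sweep; spikes in the window
log a contamination warning but do not void the mean.

**Rheobase.** The amplitude of the first sweep of the 10-pA ramp family
that elicits at least one AP; a family with no spikes returns an explicit
not-reached sentinel with the maximum tested current. The granularity of
this measurement is one protocol increment (10 pA), which is also the
tolerance used in the recovery tests.

**F–I analysis.** Average rate is spike count divided by the 1 s step
duration (so silent steps read exactly 0 Hz); f0 and f_ss are the
instantaneous rates of the first and last spike pairs; the post-step AHP
is the post-offset minimum minus pre-stimulus baseline, for steps from
50–500 pA.

**Resonance.** The impedance magnitude profile is the spectral ratio
|V(f)|/|I(f)| of the mean-subtracted 15 s ZAP sweep (0→20 Hz chirp),
smoothed with a 0.5 Hz moving average. The resonance frequency is the
argmax over 0.5–20 Hz; the band excludes DC where the ratio is singular.
A cell is classified resonant only when the peak sits away from the lower
band edge *and* exceeds the low-frequency impedance by at least 5 %
(resonance strength Q ≥ 1.05) — without the Q criterion, sub-percent
spectral ripple on a monotone low-pass profile can masquerade as an
interior peak. Traces containing APs raise a not-estimable error.

**QC.** Cells with V_m > −57 mV, AP amplitude < 75 mV or bridge balance
> 22 MΩ are excluded (strict inequalities); manually flagged putative
interneurons are excluded as well. Missing values never trigger a rule.

**Liquid junction potential.** The stationary potential of the
pipette/bath junction is computed with the generalized Henderson
equation, with species mobilities proportional to λ_eq/|z| (the
Nernst–Einstein diffusion weighting; using λ_eq directly over-weights
divalents and is a common implementation error). The shipped table holds
standard limiting equivalent conductivities at 25 °C; gluconate (24.3
S·cm²/eq), HEPES (22.05) and the organic polyanions ATP²⁻ and
phosphocreatine²⁻ (25) are literature estimates of the kind used by
junction-potential calculators. The sign convention is bath minus
pipette, so the K-gluconate internal against the NaCl-rich recording ACSF
gives a positive value (≈14.5 mV at the 25 °C default; whether such
calculations should be run at bath temperature is unsettled, and the
temperature is a parameter). On a bi-ionic junction the implementation
reduces to the Lewis–Sargent closed form exactly, which the tests verify.

## VSDI quantification

Trials (eight by default) are averaged pixelwise, then each pixel is
converted to ΔF/F in % against the mean of the first 50 frames. The dye's
emission *decreases* on depolarization, so the sign is flipped to make
depolarization positive (configurable). Pixels with non-positive baseline
are masked. Filtering is a 3×3 spatial box followed by an order-3,
5-frame Savitzky–Golay temporal filter — the cubic filter reproduces
cubic time courses exactly away from the reflected edges. ROI responses
are per-voxel trapezoidal areas (%·ms) from stimulus onset to the end of
the recording, averaged over the ROI; activated area counts pixels whose
post-stimulus peak strictly exceeds 0.05 % ΔF/F; the paired-pulse ratio
divides the second-pulse amplitude (measured relative to the ΔF/F level
immediately before the second stimulus, to separate overlapping
responses) by the first-pulse peak, per blade and averaged; stripe
profiles report peak or integral per voxel along an electrode-anchored
voxel line, in pixel units unless a µm-per-pixel scale is supplied.

## Nested mixed models

Cells (or slices) are nested in animals, so a random intercept per animal
absorbs the between-animal variance. Estimation is restricted maximum
likelihood computed by this package block-wise per animal: for the plain
random-intercept model the variance ratio is profiled with Woodbury
closed forms and optimized in one dimension; repeated-measures models
(within-cell factors such as AP number or injected current) add a
residual covariance per cell chosen among diagonal (heteroscedastic,
independent), compound symmetry, and unstructured (log-Cholesky), with
the generic REML objective minimized by Nelder–Mead. Model selection uses
smaller-is-better AIC (BIC available) among candidates that converged,
ties going to the simpler structure.

Fixed-effect tests are Wald F statistics with containment-style
denominator degrees of freedom: effects constant within animal are tested
against (number of animals − between-animal parameters), within-cell
effects against the residual. This is an approximation in the
Satterthwaite/Kenward–Roger family, chosen for robustness and speed; the
package stamps the method into its results rather than promising
numerical identity with any particular GUI package. Estimated marginal
means average model predictions over a balanced grid of the off-target
factor levels. No multiple-testing correction is applied; α = 0.05.

The simulation tests verify the calibration that matters in practice:
95 % intervals for a genotype effect cover the truth at nominal rate, and
the type-I error of the genotype test on null cohorts stays within
binomial error of 5 % over 500 replicates.

**ΔΔCt genotyping.** ΔΔCt = (Ct_target − Ct_norm) −
(Ct_target,ref − Ct_norm,ref) against a known homozygous reference;
relative quantity is 2^(−ΔΔCt). The genotype call is the nearest of
{0: negative, ½: hemizygous, 1: homozygous} on the relative quantity,
with an undetermined target (detected normalizer) called negative
outright. The thresholds are a convention; only the ΔΔCt arithmetic is
prescribed.

## Synthetic data

**Model cells.** The generator is an exponential-integrate-and-fire
neuron with up to two linear feedback conductances:

    C dV/dt = −g(V−E_L) − w₁ − w₂ + gΔ_T e^((V−V_T)/Δ_T) + I + ξ
    τ₁ dw₁/dt = a₁(V−E_L) − w₁
    τ₂ dw₂/dt = a₂(V−E_L) − w₂

w₁ is a fast H-current-like term that shapes the early sag trough; w₂ is
slower, deepens the steady-state sag, carries the subthreshold resonance,
and receives the spike-triggered adaptation increment. Two slow variables
are needed: with one, a stellate-like target set (R 50.3 MΩ, τ 13.3 ms,
sag 0.580, resonance 4.5 Hz) is jointly infeasible under the larger-tau
extraction convention, because the single slow relaxation would itself be
the larger fitted component. The spike is not integrated; when V crosses
a cut the integrator records a spike, resets, and a stereotyped waveform
template is pasted into the trace. The template is built directly from
waveform targets — a gentle quadratic foot into the upstroke (placing the
curvature maximum exactly at the target threshold), quarter-sine rise,
quarter-cosine fall into the fAHP trough, optional DAP bump, exponential
tail — with rise/fall durations rescaled in one shot to hit the target
half-width. Current noise is an Ornstein–Uhlenbeck process (σ = 2 pA,
τ = 3 ms by default, ≈0.2 mV of voltage noise), at which level QC pass
rates are effectively 100 %.

The fan and stellate presets target the control-group means of the two
cell classes (fan: R 138 MΩ, τ 28.9 ms, sag 0.803, V_m −69.3 mV, rheobase
71 pA, AP −45/91.8 mV/1.071 ms; stellate: R 50.3 MΩ, τ 13.3 ms, sag
0.580, V_m −64.7 mV, rheobase 123 pA, resonance 4.5 Hz, AP
−47.9/89.1 mV/0.991 ms, fAHP −51.6 mV, DAP 1.9 mV). Calibration solves
the linear parameters against exact eigendecomposition step responses
passed through the package's own extractors (so "τ" means exactly what
the pipeline reports), and V_T against a 1-pA-resolution simulated
rheobase; the resulting constants are frozen into the presets (re-running
`calibrate_phenotype` takes minutes) and validated by the recovery tests:
over 50 simulated cells per phenotype at the default noise, mean
re-extracted R, τ, sag, V_m are within 5 % of target, rheobase within one
10-pA increment, resonance within 0.5 Hz. The default protocol is the
full set the analysis expects: ±300 pA step family in 50 pA increments
(the −300 pA step repeated 5×), a 0–250 pA rheobase ramp in 10 pA steps,
a 15 s 0–20 Hz ZAP at 30 pA, and 10 s of spontaneous recording, all at
20 kHz with the integration step equal to the sample period (0.05 ms).

What the model cells do *not* emulate: electrode/access artifacts and
bridge imbalance, stochastic channel gating, genuine doublet dynamics
(the pasted template enforces a ~10 ms refractory period, so ISIs below
that do not occur), depolarization block, or any biophysically detailed
conductances. Passing recovery tests therefore demonstrate that the
analysis correctly inverts this generator family, not that it is robust
to every pathology of real recordings.

**VSDI scenes.** Responses are separable: anisotropic Gaussian spatial
footprints (two DG blades plus a CA3 satellite) times a
difference-of-exponentials time course (1.5 ms rise, 5 ms decay, 2 ms
latency), with per-pulse amplitude scaling for paired-pulse protocols and
the 100×100×512 @ 1 ms geometry of the acquisition. Raw movies apply the
dye's negative sign convention on a constant baseline with independent
Gaussian noise per trial. Because the kernels are analytic, per-ROI
integrals, peaks, the activated-pixel count and the pulse-scaling ground
truth come in closed form; the default blade sizes put the noise-free
single-pulse activated area at ≈1.7k pixels, the scale of wild-type DG
responses at the standard 0.05 % threshold. The fast decay is deliberate:
with a 25 ms pulse interval the first response must be essentially
complete before the second stimulus for the pre-second-pulse-referenced
PPR to recover the generative scaling within 5 %. The scenes do not
emulate bleaching, heartbeat/movement artifacts, shot-noise scaling with
intensity, or wave-like propagation (latency is uniform across space).

**Cohorts.** Hierarchical Gaussian draws: animal intercepts, then cell
responses as grand mean + genotype/age/sex/setup shifts + animal effect +
residual, optionally with a within-cell repeated factor under compound
symmetry (shared cell deviation) or per-level heteroscedastic residuals.
The preset variances (animal SD 0.03, residual SD 0.05 on a sag-ratio
scale) are conventions — the real data report marginal means, not raw
distributions — sized to give realistic intra-class correlation (~0.26).
Identical seeds give byte-identical tables.

## Numerical conventions and degenerate inputs

* Time is seconds from sweep start; frames and pixel coordinates are
  0-based; pixel coordinates are (row, col).
* Crossing-based widths interpolate linearly between samples.
* Tau fit window: onset to V_min, capped at 500 ms; shorter than 10
  samples raises an insufficient-data error.
* A hyperpolarizing step that fails to hyperpolarize raises an
  undefined-sag error; a first-pulse amplitude ≤ 0 raises an
  undefined-PPR error; empty ROIs and geometry mismatches are structured
  errors, not silent NaNs.
* All analysis settings live in one serializable `AnalysisConfig`,
  written alongside every table for provenance.

## Known limitations

* The AP-threshold voltage carries a small local-polynomial smoothing
  bias (≲2 mV on slow upstrokes); the threshold *time* matches the
  analytic curvature maximum to one sample.
* The containment degrees of freedom are approximate; for severely
  unbalanced designs a Satterthwaite approximation would be preferable.
* The unstructured covariance is practical only for small numbers of
  within-levels (its parameter count grows quadratically) and is
  fitted by a derivative-free method.
* ROI integrals on the 1 ms frame grid carry ~1 % quadrature error
  against the closed-form kernel integral, a direct consequence of the
  fast temporal kernel.
* The fan preset, like real cells with partial sag, shows a weak
  low-frequency impedance peak; fan resonance is not a calibrated target
  and the resonance flag for fan cells should not be over-interpreted.
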