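# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `opclamp`.

## Forward model of the voltage-clamp recording

OPs in developing white matter are small, electrotonically compact cells
(membrane resistance ≥ 1 GΩ, capacitance ≤ 35 pF), so the generator uses a
single compartment clamped through an access (series) resistance Rs with no
compensation, matching how such cells are recorded:

    C_m dV_m/dt = (V_cmd − V_m)/Rs − I_ion(V_m, t),   I_rec = (V_cmd − V_m)/Rs

`I_ion` comprises an ohmic leak (E_leak = −63 mV, so the holding current at
the standard −63 mV holding potential is near zero), Hodgkin–Huxley style
m³h sodium channels, agonist-gated AMPAR and kainate-receptor (KAR)
conductances reversing at 0 mV, and biexponential synaptic conductances.
The recorded sample at index *i* is the instantaneous current at the start
of the sample period, so a command step produces its full capacitive peak
ΔV/Rs at t = 0.

Numerics: exponential-Euler updates on V_m with substeps of ≤ 0.05 ms
(≤ 0.02 ms for step protocols, to resolve the 0.3 ms Na⁺ activation), which
is exact for a linear cell under piecewise-constant commands. A membrane
potential outside ±500 mV raises `SimulationError` instead of returning a
diverged trace. The integrator core is compiled with numba; an independent
`scipy.integrate.solve_ivp` oracle cross-checks it in the tests.

Parameter choices (units, defaults, rationale):

* Rm ~ lognormal(1.8 GΩ, σ=0.25) truncated at 1 GΩ; Cm ~ U(12, 34) pF;
  Rs ~ U(10, 20) MΩ — inside the OP inclusion criteria and the typical
  monitored Rs range.
* Na⁺ channels: m³h with V½ = −30/−55 mV, slopes 7 mV, τ_m = 0.3 ms,
  τ_h = 2 ms, ḡ_Na ~ lognormal(10 nS); gives transient inward currents of a
  few hundred pA. Only the presence and rough size of I_Na matter.
* Agonist conductance scale: control total kainate-evoked density
  10 pA/pF at −63 mV. The absolute scale is arbitrary (only relative
  genotype effects are constrained); all recovered contrasts are ratios.
  Per-cell density jitter: lognormal, CV 0.15; AMPAR fraction jitter
  SD 0.03.
* Rectification: GluA2-lacking AMPARs with intracellular spermine use an
  open-fraction Boltzmann f(V) = 1/(1 + exp((V − V_h)/k)) with V_h = −20 mV,
  k = 15 mV — near-full conduction at −63 mV, strong suppression at
  +17 mV. Active only when the cell is rectifying *and* the protocol's
  pipette solution contains spermine.
* Drug wash kinetics: first-order, τ_on = 20 s, τ_off = 60 s (slow bath
  application). The antagonist gate multiplies only the AMPAR component.
* Synaptic events: biexponential conductance, τ_rise = 0.3 ms,
  τ_decay = 3 ms, reversal 0 mV. Planted amplitudes are *recorded* peak
  amplitudes: the injected conductance is scaled by the computed clamp RC
  attenuation so the recorded peak matches the planted value.
* Recording noise: white Gaussian, SD 2 pA. Sampling 10 kHz (5 kHz for the
  long secretagogue recordings, 1 kHz for slow bath responses).
* Secretagogue (RR) scenario: spontaneous rate 0.02 Hz, plateau 2 Hz in
  control scaled by the preset's `synapse_rate_rel`, first-order rate rise
  with τ = 60 s so the plateau is reached by minute 3 — consistent with
  the minutes 3–6 analysis window. The triple knockout's rate factor is
  0.01 ("almost no events", not quantified; modeling choice).

## Genotype presets

Effects are planted as *relative* factors against the control genotype:
kainate density 0.53 (dko) and 0.23 × dko (tko); GYKI-sensitive fraction
0.80 (control, dko) / 0.39 (tko); EPSC rate factor 0.30 (dko) / 0.01
(tko); EPSC amplitude distribution identical across genotypes; OL density
effects by age (22% at P7 and 27% at P14 for dko); caspase fold 1.194
(dko, on a 22.7% control fraction) and 1.242 (tko, 24.8%); myelin figures
−20% (dko). The ~80% GYKI-sensitive fraction in both control and dko
implies the KAR component scales down with the knockouts; the presets
follow the reported numbers without resolving the mechanism. The tko
myelin effect (not measured at P14) is set to the tko OL effect (22%).

## Analysis algorithms

**Passive fit.** Repeated 5 mV probe sweeps are averaged; the post-step
transient is fitted with I(t) = I_ss + (I₀ − I_ss)·exp(−t/τ) starting
0.2 ms after the step (skipping clamp settling), with I₀ taken from the
fit's extrapolation to step onset rather than the raw peak sample. Then
Rs = ΔV/I₀, R_tot = ΔV/I_ss, Rm = R_tot − Rs and Cm = τ/(Rs‖Rm). The
parallel-resistance form of Cm is used; it differs from τ/Rs by < 3% when
Rm ≫ Rs, below test tolerances. Degenerate transients (I₀ ≈ I_ss) and
negative resolved resistances raise `PassiveFitError`.

**QC.** Cells fail as "not OP" when Rm < 1 GΩ or Cm > 35 pF (worst value
over the recorded time course, which makes the decision monotone in every
metric), and as unstable when Rs > 30 MΩ at any point or changes by > 50%
relative to its first value. The Rs rules can be bypassed
(`ignore_rs_rules=True`) for analyses that include all cells irrespective
of series resistance — the kainate-density measurement does this, since the
Rs correction handles the voltage error explicitly. The ">50% change" rule
is interpreted as series resistance relative to its first value.

**Na⁺ isolation.** The averaged response to the 20 mV hyperpolarizing step
(purely passive) is scaled by ΔV/(−20 mV) and subtracted from every step
response. Because the template carries the same Rs distortion, the
subtraction is exact (to noise) for any linear cell. The peak is the most
negative excursion within 10 ms of the step.

**Agonist responses.** The holding current is smoothed with a 1 s moving
average (bath responses are slow); ΔI is the peak deflection from the
pre-drug baseline. The Rs correction uses the total current at the
response peak: V_m = V_cmd − I_tot·Rs, I_corr = ΔI·V_cmd/V_m with a 0 mV
reversal. Responses with < 5 mV of remaining driving force are flagged
unquantifiable. Step steady states are measured over the last 50 ms of
each 200 ms step (after capacitive/Na transients). RI is computed on raw
(uncorrected) step currents — it is a within-cell ratio at two voltages,
so the correction largely cancels.

**EPSC detection.** The gap-free trace is high-pass filtered at 2 Hz
(zero-phase 2nd-order Butterworth). The noise SD is estimated iteratively
(threshold at 3 SD, mask detections ± 20 ms, re-estimate; ≤ 10 iterations,
with a 0.2 pA floor so near-noiseless traces keep a meaningful threshold).
Suprathreshold excursions separated by < 1 ms are merged into one
candidate (broadband noise fragments single events). Amplitudes and
kinetics are measured on the *raw* trace (median-smoothed over 0.5 ms)
against a 10 ms pre-event median baseline — the zero-phase high-pass puts
rate-dependent overshoots around events and would bias amplitudes.
Acceptance requires amplitude ≥ threshold, ≥ 1 ms above threshold and
20–80% rise time < decay constant (the operational reading of "rising
phase faster than the decay"); rejected candidates are retained for audit,
replacing the original manual accept/reject step with reproducible rules.
Per-cell quantal amplitude summaries use the median over well-isolated
(> 20 ms gap) events, since coincident events merged into one excursion
would inflate a mean.

**PPR.** Sweeps are averaged; the decay of the first response is fitted
with a single exponential from its peak to the second stimulus and its
extrapolation subtracted before measuring the second peak.

**Cohort statistics.** Densities pool counts and areas per animal (so they
are additive over fields). Caspase normalization: per-litter control mean
set to 1, mutant animals normalized within litter, normalized values
averaged across litters; litters without controls are excluded and
reported. Two-group comparisons are gated per group by Shapiro–Wilk at
α = 0.05 → t-test (Welch when a two-sided F-test rejects equal variances
at α = 0.05, an explicit trigger where the source procedure names none) or
Mann–Whitney U; ≥ 3 groups → ANOVA + Bonferroni or Kruskal–Wallis + Dunn
(implemented directly from the rank z-statistic). The step-down correction
multiplies the i-th smallest p-value by N − i + 1; by default the output
is additionally made monotone non-decreasing and capped at 1 (the bare
rule can invert orderings), with `enforce_monotone=False` reproducing the
literal rule. Ties are multiplied by their individual ranks.

## Synthetic cohorts: what they emulate and what they do not

Histology tables plant per-litter and per-animal lognormal random effects
(CV 0.06 each) on true densities and draw per-field Poisson counts
(~300 cells/field, 3–4 fields/animal ≈ 1000 cells counted per animal);
every litter contains both genotypes, as litter normalization requires.
Caspase cohorts use a litter CV of 0.12 and a within-litter animal CV of
0.05 — the litter component is exactly what the normalization removes.
Fiber cohorts draw axon diameters lognormal (mean 0.8 µm, CV 0.25) and
g-ratios N(0.78, 0.03) truncated to (0, 1); genotype scales only the
myelin-figure count. Internodes are forward-biased 3D random walks with
exactly the requested arc length. These dispersion choices make the
recovery noise small enough that 20-cell / 14-animal cohorts resolve the
planted effects.

The generator does not emulate: electrode drift or seal degradation,
correlated (1/f) noise, space-clamp errors in processes, receptor
desensitization kinetics, dendritic filtering of EPSCs, imaging/counting
errors other than Poisson sampling, or axon-diameter-dependent g-ratio
trends. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated assumptions, not robustness to every artifact
of real recordings.

## Problem sizes

The shipped pipelines use 20 cells/genotype for density and block
measurements, 15 six-minute recordings/genotype for EPSC frequency, a
6-litter caspase cohort (3 controls + 3 mutants per litter), and 14
animals/group (7 litters) for the P14 histology comparison — the group
sizes of the study design being modeled. The acceptance script completes
in about a minute on one CPU.

## Known limitations

* The Rs correction inherits a small (< 2%) bias from leak current flowing
  at the depolarized true membrane potential; it is bounded by the planted
  recovery tests up to Rs = 30 MΩ.
* The antagonist block estimate is ~1–2 pp below the planted fraction
  because the smaller residual current suffers a smaller Rs voltage error
  than the pre-block response (a real feature of uncompensated
  recordings).
* Detection recall degrades for amplitudes below ~5× the noise SD; the
  benchmark specifies ≥ 95% recall at 20 pA in 3 pA noise.
* Paranodal exclusion in g-ratio measurement is an acquisition rule and is
  not representable on circumference pairs; it is assumed upstream.
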