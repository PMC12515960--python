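# Methods

`pecircuit` implements a firing-rate model of a layer-2/3-like cortical
microcircuit in which prediction-error (PE) neurons emerge through inhibitory
synaptic plasticity, together with the analysis layer used to characterize
them.  This note documents the model, its assumptions, the parameters that
matter, the numerical choices, and the places where the published description
left the design open — and what passing the test suite does and does not show.

## The circuit model

**Populations.** 280 excitatory pyramidal cells (PCs) and 120 inhibitory
interneurons: 40 parvalbumin (PV), 40 somatostatin (SOM) and 40 vasoactive
intestinal peptide (VIP) cells.  SOM cells split 7:3 into Martinotti cells
(dendrite-targeting) and non-Martinotti cells (soma-targeting).  PCs are
two-compartment units — a somatic compartment and one (1D feature model) or
two (2D model) independent apical dendritic branches; interneurons are point
units.

**Somatic dynamics.** The somatic activation h^E of PC i follows

    tau_E dh/dt = -h + (I_i - Theta),      r = [h]_+

with tau_E = 60 ms and rheobase Theta = 14 s^-1.  The total somatic current

    I_i = (1 - lambda_E) I^syn_E,i + sum_k lambda_D [I^syn_Dk,i + c_i,k]_+

combines the somatic synaptic input with the rectified dendritic
contributions (lambda_E = 0.31, lambda_D = 0.27 are the soma and dendrite
leak fractions).  The bracket [.]_+ limits how much a hyperpolarized dendrite
can drag the soma down.  The drive term (I - Theta) itself is *not*
rectified; only firing rates are.

**Synaptic currents.** The soma receives background drive x^E = 28 Hz,
recurrent PC excitation W^EE (self-connections excluded), and inhibition from
PV cells (W^EP) and non-Martinotti SOM cells (W^EnM).  Each dendritic branch
receives its external drive, recurrent excitation W^DkE, and Martinotti
inhibition W^DkM.  A dendritic Ca2+ event of amplitude c = 7 s^-1 is added to
a branch whenever the within-dendrite input

    I0 = lambda_E I^syn_E + (1 - lambda_D) I^syn_Dk

strictly exceeds Theta_c = 28 s^-1 (the Heaviside convention at the threshold
is H(0) = 0, i.e. no event exactly at threshold; events are computed per
branch, a config flag shares one event across branches instead).

**Interneurons.** Each interneuron follows
tau_I dh/dt = -h + x^Y + W^YE r^E - W^YP r^P - W^YS r^S - W^YV r^V with no
rheobase, and rate rectification.  tau_I is not constrained by the published
parameter set; we default to fast kinetics (2 ms).  Backgrounds are
x^P = x^S = x^V = 2 Hz and x^D = 0.

**Connectivity.** Connection probabilities and mean total afferent strengths
per (postsynaptic, presynaptic) type pair are fixed tables (see
`connectivity.default_pathways`); the E<-S entry is delivered by
non-Martinotti cells, the D<-S entry by Martinotti cells, and the tabled
dendrite<-soma "probability of 1" is the structural within-cell coupling
already expressed by the leak fractions, not a synapse.  Each synapse exists
independently with probability p^XY; weights are initialized from
U(0.5 wbar, 1.5 wbar)/N_w where N_w is the postsynaptic cell's realized
afferent count on that pathway, so the expected total input equals wbar
exactly.  Robustness checks multiply every weight by an independent
U(1-f, 1+f) factor.

## Stimuli and tuning

Features are abstract scalar dimensions; the 1D space is {0, 1, 2, 3} and the
2D space {(0,2), (0,3), (1,2), (1,3)}.  A value of -1 marks the absence of a
stimulus in a dimension.  Tuned drive follows a Gaussian tuning curve with
peak 30 Hz; PCs have width sigma_PC = 0.8 and SOM cells the broader
sigma_SOM = 1.0 (an ablation flag removes SOM tuning entirely; a control sets
sigma_SOM = sigma_PC).  Preferred stimuli are evenly distributed over the
feature space within each population and within each SOM subtype.

Sensory input S drives PC somata and SOM cells through their tuning curves
and PV cells with an untuned drive; a prediction P drives each dendritic
branch through a 1D Gaussian on that branch's feature dimension, and VIP
cells with an untuned drive.  The two untuned amplitudes are not part of the
published parameter set; we default both to the tuned-input peak (30 Hz), and
they are exposed as `ModelParams.sensory_drive_pv` and
`ModelParams.prediction_drive_vip`.

Stimulus noise is additive Gaussian on the feature values, drawn once per
phase and shared by every tuning curve (the stimulus is perturbed, not the
neurons).  The published noise scale "sigma_noise = 0.35" is described as a
variance but written as a sigma; we interpret 0.35 as the standard deviation
(the symbol convention), which is also the milder reading.

Attention multiplies the feature-difference term of the attended dimension by
a gain (default 1.2) before the Gaussian is evaluated: the peak response is
unchanged and off-peak responses shrink, i.e. tuning is effectively
sharpened.

## Plasticity

Five inhibitory pathways are plastic — PV->soma, non-Martinotti SOM->soma,
Martinotti SOM->dendrite (per branch), SOM->PV and VIP->PV — with
per-presentation learning rates 1e-4, 1e-7, 1e-6, 1e-6 and 1e-6.  Weights are
reparameterized as w = softplus(v) (so they stay strictly positive) and the
rules act on v with the logistic gradient factor:

    soma:      dv = eta (r^E - rho) sigma(v) r_pre
    dendrite:  dv = eta (lambda_D (r^E - rho) + (A^Dk - eps)) sigma(v) r_pre
    PV input:  dv = -eta [W^EP-backpropagated PC error] sigma(v) r_pre

with target rate rho = 1.25 Hz and dendritic activity A^Dk = I^syn_Dk + c.
The dendritic target eps is described only as a rectified baseline quantity;
we measure it per neuron as the rectified dendritic synaptic input of the
untrained network at baseline (a scalar override, including eps = 0, is
available).

Training alternates noisy match phases (P = S = 0, or (0,2) in 2D) with
baseline phases.  Updates are computed from the frozen steady state of each
phase and applied jointly (synchronous), on match and baseline phases alike;
a flag restricts updates to stimulus phases.

**Training length and batching.** The published description does not state
the number of presentations.  The slowest pathways (learning rates 1e-6 and
1e-7 acting through logistic factors of order the per-synapse weight,
~0.02-0.1) move appreciably only after 10^6-10^8 presentations.  We therefore
integrate the learning dynamics in coarse steps:
`PlasticityParams.update_batch` presentations share one computed steady state
and their updates are applied in a single increment (clipped at
`update_clip` in v-space for stability of the fast PV->soma pathway).  This
is a step-size choice on a stiff-but-slow gradient flow, not a change to the
rules or rates.  Defaults: 2e7 effective presentations in batches of 2000,
i.e. 10000 steady-state solves (a few minutes on one CPU).  A geometric
batch-ramp mode (`update_batch = 0`) is available for longer effective runs.

The training objective (PC rates at rho in both match and baseline phases)
is only partially attained at this length: the learning flow is strongly
path-dependent, and driving the slowest (1e-7) pathway to its asymptote in
coarse batches lets other pathways overgrow first (in long-batch
experiments the tuned somatic inhibition absorbed the match balance, and the
PV-afferent rule showed per-cell runaway growth once individual PV cells
were silenced — the printed rule has no brake in that regime).  The shipped
default is the regime in which the mismatch phenomenology is reproduced
(see below); residual consequences of partial convergence are listed under
limitations.

## Numerics

Steady states are computed three ways, all agreeing on the fixed point:

- explicit Euler integration of the rate equations (dt = 0.1 ms default,
  dt <= tau_I/10 enforced; update order per step: currents, calcium,
  activations, rectification — runs are bit-reproducible for a given seed),
  with a convergence check max|dr|/dt < 1e-4 s^-2 over the final window;
- damped fixed-point relaxation h <- h + alpha (drive - h) (alpha = 0.5),
  same fixed points, far fewer evaluations;
- semismooth Newton on the fixed-point residual with the piecewise-linear
  Jacobian of the rectifiers (calcium events treated as locally constant) and
  a relaxation fallback; this is the training-loop default and converges to
  machine precision in a handful of iterations from a warm start.

The grouped linear solver computes r = -(W_grouped)^-1 S for the
population-level system whose variables stack group-mean PC rates, per-branch
dendritic activities A^Dk and interneuron group rates.  The grouped
coefficient matrix applies the leak fractions and signs of the rate equations
inside the blocks and subtracts the identity, so it reproduces the full
simulator exactly when every rectifier is interior and calcium is fixed
(oracle-equivalence test).  Dendritic "elements" appear as 2n extra rows and
columns in the 2D model.  For pathway decomposition, M = W_grouped^-1 is
Hadamard-split by entry sign; pathX_E - pathX_I = M_X . S holds exactly by
construction.

## Analysis conventions

- **PE classification**: Delta R / R = (r - r_BL)/r_BL; a PC is a PE neuron
  when |Delta R / R| < 10% in the trained match phase and Delta R / R > 20%
  in its designated mismatch phase — the phase whose actual stimulus equals
  the neuron's preferred feature under the trained prediction.  For neurons
  preferring the trained prediction itself that phase *is* the match phase,
  so no separate mismatch requirement applies: their PE signature is staying
  at baseline while the prediction is fulfilled.  Zero-baseline neurons are
  flagged unclassifiable.
- **Selectivity coefficient**: gamma is the skewness-style statistic
  <(x_s - xbar)^3> / <(x_s - xbar)^2>^{3/2} over the group means, with plain
  (unweighted) averaging across groups and an exact 0 when the across-group
  variance is below 1e-12.  For prediction-driven suppression we apply it to
  the rectified suppression depths [baseline - r_s]_+ rather than to raw
  rates: only activity reductions below baseline count as suppression, a
  network whose groups all sit at or above baseline is unselective by
  construction (gamma = 0), and graded suppression deepest at the predicted
  feature yields a positive coefficient.  Applied to raw rates the same
  statistic is dominated by the feature-graded dendritic excitation profile
  and is nonzero (~0.76) even for homogeneous untrained weights, which
  contradicts the published account of the untrained network; the
  suppression-depth form reproduces it exactly.  |gamma| > 0.5 is the
  significance convention.
- **Similarity**: 1D, the tuning-curve ratio f(s_max, s0)/f_max; 2D,
  1 - mean|s_max - s0| / (||s_max|| + ||s0||) with Euclidean norms (L1 is a
  config option; the norm is not specified in the source description).
- **Two-condition comparison**: two-sample t-test plus Mann-Whitney U-test,
  both at alpha = 0.05, no multiple-comparison correction (matching the
  reporting convention of the original analysis).

## Open design points and how they were resolved

- tau_I (unprinted): 2 ms, configurable.
- Interneuron rheobase: none (the interneuron equation has no Theta).
- Untuned PV/VIP drive amplitudes (unprinted): 30 Hz, the tuned-input peak.
- Noise "variance 0.35": treated as SD (config switch for variance
  semantics).
- eps in the dendritic rule: rectified untrained baseline dendritic input,
  per neuron.
- Updates during baseline phases: applied (the flag `update_on_baseline`
  restricts them).  With match-only updates the baseline operating point is
  never corrected and drifts well below the target rate.
- Training length: see above; free in the source description.

## What the synthetic protocols do and do not show

All inputs are generated internally from the Gaussian tuning specification;
there is no external data.  Training and test stimuli use the same noise
model (additive feature noise, SD 0.35), so passing tests demonstrate that
the plasticity rules balance excitation and inhibition and produce
feature-specific mismatch responses *under the model's own stimulus
statistics* — they say nothing about natural stimuli, spiking dynamics,
conduction delays, or spatial structure, none of which are modeled.

## Known limitations

- **Partial convergence of the slow pathways.**  At the default training
  length the network robustly acquires the mismatch phenomenology —
  S-preferring groups dominate their mismatch phases, mean mismatch
  responses grow with feature distance, and responses correlate positively
  with similarity to the actual stimulus and negatively with similarity to
  the prediction — but the absolute operating points remain off-target: the
  trained baseline rate settles near 1.5-2.5 Hz rather than rho = 1.25 Hz,
  per-neuron match responses deviate from baseline by more than the 10% PE
  band for most cells, and prediction-only input leaves every group at or
  above baseline (no below-baseline suppression), so the suppression
  selectivity coefficient is 0 after training.  Analysis of the
  two-condition balance shows that the fully converged configuration —
  PV rates clamped during stimulus phases by strong SOM->PV inhibition,
  strongly graded PV->PC weights, and non-Martinotti weights carrying the
  baseline completion — is a zero-error state of the model and reproduces
  the intended selective suppression when constructed directly, but reaching
  it from the specified initialization requires integrated learning far
  beyond what the batched flow attains stably (the 1e-7 pathway needs
  ~10^8-10^9 presentations while the PV-afferent rule becomes unstable in
  coarse batches).
- Because trained PV inhibition is not clamped at sensory-only phases,
  sensory-only responses are strongly suppressed after training; tuning
  curves are therefore characterized on the varying-stimulus family of the
  standard test protocol (actual stimulus swept under the trained
  prediction).  Gaussian peak fits on that family are clean for the
  intermediate groups but degenerate for the suppressed (predicted) group
  and the farthest group, whose curve is dominated by mismatch
  amplification.
- The gradient-derived rules are used exactly as stated; no local
  approximation of the backpropagated PV term is provided.
- Tuning-curve fits use four stimulus points per group in the 1D protocol;
  fitted widths are poorly constrained there and only peak locations are
  interpreted.
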