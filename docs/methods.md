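# Methods

`taskdcm` implements a complete task-fMRI effective-connectivity analysis
— first-level GLM, node time-series extraction, bilinear DCM inversion,
and hierarchical group inference — together with a synthetic-cohort
generator, so that every stage of the analysis, and the full
2 × 3 × 2 × 2 grid of data-processing choices it supports, can be
exercised end-to-end on a laptop with known ground truth.

## The task and its protocol

The simulated experiment is a spatial stimulus–response compatibility
(SRC) paradigm: brief (0.2 s) lateralized visual stimuli require a button
press with the ipsilateral hand (compatible, "Pro") or the contralateral
hand (incompatible, "Anti").  The protocol is a mixed block/event design:
24 blocks (12 per condition, pseudo-randomized with at most three
consecutive blocks of one condition), each preceded by a 2-s instruction
cue and containing 13–16 trials with onsets jittered uniformly 2–4.5 s
apart; rest periods of 15–19 s separate blocks; repetition time is
2.03 s.  Trial sides are Bernoulli(0.5).  These defaults generate ≈ 27
minutes of scan time, matching the emulated acquisition; desk-scale runs
shorten the experiment by reducing `n_blocks` (the test suite uses 6
blocks ≈ 7 minutes).

Behaviour is simulated with condition-specific lognormal reaction times
(Anti slower than Pro; the underlying paradigm literature reports such a
cost but no distribution, so the lognormal and its parameters are this
package's choice) and a configurable 3% error rate split between
wrong-side responses, out-of-window reaction times (valid window
150–1500 ms) and omissions.

## Generative model of the cohort

Neural dynamics follow the bilinear neural-mass equation

    dz/dt = (A + Σ_k u_k(t) B_k) z + C u(t)

with nine nodes (bilateral DLPFC, PMC, IPS, AI and the AMCC, centred at
fixed MNI template coordinates), driving input u(t) confined to bilateral
IPS, and task-modulated coupling B_k.  Inputs are {0,1} boxcars and are
*not* mean-centred, so A retains its interpretation as task-independent
baseline coupling.  Self-connections are parameterized as
−0.5·exp(a_ii) Hz: sampled subjects are automatically self-stable, and a
spectral check (largest real eigenvalue of A and of A+B_k negative)
rejects destabilizing random-effect draws with a bounded number of
redraws.

Hemodynamics follow the balloon–Windkessel model (vasodilatory signal,
flow, volume, deoxyhemoglobin; constants κ=0.64 s⁻¹, γ=0.32 s⁻¹, τ=2 s,
α=0.32, E₀=0.4, V₀=0.04, k₁=7E₀, k₂=2, k₃=2E₀−0.2) with per-node transit
time and a read-out gain ε as the regionally variable parameters.  The
BOLD read-out is expressed in percent signal change.  Neural and
hemodynamic states are integrated jointly with fixed-step Heun at the
microtime resolution (TR/16 ≈ 0.127 s, fine enough that every 0.2-s event
occupies at least one bin); inputs are treated as constant within a step.
A numba kernel with the batch dimension innermost makes the batched
integration (used for finite-difference Jacobians) fast; a pure-numpy
implementation with identical dynamics serves as fallback and
cross-check.  Step-halving changes trajectories by well under 1%, and the
linear (B=0) special case matches the piecewise matrix-exponential
solution to the same accuracy.

Ground-truth effect sizes are this package's own simulation defaults —
the emulated study publishes no generative parameters.  The default group
mean has feed-forward intrinsic coupling 0.25 Hz from each IPS to its
ipsilateral targets, weak homotopic (0.05 Hz) and feedback (−0.05 Hz)
links, driving weights 1.0 on bilateral IPS, and twelve planted
event-locked modulatory edges of ±0.5–0.9 Hz concentrated on the
connections of the driving IPS nodes (positive feed-forward, negative
feedback — the pattern task-network analyses of this paradigm report).
Between-subject variation is additive Gaussian per parameter class (SDs
0.02 / 0.05 / 0.08 / 0.08 for A off-diagonal, self-scalings, B and C).
The planted modulations sit at the strong end of the range reported for
task fMRI; this is a deliberate scaled-down-design choice backed by a
pilot power analysis: the desk-scale cohorts are roughly four times
shorter and an order of magnitude smaller than the emulated study, and
modulation exerted only during 0.2-s stimulus windows carries
intrinsically little leverage, so weaker effects would require
full-length protocols and hundreds of subjects to resurface at a 95%
posterior-probability threshold.

Voxel rendering places each node's voxels on a 4-mm lattice inside its
10-mm group sphere (≈ 81 voxels, with a per-subject sub-voxel jitter of
the whole lattice; voxels falling outside the sphere are dropped).  A
subject-specific true peak is drawn near the template centre (Gaussian,
SD 2.5 mm, clipped at 6 mm) and voxel weights fall off as a Gaussian with
10-mm FWHM around it — the wide profile stands in for the 8-mm spatial
smoothing of the emulated pipeline, which is out of scope at voxel-cloud
scale.  Voxel signal = weight × node BOLD + global confound (smooth
series, amplitude 0.5% with ±10% voxel-wise loading scatter) + six
motion-like random-walk confounds + two slow nuisance series (white
matter / CSF stand-ins) + white noise (SD 0.1% by default).  The noise
level is likewise a scaled-down-design choice (it yields single-subject
peak t-values ≈ 10–20 and model fits explaining ≈ 70–90% of node-series
variance); real single-voxel noise is larger, and is compensated in real
studies by four times more volumes and ten times more subjects.  What the
simulator does *not* emulate: spatially correlated or physiological
noise, temporal autocorrelation (noise is white, hence OLS rather than
prewhitened GLM by default), susceptibility artefacts, slice timing, or
task-correlated motion — so passing tests demonstrate the pipeline's
statistical machinery, not robustness to those real-data complications.

## First-level analysis

Preprocessing regresses, per voxel, an intercept, the motion-like and
slow nuisance regressors, and (iff GSR is enabled) the global series,
then removes a discrete-cosine drift basis with a 128-s high-pass cutoff.
The GLM convolves condition boxcars (four regressors Anti-L/R, Pro-L/R
for event designs, built from all trials or only correct trials; two
full-block regressors for the block design) with the canonical
double-gamma HRF, pairs each task regressor with its temporal derivative,
and fits by OLS (optional single-pass AR(1) prewhitening).  Contrasts
(Anti, Pro, Anti+Pro, Anti−Pro) average the relevant condition
regressors; t-maps are one-sided.

Thresholding is voxel-wise p < .05 (uncorrected) or cluster-extent
corrected: clusters form at one-sided p < .01 (config knob) under face
connectivity on the voxel lattice, and survive if their extent exceeds
the 95th percentile of the maximum null extent from sign-flip
permutations of the GLM residuals (200 by default).  The emulated
pipeline's cluster inference is not fully specified, so these three knobs
are explicit configuration with no fidelity claim.  Both one-sidedness
choices follow the activation-direction convention.

Node extraction intersects each 10-mm group sphere with the
suprathreshold mask; any empty intersection excludes the subject
(recorded, not raised).  The maximal-t voxel of the intersection becomes
the individual peak; suprathreshold voxels within a 4-mm sphere of it are
summarized by the first eigenvariate — the leading singular component,
scaled to the RMS amplitude of the contributing voxels and sign-aligned
with their mean series (the alternative plain voxel mean is available).

## Model inversion

The full-connection DCM frees all 72 off-diagonal A couplings, 9
self-scalings, all 81 B entries, the 2 IPS driving weights and, by
default, 9 log-transit times and a log read-out gain (174 parameters).
Priors are zero-mean Gaussians: intrinsic off-diagonal couplings
N(0, 1/64), self and hemodynamic log-scalings N(0, 1/256), modulatory
couplings and driving weights N(0, 1) — modulatory effects are the
quantities under study and carry broad priors in standard bilinear
implementations, whereas a 1/64-variance prior was found in piloting to
shrink desk-scale modulation estimates to a few percent of their true
values; per-node observation noise has log-precision hyperpriors
N(4, 1).  Inversion is
variational Laplace: Gauss–Newton ascent on the free energy
F = accuracy − complexity with finite-difference Jacobians (step 1e-3)
evaluated in one batched integration, step-halving whenever a proposed
update would lower F, a trust-region cap of 1 per-parameter step, and
one damped, clamped Newton update of each noise log-precision per
iteration (step ≤ 2, bounds [−8, 16]).  A per-node constant plus the same
128-s cosine drift basis is projected out of both data and prediction
(the observation-model confounds).  Iteration stops when the accepted
step's F gain falls below 0.05 nats (after at least 8 iterations while
noise precisions are still adapting) or at 32 iterations; study-scale
runs in the test suite cap at 16 iterations.
Accepted steps never decrease F *within* an iteration's linearization —
that is the property the step-halving rule enforces and the tests assert;
across relinearizations and hyperparameter updates the reported F is a
fresh bound and may move either way, which is inherent to this family of
schemes.  If no step improves on the prior expansion point, the
prior-centred posterior is returned with a non-convergence flag.

Model quality is the pooled explained variance
EV = 100·(1 − SS_res/SS_tot) of the drift-projected data (SS_tot about
per-node means); subjects below 10% are excluded from group analysis,
with both bookkeeping stages (extraction-qualified and EV-qualified
counts) logged.

## Group inference

PEB models the selected first-level parameters (the B matrix by default)
as θ_i = (x_iᵀ⊗I)β + ε_i with a scalar random-effect precision optimized
by bounded search on the hierarchical free energy (β marginalized
analytically).  The group-effect prior is zero-mean with an
empirical-Bayes variance four times the pooled first-level scale
(posterior uncertainty + between-subject spread + mean magnitude) — broad
enough not to shrink genuine group effects, while the evidence-based
effect test retains its Occam penalty.  Each effect's posterior
probability comes from analytic Bayesian model reduction (prior clamped
to zero for that effect; PP = 1/(1+exp(−ΔF))), with PP > 95% as the
evidence threshold.  Between-group analysis stacks two condition sets
with a mean-centred indicator covariate; when the two "groups" are the
same cohort processed twice the induced dependence is noted in reports
but not modelled, mirroring common practice.  Bayesian data comparison
reports, per common subject, the negentropy difference
½(ln det Σ_b − ln det Σ_a) of the B-block posteriors in nats, averaged
over subjects and classified by the 1.1 / 3 / 5-nat evidence bands.

## The processing grid

`grid.enumerate_conditions` crosses GSR (with/without), GLM design
(AllTrials / STrials / Blocks), extraction-and-modulation contrast
(Anti / Anti+Pro) and thresholding (corrected / uncorrected) into 24
conditions; one cohort is simulated once and reprocessed per condition.
The DCM stimulus binding follows the condition (the paper's consistent
formulation): event designs drive the model with 0.2-s trial boxcars
(STrials: correct trials only), the block design with full-length block
boxcars; the modulatory input contains the Anti events alone or the
Anti∪Pro union; the driving input always covers the stimuli of both
conditions, since every trial presents a visual stimulus (an option makes
driving = modulatory for sensitivity checks).  For the Anti+Pro contrast
a single modulatory input carries the union of events; a two-input
layout is available behind a flag.  Inversions are cached by a content
hash of (extracted series, stimulus functions, priors, options), so
conditions yielding identical series reuse fits, and results are
independent of execution order.

## Problem sizes and what the tests show

The shipped test suite runs the full pipeline on 6-block protocols
(≈ 207 volumes) in two regimes.  Recovery checks use a clean 30-subject
cohort (voxel noise 0.1%): planted-edge signs and posterior
probabilities, rank correlation between true and estimated modulation,
12-subject subsets for the GSR and thresholding null comparisons, and a
second 24-subject cohort with one modulatory edge removed for the
between-group difference test.  Design-comparison checks use a noisier
16-subject cohort (voxel noise 0.25%): in that regime the event-related
analysis — whose modulatory input matches the event-locked ground truth
— calls more evident modulatory edges than the block analysis, while the
block analysis retains far higher parameter certainty; at low noise the
ordering of edge counts reverses, because the misspecified block model
concentrates on biased nonzero values with very tight posteriors, so the
noise level is part of the phenomenon, not a nuisance.  Analytic components
(t-statistics, eigenvariate, model reduction, conjugate linear-model
limit, entropy arithmetic) are checked against independent oracles at
machine-level tolerances; stochastic claims (false-positive calibration,
recovery, directional condition effects) are asserted with soft bounds at
these desk-scale sizes.

## Known limitations

- The white-noise observation model makes OLS exact in simulation but
  understates real fMRI autocorrelation; the AR(1) option is provided but
  untested against real data.
- Event-locked modulation with 0.2-s boxcars is weakly identified at
  desk scale; group-level recovery depends on the strong planted effects
  discussed above.
- The between-condition PEB treats twice-processed cohorts as independent
  groups (as in common practice); certainty comparisons inherit that
  approximation.
- The hierarchical random-effect precision is a single scalar per fit,
  not a full covariance component model.
- No spatial normalization, image-space statistics, or group-level
  voxelwise inference: node template coordinates are fixed inputs.
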