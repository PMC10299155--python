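# Methods

This note describes the models, estimators and numerical choices behind
`smg4`, and what the synthetic-data generators do and do not emulate.

## The binding model

A surface-tethered G-quadruplex visited by a fluorescently labeled
G4-binding protein is modeled as a continuous-time Markov chain over
discrete intensity states. In the two-state model, state 0 (unbound, dark)
converts to state 1 (bound, bright) at the observed association rate
v+1 = k_on · [P] · f_label, where [P] is the nominal protein concentration
and f_label the fraction of molecules carrying a dye; state 1 converts
back at the dissociation rate k_off, which is concentration independent.
Dwell times in each state are exponential, so

- τ = 1/k_off is the mean bound-state lifetime,
- k_on = v+1 / ([P] · f_label),
- Kd = k_off / k_on.

The three-state variant (substrates folding two quadruplexes) adds a
second, brighter bound level on a linear chain 0 ↔ 1 ↔ 2.

## Synthetic trajectories

`simulate_trajectory` samples the chain exactly (exponential waiting
times, Gillespie-style) and renders it the way an EMCCD camera would: the
noiseless intensity of a frame is the occupancy-weighted average of state
intensities over that frame, so a frame spanning a transition takes an
intermediate value. Gaussian noise of SD `noise_sd` is then added.
Defaults: 0.1 s frames, 3000 frames, a 300-frame pre-injection baseline
held in state 0, state intensities 0 and 500 AU, noise SD 100 AU
(SNR = separation/noise = 5). Intensity units and SNR are conventions —
the instrument's are unknowable from printed results — and are
configurable everywhere; all kinetic quantities are intensity-scale
invariant by construction since they derive from dwell durations only.

The ground truth records both the exact chain dwells and the
frame-discretized path (per-frame majority state). Sub-frame dwells can
be invisible after camera integration; this is deliberate, so that
missed-event bias is part of what recovery tests measure.

What the generator does *not* emulate: Poisson/EMCCD gain statistics
(Gaussian noise only), evanescent-field depth, spectral cross-talk in the
binding channel, stage drift, or heterogeneity of rates between
molecules. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
instrumental pathology of real data.

Movies render each trajectory as a 2-D Gaussian point-spread function
(σ default 1.2 px) whose full-grid integral equals the trajectory
intensity, on a constant background with Gaussian pixel noise. Spot
centers are placed by rejection sampling with a minimum pairwise
separation of 6σ, which keeps the overlap probability negligible (<5%)
by construction.

## Trajectory selection

`qc_select` applies three criteria, mirroring conventional manual
selection: (i) no excursion above baseline + 3 SD lasting ≥ 3 frames in
the 300 pre-injection frames; (ii) the post-injection baseline (median of
sub-threshold frames) within 2 baseline SDs of the pre-injection baseline
("baseline consistent throughout"); (iii) at least 2 post-injection
events persisting ≥ 3 frames above threshold. The numeric thresholds for
"above baseline" (3σ) and "consistent" (2σ drift) are this package's
choices — selection conventions are rarely published with numbers — and
every threshold applied is echoed in the QC report and run manifest so it
is auditable. Frame indexing is 0-based with a half-open boundary: frames
[0, 300) are pre-injection. The first 300 frames are removed before
idealization.

## Idealization

All selected trajectories of an experiment are pooled and fit with a
single Gaussian hidden Markov model (shared emission means/SDs, shared
transition matrix) by Baum–Welch EM, using hmmlearn for the E/M steps.
Choices:

- Convergence on *relative* log-likelihood change < 1e-6, max 500
  iterations. (An absolute tolerance is meaningless when pooled
  log-likelihoods vary by orders of magnitude with ensemble size.)
- 5 restarts (2–3 in the cheaper screening contexts), each initialized
  from k-means++ cluster centers of a ≤20k-point subsample of the pooled
  intensities, with a sticky transition prior (0.9 on the diagonal).
  Best final likelihood wins.
- States are always relabeled by ascending mean, so state 0 is unbound.
- Per-molecule intensity normalization is not modeled; the generator
  produces a common scale, and the global emission model mirrors a pooled
  analysis of all molecules. This is a documented simplification, not a
  claim about any particular instrument's behavior.

Model order (2 vs 3 vs 4 states) is chosen by BIC on the pooled
log-likelihood, `p·ln(N) − 2·LL` (lower is better), standing in for a
variational evidence bound: both penalize complexity, and what the
package validates is parameter recovery, not equivalence to any specific
Bayesian implementation. The score name is recorded in output metadata.

Raw BIC alone is not enough here, for an instructive reason: camera
integration paints intermediate intensity values across every transition
frame, and an extra HMM state parked on those values wins likelihood even
though it is not a molecular state. Such states are identifiable after
the fit: their expected lifetime `1/(1 − T[k,k])` is below the time
resolution (threshold 1.5 frames), or they sit closer than 2 emission SDs
to a neighbor (two equal Gaussians are unimodal below a 2σ separation, so
closer levels are indistinguishable in the intensity histogram), or they
hold almost no frames (weight < 1e-3). Fits with any such state are
flagged, and model selection prefers the best-scoring *unflagged*
candidate, falling back to raw BIC if every candidate is flagged. Flags
are always reported, never silently dropped.

Decoding is Viterbi, in log space. The learned start distribution is
floored at 1e-6 before decoding so that a hard zero (every training
molecule begins unbound) cannot force the first frame of an arbitrary
trace.

## Dwell-time analysis

Maximal constant-state runs of the idealized paths become dwells. The
first and last run of every molecule are censored by the observation
window; they are recorded (so dwells tile each trajectory exactly) but
excluded from fits by default. Dropping censored end-dwells is a
documented default, not a claim about the original analyses, and the
flags are retained so the sensitivity is testable.

Rates are estimated two ways:

- **MLE with left truncation.** At 100 ms resolution no dwell shorter
  than one frame is observable; ignoring this biases rates low (for an
  exponential with rate k truncated at t_min, the naive estimate
  converges to 1/(t_min + 1/k)). The truncated likelihood uses
  f(t | T ≥ t_min) = k·exp(−k(t − t_min)); its single-component MLE is
  the closed form k = 1/(mean − t_min) with SE k/√n, and without
  truncation it reduces exactly to 1/mean. The two-component truncated
  mixture is maximized numerically (Nelder–Mead over log-rates and a
  logit weight, six spread starts), with SEs from the numerically
  differentiated observed information and the delta method.
- **Histogram least squares** (the conventional Prism-style procedure):
  counts binned at one frame interval up to the 95th-percentile dwell,
  fitted by unweighted least squares to A·exp(−kt) (or a two-phase sum),
  SEs from the covariance of the fit.

Phase count (one vs two exponentials) is tested by the extra-sum-of-
squares F-test on the histogram route and a likelihood-ratio test
(2ΔLL ~ χ², 2 df) on the MLE route, at α = 0.05. On *frame-discretized*
dwells these tests are opt-in rather than default: the discrete spike of
single-frame dwells is genuinely non-exponential and a mixture test will
happily spend its second component on it. The pipeline's headline
estimate is therefore the single-component truncated MLE; phase testing
(`components="auto"`) is for distributions, like continuous or coarsely
binned ones, where it answers the intended question.

## Kinetic constants

k_on is computed per concentration from its v+1 (labeling-adjusted
effective concentration) and pooled across concentrations by inverse-
variance weighting, matching a per-concentration calculation rather than
a single regression of v+1 on [P]. k_off is pooled the same way and must
be concentration independent: a weighted linear regression of k_off on
[P] is reported, and a slope with p < 0.01 is flagged as a model
violation. Monotonicity of v+1 with [P] is checked and reported.
τ = 1/k_off and Kd = k_off/k_on hold exactly in every emitted result;
SEs propagate first order (SE_τ = SE_k/k², relative SEs of a ratio add in
quadrature). Units: rates 1/s, k_on 1/(M·s), Kd kept in molar with an nM
convenience view. For a three-state selection, a single k_off/τ/Kd is
ill-defined and only v+1/k_on-level quantities are meaningful; the
bound-fit path rejects multi-component summaries unless explicitly asked
for the dominant phase.

The published rate-constant table for the four G4P variants is packaged
in `smg4.reference` as ground-truth input for recovery studies and
internal-consistency checks (τ·k_off ≡ 1, Kd·k_on ≡ k_off at printed
precision). Two printed entries disagree with their own rate constants
(one Kd, one τ, both by rounding-inconsistent amounts); the reference
module documents them and consistency checks use the remaining rows.

## FRET

Apparent efficiency per frame is E = A′/(A′ + D) with A′ = A − l·D, where
l is the donor-leakage coefficient (default 0.10; the true instrument
value is unknowable from published material, so it is a mandatory,
recorded parameter). E is clamped to [0, 1]; frames with non-positive
corrected total are excluded and counted, and the out-of-range fraction
is reported as a QC metric. Histograms use the per-molecule mean E
(matching a per-molecule analysis; per-frame pooling is available) at a
fixed 0.01 bin width on [0, 1] and are fitted with a two-component
Gaussian whose *bin-integrated* form (CDF differences) is used in the
least squares — essential for populations narrower than a bin, where a
center-sampled density is ill-conditioned. Component SDs are bounded
below at a quarter bin. If the two-component fit fails, a flagged
single-Gaussian fallback is fitted. Two conditions are compared by the
shift in matched component means (threshold 0.05) plus a two-sample KS
test on per-molecule means (α = 0.01); "no change" requires both.

## Mass photometry

Contrast-to-mass calibration is an ordinary least-squares line through
≥ 2 standards (the conventional ladder: β-amylase 56/112/224 kDa,
thyroglobulin 670 kDa), required to be strictly monotonic. Event masses
are binned at exactly 3 kDa; landing (positive) and departure (negative)
events can be analyzed separately or together — the generator mirrors
each landing event with an exact negative twin, reproducing the
mirror-image distributions seen on glass at equilibrium. Default
analysis takes positive events; both signs are reported where relevant.
Histograms are fitted with a sum of Gaussians (component count fixed, or
swept 1..n and chosen by a residual-based BIC). Fitted means are
interpreted as integer stoichiometries a·protein + b·DNA by exhaustive
bounded search (a ≤ 6, b ≤ 4, tolerance 4 kDa ≈ one bin plus fit error);
"unassigned" is a reported outcome, not an error. Raw interferometric
video processing is out of scope — the pipeline starts at event lists,
which is where instrument vendor software hands off.

## EMSA and labeling efficiency

Fraction bound versus protein concentration is fitted by nonlinear least
squares to f = [P]ⁿ/(Kdⁿ + [P]ⁿ), n fixed at 1 (hyperbolic) or free
(Hill, bounded [0.2, 8]). A fitted Kd outside the titration range is
flagged as extrapolated. Supershifted species are pooled into "bound";
gel densitometry is out of scope and input begins at quantified
fractions. Labeling efficiency follows Beer–Lambert:
C_dye = A550/(ε_dye·l), C_protein = (A280 − c·A550)/(ε_protein·l),
efficiency = C_dye/C_protein; the dye-at-280 nm factor c defaults to 0
(the plain two-wavelength calculation) with ~0.08 conventional for Cy3,
and extinction coefficients are required user inputs.

## Problem sizes and determinism

Recovery studies use ensembles chosen to give the estimators adequate
power at modest cost: 500 trajectories × 3000 frames for dissociation-
rate recovery (≈10⁴ bound dwells), 120 × 2000 per concentration for the
association series, 20 × 500 per replicate (×20 replicates) for
model-order selection, 500–2000 molecules for FRET populations, 5000
events for mass histograms, 12-point titrations for EMSA. Every
stochastic component draws from `numpy.random.SeedSequence` streams
derived from a single seed: per-molecule, per-restart and per-stage
streams are spawned deterministically, so identical configurations give
bit-identical trajectories and byte-identical result JSONs.

## Known limitations

- No missed-event correction beyond left truncation; very fast kinetics
  (lifetimes ≲ 2 frames) are outside the validated regime and will be
  flagged rather than estimated.
- The pooled emission model assumes a common intensity scale across
  molecules; strong per-molecule brightness variation would broaden
  emission SDs and, at worst, masquerade as extra states (which the
  degeneracy flags would surface, not fix).
- Dual-channel registration is a fixed translation supplied by
  configuration; no registration estimation, drift correction or
  colocalization analysis.
- The F-test/LRT phase-count machinery assumes continuous dwell
  distributions; on frame-quantized data it is intentionally opt-in.
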