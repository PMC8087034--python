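# Methods

This note records the modelling assumptions, numerical choices, and design
decisions behind `bvselect`, in the order the pipeline runs. It states no
empirical results beyond what the test suite and `scripts/acceptance.py`
compute.

## Model realization and integration

Both candidate models are linear time-invariant systems. Rather than the
third/fourth-order single-equation forms — whose right-hand sides contain
Ü and V̈, which are impulsive for piecewise-constant inputs — the package
realizes the structural form as a four-state system
x = (ΔBV, ∫e_BV, r_u, r_v) with inputs (U, V), plus an auxiliary ∫q state
used to report the interstitial volume change. The equivalence of this
realization to the collected single-equation forms was verified
symbolically during development, and is enforced at test time by two
independent oracles: the per-channel rational transfer functions
(`transfer_function`, shared denominator s³+Kp·s²+Ki·s for the original
model and (s²+Kp·s+Ki)(s−A_u)(s−A_v) for the refined), and an external
zero-order-hold discretization (`scipy.signal.cont2discrete` + `dlsim`).
Note the refined model has no pure integrator unless one of the state
parameters is exactly zero; the s = 0 denominator root is a property of
the original model only.

Integration is exact for the input class: rates are piecewise constant and
left-continuous on a uniform grid (the inputs' interpolation rule is a
package convention; nothing finer is defined by the experiment), and each
step applies the matrix exponential of the augmented (state + input)
system. There is no solver tolerance; the only error is floating point.
All states start at zero. Volumes are ml, time is minutes; per-kg protocol
quantities are converted to ml at protocol construction using the subject
weight.

`TrajectoryEvaluator` is the performance-critical path used inside the
optimizer: it compresses the protocol into maximal constant-input segments,
computes one matrix exponential for the shortest hop, composes longer hops
by the zero-order-hold chain rule (Ad(k·h) = Ad(h)^k,
Bd(k·h) = (Ad^{k−1}+…+I)·Bd), and runs the hop recursion in a compiled
(numba) loop. Its output is bit-identical to sampling the dense simulation.

## Structural identifiability

`params_to_theta` materializes the frequency-domain coefficient vector Θ
(7 entries for the original model, 11 for the refined); the entry
multiplying the s⁻¹(U−V) regressor is identically 1 and serves as a
structural anchor. The inverse map factors the quartic characteristic
polynomial implied by the first four refined entries by root pairing:
every partition of the four roots into a real pair (A_u, A_v) and a
quadratic pair (s²+Kp·s+Ki) is scored by the relative consistency residual
over all Θ entries, and the best consistent candidate is returned. The
residual tolerance (default 1e-5 relative) is configurable; an
inconsistent Θ raises an error naming the disagreeing entries. The
regressor Φ(s) itself is never materialized and no persistent-excitation
check gates fitting; the consistency residual is the exposed diagnostic.

## Measurement model

ΔBV is reconstructed from hematocrit by red-cell mass accounting:
RBC(t_k) = BV(0)·H(0) − Σ_{i≤k} V_H(t_i)·H(t_i),
PV = (1−H)·RBC/H, ΔBV = RBC + PV − BV(0). The recursion is implemented
exactly as stated (it is itself a first-order approximation; no
higher-order correction is added). The withdrawal V_H(t_i) is attributed
to the hematocrit reading at the same timestamp — whether hematocrit was
read before or after a withdrawal is not determined by the data layout,
and the generator exposes the convention through its withdrawal schedule.
The synthetic inverse (`hct_from_bv`) is closed-form:
H(t_k) = R_{k−1}/(BV(t_k)+V_H(t_k)); the round trip is exact to
floating point, which the tests verify at 1e-6 ml.

## Synthetic cohort

The generator emulates the experiment's structure, not its animals. Per
subject: weight ~ U(30, 45) kg and baseline BV = 60 ml/kg (neither is
given by the experiment; both configurable), hemorrhage events of
25 ml/kg over 0–15 min and 5 ml/kg over 50–55 and 70–75 min, infusion
active in 30–180 min, measurements every 5 min to 80 min and every 10 min
after. Parameters are drawn per fluid group from independent normal
priors whose means and spreads follow the fitted cohort statistics of the
two models, truncated to the invariants (1+α > 0, Kp, Ki > 0, A ≤ 0).
Measurement noise is iid Gaussian with noise_sd = 50 ml by default —
a free knob chosen so synthetic per-subject RMSE magnitudes are of the
order seen in sheep data, not a measured value.

The infusion controller of the physical experiment is not reproduced (it
is unspecified here); a discrete proportional law stands in:
every 5 min inside the infusion window, u = clip(−Kc·ΔBV, 0, u_max) with
Kc = 0.1 min⁻¹ and u_max = 100 ml/min. It produces the decaying
resuscitation profile the experiments describe, is seedable, and couples
the protocol to the subject's own dynamics; a fixed piecewise-constant
infusion table is accepted as an alternative. Because generated data are
exactly LTI + iid noise, calibration on them is a well-specified
recovery experiment — passing tests demonstrate correct machinery, not
that real sheep follow the model.

The protocol grid step defaults to 1 min in the generator (0.5 min and
finer work identically): with piecewise-constant inputs the integration is
exact at any step, so the grid only needs to resolve the event boundaries
and measurement times.

## Calibration

The likelihood is Gaussian iid; σ is profiled analytically
(σ*² = RSS/K), so the fitted objective is −L*(Θ, σ*(Θ)) + 2γ·‖Θ‖₂ with
the penalty on the L2 *norm* (not its square — a `penalty="squared"`
switch exists because "penalizing the L2 norm" is ambiguous between the
norm and its square), on
the raw parameter scale (no standardization; a documented limitation:
parameters with larger magnitudes absorb more shrinkage). σ is excluded
from the penalized vector. Bounds default to the pooled per-parameter
cohort statistics (mean ± 4 sd over both fluid groups) intersected with
the invariants.

The optimizer is multi-start: Latin-hypercube starts inside the bounds
(n_starts = 10 by default), each polished by trust-region least squares on
the residual vector — valid because the profiled −L* is a strictly
monotone transform of RSS, and far better conditioned than the
log-likelihood surface itself, which is near-singular as RSS → 0 on
noise-free data. When γ > 0, the best least-squares candidate is further
polished by bounded L-BFGS-B on the penalized objective. Kp and Ki are
optimized on a log scale internally (they are positive and span decades);
bounds and penalty are applied on the raw scale. Everything is
deterministic given the seed.

Penalty selection fits each γ ∈ {1, 3, 5} to the first 120 min and scores
the last 60 min by AIC computed on the held-out residuals with σ profiled
there (`aic_on="full"` is available; which segment the AIC should use was
an open choice). Ties go to the smallest γ. γ is selected once per
(subject, model) and reused for all replicate fits of that subject.

Bootstrap replicate fits (the prediction scenarios run up to
2 models × 2 scenarios × 100 replicates per subject) warm-start from the
full-data fit with a single start and looser convergence
(`REPLICATE_OPTIONS`); envelope percentiles are insensitive to the last
digits of each replicate optimum, and this is what keeps the full study
tractable on one CPU.

## Calibration assessment

Four residual features — |mean residual|, residual SD (the "standard
error of residuals" is read as the SD, with ddof = 1), |OLS slope of
residual vs time|, |OLS slope of residual vs measured ΔBV| — are taken as
absolute values so the origin is the ideal point, normalized per feature
by the maximum over the pooled subjects × models (normalizing per model
would destroy inter-model comparability of U_d), and collapsed to the
Euclidean distance U_d ∈ [0, 2]. Degenerate trend regressors yield a
0 trend with a warning. Group comparisons: paired t-tests between models
on per-subject metrics, Welch t-tests between fluid groups on fitted
parameters, chi-squared (no continuity correction) on coverage
proportions. No multiple-testing correction is applied, by design.

## Sensitivity analysis

First-order Sobol indices use a Saltelli pick-and-freeze estimator with
independent uniform sampling over per-parameter ranges (by default the
min–max of fitted values across the cohort), N = 1000 base samples and
N·(P+2) model runs, evaluated at report times 30, 80, 120, 180 min. The
B-sample factor is centered, making the estimator exactly invariant under
affine rescaling of the output. Small negative estimates are Monte-Carlo
noise, clipped to 0 for classification (raw values retained). Thresholds:
< 0.01 insensitive, > 0.1 highly sensitive; a parameter insensitive at
all report times is flagged insignificant. The first-order indices sum to
1 only for additive models; the BV models are not additive in their
parameters, so the package asserts Σ G_i ≤ 1 + Monte-Carlo tolerance
rather than equality. Indices are computed per subject protocol; the
study reports the cohort mean matrix.

## Predictive capability

Sub-sampling is without replacement at 75% of the calibration set
(classical with-replacement bootstrap is a switch, default off); the
baseline t = 0 point is always retained when present, since sub-samples
without it leave the fit unanchored. The nominal guidance of keeping at
least 4·P points per fit cannot be satisfied by the six-parameter model
under the sparse 5/10-min schedule (75% of the transient calibration set
is 14 points < 24), so the enforced floor is 2·P by default and
configurable; identifiability still requires K > P. Envelopes are
pointwise 2.5th–97.5th percentiles with the linear-interpolation quantile
rule. Envelope membership and the interval-score branches treat boundary
equality as inside, with a 1e-9 ml absolute tolerance that absorbs
optimizer round-off in degenerate (zero-width) envelopes. The transient
holdout window is [45, 80] min, boundaries inclusive.

The leave-one-out scenario fits a normal distribution per parameter to
the donor estimates and samples with rejection outside the donors'
min–max range; the infusion-retention parameter (α_u original, A_u
refined) uses donors of the held-out subject's fluid type only.
Parameters are drawn independently (no donor correlation structure is
imposed). Zero donor variance degrades to a point mass with a warning.
Per-point scores are pooled over subjects for the model comparison
(paired t-test per point, chi-squared on within-envelope counts).

## Study orchestration and reproducibility

Every random draw descends from the master seed through a documented
derivation: `SeedSequence((master, crc32(stage), crc32(variant),
crc32(subject_id)))`, so stages are independent, order-insensitive, and
bit-reproducible; no stage touches global RNG state. The study writes the
cohort (CSV + key=value sidecars + JSON manifest with the hidden ground
truths), per-variant fit results, a calibration table, per-scenario
envelope CSVs, and a summary JSON carrying the config hash.

Default study sizes (11 LR + 5 HEX subjects, 100 bootstrap replicates,
1000 leave-one-out draws, N = 1000 Sobol base samples) follow the
emulated experiment's own settings and complete in roughly ten minutes on
one CPU; the inner penalty-selection fits use 3 starts and the scenario
anchor fits warm-start from the full-data optimum, which is where the
orchestrator saves most of its time relative to fitting everything cold.

## Known limitations

* The generator's noise level, weights, baseline BV, and controller are
  plausible conventions, not measured quantities; only the study's
  qualitative contrasts (refined vs original) are meaningful, not the
  absolute score magnitudes.
* Penalization on the raw parameter scale makes γ's effect depend on
  parameter units.
* The least-squares stage optimizes the unpenalized RSS before the
  penalized polish; for very large γ the two-stage scheme could in
  principle miss a strongly shrunk optimum.
* A ≤ 0 is enforced as a stability constraint on the refined target
  dynamics; fitted values on the boundary (A = 0) are reported as-is.
* Single-process execution; determinism is the contract, parallelism is
  not.
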