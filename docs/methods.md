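# Methods

This note documents the models, estimators and numerical choices behind the
`corticospinal` package: an analysis chain for simultaneous primary motor
cortex (M1) + cervical spinal cord fMRI that estimates corticospinal
connectivity, fits direct/indirect network models at the group level,
compares them with a swap-bootstrap null, and recovers per-participant
sign-constrained network weights that can be correlated with handedness.

## Experimental model

The design is a block alternation of unilateral finger movement: by default
8 task blocks (right-hand movement, RHM, alternating with left-hand
movement, LHM, starting with RHM) interleaved with 9 rest blocks, each 11
TRs of 2.6 s (28.6 s), 187 TRs in total. Six regions are carried per
participant: left/right M1 and the left/right spinal hemicord (SHc) at two
segmental levels — C7–Th1, where the hand motoneurons sit, and C5, a
control level expected to carry no task signal.

One protocol ambiguity deserves note: the movement bout itself is shorter
than the modelled block (≈11 s of tapping inside a ≈28.6 s epoch as
commonly described for such designs), and different stages of the original
style of analysis use slightly different effective task durations. We use a
single convention — task block = 11 TRs = 28.6 s — for the boxcar, the
block averaging and the generator, and expose the block length as a
parameter.

## Synthetic cohort generator

The generator (`cohort.simulate_cohort`) is the ground-truth world every
downstream stage is tested against. Per participant and hand `h` (with `c`
the contralateral and `i` the ipsilateral hemisphere):

* clean M1 drives: `M1(t) = a_contra·d_h(t) + a_ipsi·d_h'(t)`, where `d` is
  the hand's boxcar convolved with a canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, peak:undershoot 6:1, 32 s support, sampled at the TR,
  normalised to unit sum so a boxcar of height 1 produces a plateau near 1);
* ipsilateral C7–Th1 hemicord:
  `SHc(t) = w_dc·M1c(t) + w_di·M1i(t) + w_ind·g(M1c, M1i)(t)`, with the
  indirect-pathway drive `g` defaulting to the elementwise product of the
  two clean M1 series ("multiplication of influences"); sum- and
  single-hemisphere-gated variants are selectable;
* C5 hemicords: noise only;
* i.i.d. Gaussian noise everywhere (default SD 0.3 in the same units as the
  unit M1 amplitude), optional sinusoidal physiological noise on the spinal
  rows (off by default), and six random-walk motion-confound series for
  interface completeness.

Default population parameters, chosen once as a realistic regime and used
by all recovery experiments: `a_contra ~ N(1.0, 0.2)` folded positive,
`a_ipsi ~ N(−0.1, 0.15)` (near zero, slightly negative, with genuine
participant spread — the regime in which ipsilateral M1 shows no group-level
activation), `w_dc ~ |N(0.8, 0.2)|`, `w_di ~ |N(0.3, 0.15)|`,
`w_ind ~ −|N(−0.5, 0.2)|`, noise SD 0.3, cohort size 13.

Edinburgh Handedness Inventory (EHI) scores are generated as a linear map
of one chosen ground-truth weight (default: the RHM direct-contralateral
weight) plus Gaussian noise scaled to a target population correlation
(default 0.7), with marginal mean 84 and SD 13.4 before clipping to
[−100, 100]. Clipping truncates the upper tail slightly, pulling the
realised mean a few points below 84; correlation targets are specified
before clipping.

What the generator does **not** emulate: spatially structured physiological
noise (CSF pulsation, ghosting), motion-correlated signal, serial
correlation of the noise (an AR(1) prewhitening hook exists but the
generator's noise is white), task-correlated motion, and nonstationary
coupling. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
artifact of real spinal fMRI.

## Region-level GLM and derived series

`prep.fit_glm` regresses each region's series on HRF-convolved RHM and LHM
boxcars plus nuisance regressors — optional motion confounds, a
discrete-cosine drift basis with a 128 s cutoff, and an intercept — after
discarding the first 8 volumes (T1 equilibration). Betas are the OLS
solution; with 187 TRs and ≤ 16 columns the problem is tiny and solved by
`numpy.linalg.lstsq`.

`prep.block_mean_series` builds the 11-point condition series: task blocks
of one hand (or, for rest, the rest block immediately preceding each task
block of that hand — the pairing the protocol leaves open) aligned by
within-block index and averaged across the four blocks.

Because signal variance differs grossly between cortex and cord, series are
standardised per region before connectivity analysis. Order matters and is
configurable: the default averages raw blocks first, then z-scores each
region by the pooled mean/SD of its four condition series; the alternative
z-scores the full run first and then averages. Either way a region is
standardised *once* over a window larger than any single condition, so
within-window regression slopes and correlations remain distinct
quantities (a slope on same-window z-scored series would trivially equal
the correlation).

## Connectivity

Effective connectivity is the slope of the within-participant least-squares
regression of ipsilateral SHc activity on M1 activity (M1 explanatory, SHc
response) over the 11-point condition series; functional connectivity is
the Pearson correlation of the same series. Task-vs-rest changes are tested
across participants with the two-tailed Wilcoxon signed-rank test on
within-participant differences; raw r is compared (the test is rank-based,
so a Fisher transform would not change it, but it is available).

The dependency of the ipsilateral-M1→SHc effective connectivity on
contralateral M1 activity is a Pearson correlation across participants
between the contralateral M1 beta and the ipsilateral task slope. In the
generator this dependency emerges as a second-order consequence of the
multiplicative indirect drive (the ipsilateral slope absorbs
`w_ind · a_contra`), and it is weak at realistic noise; the test suite
probes its direction under a clearly expressed indirect pathway rather than
asserting a large effect.

## Statistical kernels

* **Wilcoxon signed-rank** — exact two-tailed p for n ≤ 20 by dynamic
  programming over doubled midranks (ties handled exactly, equivalent to
  enumerating all 2ⁿ sign patterns); normal approximation with continuity
  and tie correction above. Zero differences dropped by Wilcoxon's
  convention (`pratt` available).
* **Three-way repeated-measures ANOVA** — fully-crossed within-subject
  decomposition by inclusion–exclusion over marginal means; every effect is
  tested against its own effect-by-subject interaction mean square. With
  2-level factors each effect has df (1, n−1) and F equals the squared
  paired t of its contrast, which the tests verify. Sphericity corrections
  are unnecessary for 2-level factors and omitted.
* **Holm–Bonferroni** — standard step-down with monotonicity enforcement.
* **OLS metrics** — R²; adjusted R² = 1 − (1−R²)(n−1)/(n−k−1) with k
  non-intercept terms; Gaussian-likelihood criteria counting the intercept
  and the noise variance as parameters: AIC = n·ln(RSS/n) + 2(k+2), BIC
  with a ln(n) penalty. AIC/BIC comparisons are valid only within this one
  convention, which every model in the package uses.

## Group network models

For one hand, each participant contributes four factors — the contralateral
and ipsilateral M1 betas and the two task effective-connectivity slopes
onto the ipsilateral C7–Th1 hemicord — and the response, the ipsilateral
SHc beta. Terms are products of factors:

| term | product | network |
| --- | --- | --- |
| single_contra | slope_c · β_c | direct, contralateral |
| single_ipsi | slope_i · β_i | direct, ipsilateral |
| interaction_contra | slope_c · slope_i · β_c | indirect, contra-modulated |
| interaction_ipsi | slope_c · slope_i · β_i | indirect, ipsi-modulated |

Model 1 ("full") carries all four terms; model 2 the two single terms. The
activity family replaces connectivity products with the M1 betas and their
product (four variants). Columns and response are z-scored across
participants before fitting — R², adjusted R² and the model F-test are
invariant to this, which the tests assert. The exact functional forms are a
reconstruction from the verbal description of the modelling approach
(interaction = multiplication of the two connectivities, modulated by one
M1's activity); every term is spec-driven, so alternative reconstructions
are a one-line config change.

### Swap bootstrap

The model-1 vs model-2 comparison statistic is ΔR² ("δ"). The null is built
by permuting, with two independent permutations per iteration, the activity
rows and the slope rows across participants, leaving the response in place,
then rebuilding the terms and refitting both models. Two design choices
were settled by calibration measurements rather than taken on faith:

1. **Swap scope.** Swapping only within a random half of the cohort per
   iteration (one reading of "choosing arbitrary participants") makes the
   null draws positively correlated with the observed statistic and the
   test badly conservative (measured null rejection ≈ 0.01 at nominal
   0.05). The default therefore permutes the whole cohort every iteration,
   which makes the procedure an exact randomisation test; the subset
   variant is kept behind `subset="random"`.
2. **Interval.** Significance is "outside the 2.5–97.5 percentile band" of
   the null ΔR², with the observed value included in the null set (the
   standard randomisation correction). Measured null rejection: 0.052 over
   600 null cohorts × 500 iterations.

### Group-level summary generator

Model-recovery and calibration experiments need cohorts generated *under*
the group model, which is defined on per-participant summary quantities,
not time series. (Cohorts generated at the time-series level cannot serve:
the per-participant standardisation that the connectivity analysis
requires introduces 1/SD scale factors into the slope terms that absorb
much of the response signal, so no setting of the time-series generator
makes model 1 separate cleanly from model 2 — an instructive property of
the mean-series weights documented below.) `simulate_group_summary` draws
factors from realistic marginals (β_c ~ N(1, 0.2), β_i ~ N(−0.1, 0.15),
slope_c ~ N(0.8, 0.2), slope_i ~ N(−0.3, 0.3)) and builds the response as
a linear combination of z-scored terms plus Gaussian noise. Defaults are
an interaction-dominant, mid-SNR regime — coefficients (0.2, 0.1, −0.8,
−0.6), noise SD 0.6, giving full-model R² ≈ 0.7 and direct-only R² ≈ 0.3,
the qualitative regime the group analysis is designed to detect; the
direct-only world uses (0.5, 0.3) and no interactions.

## Individual sign-constrained weights

The per-participant full model explains ipsilateral SHc activity with three
network regressors under the biologically motivated constraints
w_direct_contra ≥ 0, w_direct_ipsi ≥ 0, w_indirect ≤ 0, plus a free
intercept, minimising RSS. The problem is convex bounded least squares,
solved with BVLS (`scipy.optimize.lsq_linear`); the global optimum equals
unconstrained OLS whenever that is feasible, and bound-pinned weights are
reported as exactly 0 with a flag. Tests verify agreement with an
exhaustive active-set oracle (all 2³ sign supports).

Two regressor bases:

* **Mean-series basis** (the connectivity-style analysis): 11-point
  z-scored task series with columns slope_c·M1c(t), slope_i·M1i(t),
  slope_c·slope_i·mod(t); the modulator defaults to the elementwise M1
  product (`contra`, `ipsi`, `sum` selectable, and the single-indirect-term
  layout is the default with a two-term variant reachable through the
  group specs). These weights inherit participant-specific slope and
  z-scale factors, so they are comparable within participant but only
  loosely across participants.
* **Run-level drive basis** (`fit_run_level_weights`): clean M1 series are
  reconstructed from the GLM betas times the HRF-convolved boxcars and the
  full-run SHc series is regressed on them. This puts weights on the
  generator's scale: noiseless cohorts are recovered to machine precision,
  and it is the basis used for recovery and EHI-correlation experiments.

**Contribution-scale normalisation.** Under realistic conditions the
ipsilateral M1 amplitude is near zero, so the indirect product regressor is
small and nearly collinear with the ipsilateral one; the information bound
on the raw indirect weight is wide (OLS SE ≈ 1.4 at noise SD 0.3) no matter
the estimator. Recovery accuracy is therefore assessed on the per-timepoint
contribution scale — each weight error multiplied by the RMS of its clean
generative regressor (`generative_regressor_rms`) — on which the three
networks are commensurable. Measured mean absolute errors under the default
conditions (100 cohorts of 13): ≈ 0.065, 0.060, 0.081 for the
direct-contra, direct-ipsi and indirect weights.

EHI correlations are Pearson r per weight term, reported uncorrected with
Holm adjustment optional. With the generator coupling the RHM
direct-contra weight to EHI at r = 0.7, the median recovered correlation
across 300 cohorts of 13 is ≈ 0.55 — attenuated from 0.7 exactly as
small-sample estimation noise in the weights predicts.

## Activation analysis

The 2×2×2 within-subject ANOVA takes factors HAND (RHM/LHM), SEGMENT
(C5/C7–Th1) and SIDE (contra/ipsi, resolved per hand from the anatomical
labels at call time — labels stay anatomical in storage to avoid
double-flip bugs). The posthoc family defaults to the six paired contrasts
of scientific interest (segment within side×hand, side within hand at
C7–Th1), Holm-adjusted; the family is configurable since the choice of
family is an analysis decision, not a mathematical one. The ipsilateral-M1
deactivation asymmetry is a paired t between hands.

## Orchestration and determinism

`run_pipeline` chains simulate → prep → connectivity → activation → group
models → weights, writes every intermediate table as TSV plus a sorted-key
JSON report, and derives every random stream from the single config seed
(participant streams via `SeedSequence.spawn`). Reports contain package
versions and the config but no timestamps, so a rerun with the same config
is byte-identical — asserted by the tests. Any stage failure aborts with
the stage name attached.

Problem sizes used by the verification experiments (chosen to make the
Monte-Carlo error small relative to each acceptance band): 100 random
instances per solver oracle; exhaustive enumeration to n = 12 for the
Wilcoxon check; 20 random tables for the ANOVA check; 100 cohorts of 13
for weight recovery; 200 replicates per model-recovery condition; 600 null
cohorts × 500 iterations for bootstrap calibration; 300 + 500 cohorts for
the EHI analyses.

## Known limitations

* The network-term functional forms are a reconstruction (see above); the
  package treats them as configuration, not truth.
* The mean-series weights are scale-entangled across
  participants; cross-participant claims should use the run-level basis.
* The EC-vs-contralateral-activity dependency is weak in the generator's
  world; the package measures it but the generator is not designed to
  reproduce any particular effect size for it.
* No voxel-level modelling, spatial preprocessing, ICA denoising or
  family-wise-error inference: inputs are region-level series by design.
* AR(1) noise modelling is not applied by default; with white generator
  noise it is unnecessary, with real data it may not be.
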