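# corticospinal

Network modelling of simultaneous primary motor cortex (M1) + cervical
spinal cord fMRI.

Humans control unilateral hand movement through two corticospinal routes: a
*direct* network carrying influence from the contralateral M1 onto the
spinal motoneurons, and an *indirect* network integrating influence from
both M1s through multi-synaptic relays. This package implements, as a
tested and reusable pipeline, the analysis chain needed to study how those
two networks share the work and how their balance relates to handedness:

* **Effective / functional connectivity** — per participant, the slope of
  the regression of spinal hemicord (SHc) activity on M1 activity over
  block-averaged 11-point task and rest windows (effective connectivity,
  an input–output estimate), and the Pearson correlation of the same
  series (functional connectivity), compared task-vs-rest with the exact
  Wilcoxon signed-rank test.
* **Group network models** — across participants, ipsilateral SHc activity
  β<sub>SHc</sub> is modelled from products of activity and connectivity:
  single terms `slope_c·β_c` and `slope_i·β_i` for the two direct networks,
  and interaction terms `slope_c·slope_i·β_{c|i}` (the multiplication of
  the two connectivities, modulated by one M1's activity) for the indirect
  network. The full model (singles + interactions) is compared with the
  direct-only model on adjusted R², AIC/BIC, and a swap-bootstrap null for
  ΔR² in which activity rows and slope rows are independently permuted
  across participants.
* **Individual weights** — per participant and hand, a sign-constrained
  least-squares fit (w_direct ≥ 0, w_indirect ≤ 0, convex, solved to the
  global optimum) of the three-network model, and the correlation of those
  weights with the Edinburgh Handedness Inventory (EHI) score.
* **Activation statistics** — 2×2×2 within-subject ANOVA on SHc betas
  (HAND × SEGMENT × SIDE) with Holm–Bonferroni posthoc paired tests.
* **Synthetic cohorts with ground truth** — a block-design BOLD generator
  (HRF-convolved boxcars, direct/indirect coupling with known weights,
  C5 control level, EHI coupled to a chosen weight) so every stage is
  testable end to end without any external data.

Statistical kernels (exact Wilcoxon, within-subject three-way ANOVA,
Holm–Bonferroni, OLS metrics with a fixed AIC/BIC convention) are
implemented in `corticospinal.stats` and verified against independent
oracles. See `docs/methods.md` for the full model description, parameter
defaults and numerical choices.

## Worked example

```python
import corticospinal as cs

cohort = cs.simulate_cohort(seed=4)          # 13 participants, known truth
betas = cs.cohort_betas(cohort)              # region-level GLM betas
est = cs.cohort_connectivity(cohort)         # slopes + correlations

# task-induced change in contralateral M1 -> ipsilateral SHc coupling (LHM)
res = cs.compare_task_rest(est, "LHM", source_role="contra")
print(f"W = {res.value}, p = {res.p:.6f}, n = {res.n}")

# group network models for left-hand movement
summary = cs.hand_summary_table(betas, est, "LHM")
print(cs.fit_group_model(cs.MODEL_FULL, summary).summary())

comp = cs.bootstrap_compare(cs.MODEL_FULL, cs.MODEL_DIRECT_ONLY, summary,
                            n_iterations=1000, seed=8)
print(f"delta R2 = {comp.observed_delta:.4f}, "
      f"null 95% CI = [{comp.ci_low:.4f}, {comp.ci_high:.4f}]")

# individual weights vs handedness
w = cs.cohort_run_level_weights(cohort, hands=("RHM",))
print(cs.correlate_weights_ehi(w, cohort.metadata, "RHM").to_string(index=False))
```

prints

```
W = 88.0, p = 0.001221, n = 13
Group network model: model1 (connectivity family)
  n = 13 participants, 4 terms
  R2 = 0.6452  adj. R2 = 0.4679  AIC = -2.51  BIC = 0.88
  F(4, 8) = 3.638, p = 0.0567
  coefficients:
    const                  -0.0000  (se 0.2023)
    single_contra          +0.8171  (se 0.3024)
    single_ipsi            +0.6194  (se 0.9258)
    interaction_contra     +0.2013  (se 0.4104)
    interaction_ipsi       -0.4276  (se 1.0388)
delta R2 = 0.0295, null 95% CI = [0.0046, 0.5216]
hand            term         r        p  n
 RHM w_direct_contra  0.589225 0.034085 13
 RHM   w_direct_ipsi -0.019953 0.948414 13
 RHM      w_indirect  0.067984 0.825346 13
```

Reading the output: the contralateral M1→SHc effective connectivity rises
significantly during left-hand movement relative to rest (Wilcoxon
W = 88, p ≈ 0.001 across the 13 participants); the full network model
explains 65% of the between-participant variance in spinal activity
(adjusted R² 0.47, F-test p 0.057); in this particular cohort the
interaction terms' ΔR² of 0.03 stays inside the swap-null band, so the
indirect network is not demanded by the group fit; and the EHI score
correlates with the direct contralateral weight during right-hand movement
(r = 0.59, p = 0.034) — the generator couples them at r = 0.7, attenuated
here by small-sample weight-estimation noise.

## Command line

A thin CLI mirrors the pipeline stages:

```bash
corticospinal simulate --seed 7 --out out/          # cohort tables (TSV + JSON truth)
corticospinal run --seed 7 --out out/               # full pipeline -> report.json
corticospinal model-fit --betas out/betas.tsv \
    --connectivity out/connectivity.tsv --hand LHM --boot 10000 --seed 7 \
    --out out/models.json
```

All tables are plain TSV; `report.json` is sorted-key JSON, and a rerun
with the same config and seed is byte-identical. `ingest-deposited` maps
user-supplied external verification tables (EHI, betas, slopes) onto the
internal schema; it never touches the network.

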