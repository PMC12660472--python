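# mednf

Analysis pipeline for intermittent fMRI neurofeedback (NF) studies of
focused-attention meditation, built around three computational stages and a
synthetic-data generator that makes every stage testable without scanner data:

1. **Real-time NF scoring engine** (`mednf.nf`). A streaming ("incremental")
   general linear model — intercept, linear trend, HRF-convolved meditation
   regressor — is updated volume by volume over the target region (posterior
   cingulate cortex, PCC) and a physiological confound region. After each
   26-s meditation block the engine selects the 33% of target voxels with the
   most negative meditation-vs-rest *t* statistic, computes their percent
   signal change (PSC) against the cumulative rest baseline, residualizes it
   against the confound-ROI PSC (cumulative least squares), averages the
   residual over the haemodynamically shifted block window, and maps the
   score onto a 20-level thermometer (higher bar = deeper PCC deactivation).
   Yoked-sham mode replays a matched donor's stored scores verbatim while the
   recipient's own scores are still computed and logged for blinding checks.
2. **Offline inference** (`mednf.offline`). Voxel-wise block GLM activation
   (meditation − rest contrast in PSC units), generalized psychophysiological
   interaction (gPPI) estimation of condition-dependent seed coupling
   (γ = β[seed × meditation] − β[seed × rest]), a max-statistic cluster-level
   permutation test for group differences (cluster-forming p < 0.005, FWE
   α = 0.05, 6-neighbour connectivity, cluster-mass statistic), and
   baseline-to-transfer Pearson functional-connectivity change scores.
3. **Behavioural endpoints** (`mednf.behavior`). The five-test battery:
   State-Mindfulness (SMS) Mind and Body slopes over six session days after
   pooled covariate residualization (pre-score, sleepiness, age, sex), DASS-21
   and breath-counting-task (BCT) difference-score ANCOVAs with age/sex
   covariates, and a Wilcoxon rank-sum for the discrete BCT probe accuracy
   (exact enumeration for combined n ≤ 12). Raw p-values are
   Benjamini–Hochberg adjusted across the five tests; t statistics convert to
   Cohen's d via d = t·√(1/n₁ + 1/n₂). Partial correlations (residual method,
   df = n − 2 − k) and one-sample t-tests support brain–behaviour follow-ups.

`mednf.synthetic` generates the inputs: blocked NF runs (three 51-s rest and
six 26-s meditation blocks per 10-min run at TR = 0.8 s) with HRF-convolved
target deactivation, slow drift, a shared physiological component and thermal
noise; and behavioural cohorts (default 19/group) with configurable
group×time SMS slopes, DASS change distributions, BCT effects, and a
within-group correlation between seed-coupling betas and distress change.

## Worked example

```python
from mednf import nf, synthetic
from mednf.design import AcquisitionParams, make_block_design

acq = AcquisitionParams()                 # TR 0.8 s, 600 s runs -> 750 volumes
design = make_block_design(acq)           # 3 rest + 6 meditation (+cue/feedback)
truth = synthetic.GroundTruth(target_deactivation_pct=-0.5, seed=1)
run = synthetic.simulate_roi_run(design, acq, truth, 30, 30)
scores, log = nf.run_nf_session([run], nf.NfConfig())
print(log)
```

```
   run  block   raw_psc  residual_psc  level  displayed_level  n_selected
0    0      0 -0.728931     -0.410205      9                9           9
1    0      1 -0.414463     -0.342365      8                8           9
2    0      2 -0.468194     -0.350758      8                8           9
3    0      3 -0.336488     -0.345129      8                8           9
4    0      4 -0.715925     -0.433681      9                9           9
5    0      5 -0.524082     -0.453860     10               10           9
```

Each row is one meditation block: the raw selected-voxel PSC (%), the
confound-residualized score, and the thermometer level shown to the
participant (level 8–10 here ≈ 0.34–0.45% deactivation on the default 0 to
−1% display range). `n_selected` is ⌊0.33 × 30⌋ = 9 voxels.

The same stages run from the shell:

```bash
mednf simulate --out results/sim --seed 1
mednf nf-run --target results/sim/run_target.nii.gz \
             --confound results/sim/run_confound.nii.gz \
             --target-mask results/sim/run_target_mask.nii.gz \
             --confound-mask results/sim/run_confound_mask.nii.gz \
             --events results/sim/run_events.tsv --mode veridical
mednf behavior --cohort results/sim/cohort.csv
mednf pipeline --seed 1 --out results/pipeline   # everything, end to end
```

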