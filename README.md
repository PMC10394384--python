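# neurofactor

Patch-based 3D deep-learning regression of depression-symptom factor scores
from structural MRI, with ranking of brain regions by predictive
informativeness.

## The problem

In late-life depression, symptom phenotypes can be summarized as five
standardized factor scores per patient — Anhedonia, Suicidality, Appetite,
Sleep Disturbance, Anxiety — derived from clinician-rated scales by factor
analysis. `neurofactor` asks which brain regions' local morphology in a
T1-weighted MRI predicts each factor, using a sample-efficient patch-based
strategy suited to modest clinical cohorts (~10² subjects):

1. **ROI patch sampling.** From each of M a-priori regions of interest
   (lateralized limbic/prefrontal regions of an AAL-style atlas, organized
   into testing sets), draw I = 5 random 32³ patch centers inside the ROI
   mask, subject to a pairwise overlap cap that grows linearly from 50% for
   the smallest ROI to 75% for the largest (up to 20,000 candidate draws,
   then stepwise cap relaxation). Patches may extend past the ROI but never
   past the volume; intensities are z-scored per volume.
2. **3D-ResNet-12 regression.** A 12-convolution residual network (stem
   conv + five basic blocks of two 3×3×3 convs + a final 1³ conv, each conv
   followed by batch norm and ReLU, parameter-free shortcuts, global average
   pooling, linear scalar head) maps one patch `x` to one score estimate
   `ŷ_patch = Φ(x)`. One network per factor; every patch of a subject is
   labeled with that subject's factor score; training minimizes
   `L = ‖y − ŷ‖₂²/n` with Adam (batch 1000, initial lr 0.001).
3. **Hierarchical aggregation under 10-fold CV.** Subject-level 10-fold
   cross-validation (all patches of a subject on one side of each split);
   `ŷ_ROI = mean_i ŷ_patch,i`, `ŷ_subject = mean_m ŷ_ROI,m`.
4. **Evaluation.** Pooled over (subject, ROI) pairs: Pearson r with its
   t-transform p; a robust straight-line fit by iteratively reweighted least
   squares (IRLS), iterating weights `w_i² = max(|e_i|, ε)^(p−2)` so the
   p-norm objective `Σ|e_i|^p` is minimized by repeated weighted 2-norm
   solves (p = 2 reduces exactly to OLS); the chi-square formula
   `Σ(O−E)²/E` with an upper-tail p; and per-ROI **median MSE** of the
   ROI-level estimates — lower median = more informative region — with the
   five smallest forming the per-factor ROI ranking.

Clinical cohorts of this kind are not publicly deposited, so the package
ships a first-class synthetic-cohort generator: phantom atlases of
non-overlapping ellipsoidal ROIs, standardized orthogonal factor scores,
and intensity volumes in which designated ROIs carry a linear
score-dependent signal on top of a brain-like radial baseline and Gaussian
noise. The generator's ground truth makes full-pipeline recovery testable.

## Worked example

Run the desk-scale end-to-end experiment (40 subjects, 64³ phantom volumes,
6 ROIs, one planted intensity effect of 2 intensity units per score SD in
ROI `R01` on the Anxiety factor, 10-fold CV, quarter-width network):

```bash
neurofactor run-all --seed 1 --factors Anxiety --out out/
```

which prints (about half a minute on one CPU):

```
Anxiety: r=0.1575 p=0.0146 t=67.820 top5=R01,R04,R06,R02,R03
artifacts in out/
```

Reading: the pooled (subject, ROI) correlation between estimated and true
Anxiety scores is r = 0.157 (p = 0.015, n = 240 pairs), and the planted
signal region `R01` ranks first by median MSE (0.147 vs 0.40–0.60 for the
five null ROIs) — the pipeline recovers which region carries the signal.
The robust-regression t is large because the L1 fit tracks the dense null
bulk with a small weighted standard error. `out/` contains tidy prediction
tables (`predictions_Anxiety.csv`), per-factor report JSONs, a statistics
CSV and the factor × rank-1..5 ROI table (`roi_ranking.txt`).

The same stages are scriptable: `simulate`, `extract`, `train-cv`,
`evaluate`, `report`, or from Python via
`neurofactor.run_experiment(ExperimentConfig(...))`. Estimators follow the
scikit-learn protocol (`PatchRegressor3D`, `IRLSRegression`:
`fit`/`predict`/`get_params`).

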