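# mosaicmap

Normative, patch-wise cortical-thickness statistics for tracking focal
atrophy, and everything needed to evaluate them: a synthetic-cohort
generator with planted ground truth, domain-specific region-of-interest
(ROI) restriction, baseline clinical association models, progressor
dichotomization with signed-rank testing, and SVM-based progression
classification.

## The problem and the statistic

Group-level cortical-thickness analyses wash out the focal, spatially
heterogeneous atrophy seen in individual patients with neurodegenerative
disease. `mosaicmap` instead scores **each patient individually** against a
personally matched healthy reference:

1. The cortical surface is divided into ~1000 equal-area **patches**
   (500 per hemisphere). Each subject is a vector of mean patch
   thicknesses (mm).
2. For a patient of sex *s* and age *a*, the reference is every normative
   subject with the same sex and age within ±2 years (inclusive).
3. Per patch *j*, the patient's thickness x_j is standardized against the
   reference (z_j, sample SD) and converted to an **exact left-tail rank
   p-value**: with n reference values, the exhaustive, replacement-free
   permutation distribution of the patient's position among the n + 1
   exchangeable values gives

   p_j = (1 + #{reference values ≤ x_j}) / (n + 1).

4. A patch with p_j < 0.05 (strict) is **significantly thin**. The
   **thin-patch fraction (TPF)** — the proportion of thin patches within a
   patch set — is the scalar atrophy-burden statistic. It can be computed
   over the whole brain or **restricted** to a domain-specific patch set
   (e.g. 79 patches covering the extremity motor representation), the
   hypothesis being that domain-restricted TPF tracks the matching
   clinical function better than whole-brain TPF.

Downstream, the package fits OLS models `clinical score ~ TPF + age + sex
+ handedness + symptom duration`, compares restricted vs. whole-brain TPF
models by adjusted R², dichotomizes patients into progressors (any motor
score increase / any cognitive score decrease over 1 or 3 years; Wilcoxon
signed-rank V with exact enumeration up to n = 25), and trains RBF-SVM
classifiers (80/20 split, 79 features, fivefold-CV grid search) that
predict progression from baseline patch z-scores.

Because the clinical datasets this design targets are access-restricted,
the package ships a **synthetic-cohort generator** that plants the assumed
structure — ROI-confined atrophy proportional to a latent severity that
drives the extremity motor score and its progression — so every stage is
testable against known truth.

## Worked example

```python
from mosaicmap import (GeneratorConfig, MosaicNormativeScorer,
                       fit_tpf_model, compare_by_adjusted_r2, generate_study)

config = GeneratorConfig(seed=42)          # 650 controls, 135 patients, 1000 patches
study = generate_study(config)
roi = config.resolved_roi()                # the 79-patch extremity set

scorer = MosaicNormativeScorer(age_window=2.0, alpha=0.05)
scorer.fit(study.normative.thickness, study.normative.demographics)
stats = scorer.score_patients(study.patient_thickness, study.patient_demographics)

tpf = scorer.tpf_table(stats, {"restricted": roi, "wholebrain": None})
print(tpf.groupby("patch_set")["tpf"].mean().round(4))

order = [s.patient_id for s in stats]
bl = (study.clinical.query("visit == 'BL'")
      .pivot_table(index="subject_id", columns="measure", values="value").loc[order])
wide = tpf.pivot_table(index="patient_id", columns="patch_set", values="tpf").loc[order]

fit_r = fit_tpf_model(bl["extremity"].to_numpy(), wide["restricted"].to_numpy(),
                      study.patient_demographics, outcome_name="extremity")
fit_w = fit_tpf_model(bl["extremity"].to_numpy(), wide["wholebrain"].to_numpy(),
                      study.patient_demographics, outcome_name="extremity")
cmp = compare_by_adjusted_r2(fit_r, fit_w)
print(f"restricted:   R2_adj = {fit_r.r2_adjusted:.3f}, p(TPF) = {fit_r.tpf_p_value:.2e}")
print(f"whole-brain:  R2_adj = {fit_w.r2_adjusted:.3f}, p(TPF) = {fit_w.tpf_p_value:.2e}")
print("winner:", cmp.winner)
```

Output:

```
patch_set
restricted    0.1634
wholebrain    0.0407
Name: tpf, dtype: float64
restricted:   R2_adj = 0.482, p(TPF) = 1.52e-19
whole-brain:  R2_adj = 0.081, p(TPF) = 3.08e-03
winner: restricted
```

Reading it: patients carry, on average, 16.3% thin patches inside the
extremity ROI (where atrophy was planted) against 4.1% across the whole
brain — close to the ~4.5% null rate implied by the discrete rank p-value,
since 921 of 1000 patches carry no signal. Restricting the TPF to the ROI
concentrates the signal, so the restricted model explains far more
variance in the extremity motor score (adjusted R² 0.48 vs. 0.08) and
wins the comparison.

The same steps are available from the shell:

```bash
mosaicmap simulate --out sim --seed 42
mosaicmap map --patients sim/patient_thickness.csv \
              --patients-demo sim/patient_demographics.csv \
              --normative sim/normative_thickness.csv \
              --demo sim/normative_demographics.csv --out stats
mosaicmap tpf --stats stats/patch_stats.csv --patchset extremity.txt --out tpf.csv
mosaicmap pipeline --out run1 --seed 42     # the full pipeline + manifest
```

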