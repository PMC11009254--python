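# tractclass

Classification of eye disease from white-matter tract profiles: a tested,
reusable pipeline for tractometry case/control studies, driven by a
synthetic-cohort generator.

## The problem

Diseases of the retina (glaucoma, age-related macular degeneration)
deprive downstream visual pathways of input. Whether that leaves a
measurable signature in the brain's white matter is asked with a
classification design: extract *tract profiles* — a tissue property
(fractional anisotropy FA, mean diffusivity MD, mean kurtosis MK) sampled
at 100 nodes along a bundle's core — for the optic radiations (OR, the
visual pathway of interest) and two non-visual control bundles
(corticospinal tract CST, uncinate fasciculus UNC), and train one
classifier per bundle to predict disease status in held-out subjects. If
disease information is specific to the visual pathway, the OR classifier
should beat the control bundles, whose AUCs should sit inside a chance
band.

Because disease correlates with age and demographics, cases are first
matched to controls by **minimum-total-Mahalanobis-distance assignment**:
solve the rectangular linear assignment problem on the case × control
distance matrix over confounders (age, sex, ethnicity, Townsend
deprivation index), using the pooled covariance metric, then keep pairs
with distance ≤ 0.3. Matched pairs move through 64/16/20
train/validation/test splits *in tandem*.

Per bundle, two models are fitted on the middle 80 profile nodes × 6
channels (3 properties × 2 hemispheres):

- a **1D residual CNN** — three residual blocks with kernel sizes 8/5/3
  and 64/128/128 filters, batch norm + ReLU, global average pooling,
  sigmoid output (implemented in numpy with hand-written backprop; no
  deep-learning framework required);
- an **L2 logistic baseline** on every other node from the 20th to 78th
  (30 nodes × 6 channels = 180 features), with the penalty chosen on the
  validation split.

Inference is AUC-based with the **DeLong** machinery: the AUC is the
Mann–Whitney statistic U/(n₊·n₋) with variance
var(V₁₀)/n₊ + var(V₀₁)/n₋ from placement values; models scored on the
same subjects are compared with the paired DeLong test (FDR-corrected
across bundle comparisons); per-bundle AUCs are screened against 0.5 with
Bonferroni-corrected confidence intervals. Frozen models are also applied
across tasks (disease model → second-disease and age-gap datasets; age
model → disease datasets) to test whether the learned signature
generalizes.

Real cohorts of this kind are access-restricted, so the package ships a
first-class synthetic-cohort module that emulates the statistical
structure of the problem — the age confound (cases 68 ± 7 vs controls
62 ± 7 years), OR-specific group effects in the 0.2–0.4 SD range over
heavily overlapping distributions, and realistic bundle missingness —
plus synthetic streamline scenes for the bundle-recognition primitives.
The full analysis runs end to end with no download; on real data, the
same functions consume the same `subjects.csv` / `profiles.csv` formats.

## Worked example

```python
import numpy as np
from tractclass import (generate_subjects, match_cohorts, split_tandem,
                        EffectConfig, generate_profiles)

subjects = generate_subjects(n_case=300, n_control=1800, seed=0)
cases = subjects[subjects.label == "case"]        # ages ≈ 68 ± 7
controls = subjects[subjects.label == "control"]  # ages ≈ 62 ± 7

pairs = match_cohorts(cases, controls, threshold=0.3)
age = subjects.set_index("id").age
print(len(pairs), round(age.loc[pairs.case_id].mean(), 1),
      round(age.loc[pairs.control_id].mean(), 1))
```

prints

```
245 67.3 67.1
```

— 245 of 300 cases found a control within the 0.3 threshold, and the
six-year age confound has collapsed to 0.2 years. Continuing through the
full pipeline (`examples/04_train_classifiers.py`, ~300 pairs, one CPU):

```
CNN: 4 epochs, OR test AUC 0.642
logistic: C = 100, OR test AUC 0.729
```

Both models detect the weak OR signal; control bundles stay at chance.
The `examples/` directory holds one short script per capability
(cohort generation, matching, bundle recognition from streamline scenes,
classifier training, correlated-ROC inference, and the full experiment);
the experiment is also runnable from the shell:

```sh
tractclass run --out runs/demo --seed 0
tractclass report --run-dir runs/demo
```

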