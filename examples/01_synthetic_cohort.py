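"""Generate a synthetic case/control cohort with tract profiles.

Builds a small age-confounded cohort (cases are ~6 years older on
average), attaches tract profiles in which only the optic radiations carry
a group effect, and knocks out whole bundles at realistic rates.
"""

import numpy as np

from tractclass import EffectConfig, generate_profiles, generate_subjects, \
    inject_missingness
from tractclass.cohort import NODE_COLUMNS

subjects = generate_subjects(n_case=200, n_control=800, seed=0)
print(f"{len(subjects)} subjects; "
      f"case age {subjects[subjects.label == 'case'].age.mean():.1f} ± "
      f"{subjects[subjects.label == 'case'].age.std():.1f}, "
      f"control age {subjects[subjects.label == 'control'].age.mean():.1f} ± "
      f"{subjects[subjects.label == 'control'].age.std():.1f}")

effects = EffectConfig()  # OR-only disease effect, study-like missingness
profiles = generate_profiles(subjects, effects, seed=1)
profiles = inject_missingness(profiles, effects, seed=2)

merged = profiles.merge(subjects[["id", "label"]], left_on="subject_id",
                        right_on="id")
for bundle in ("OR", "CST"):
    sel = merged[(merged.bundle == bundle) & (merged.tissue_property == "MK")
                 & (merged.hemisphere == "L") & ~merged.missing]
    case = sel[sel.label == "case"][NODE_COLUMNS].to_numpy().mean()
    ctrl = sel[sel.label == "control"][NODE_COLUMNS].to_numpy().mean()
    print(f"{bundle}: mean MK case {case:.4f} vs control {ctrl:.4f} "
          f"(difference {case - ctrl:+.4f})")

missing_or = profiles[(profiles.bundle == "OR")].groupby(
    ["subject_id", "hemisphere"]).missing.first().mean()
print(f"OR bundle missing in {100 * missing_or:.1f}% of hemispheres")
# Cases show lower mean kurtosis in the optic radiations only; the control
# bundle difference is sampling noise, and OR bundles go missing at a few
# percent, as bundle recognition does for this highly curved tract.
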