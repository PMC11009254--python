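"""Confound-matched case/control construction.

Matches each case to the control minimizing the total Mahalanobis
distance over (age, sex, ethnicity, TDI), prunes pairs above the 0.3
threshold, and splits the matched pairs 64/16/20 in tandem.
"""

from tractclass import generate_subjects, match_cohorts, split_tandem

subjects = generate_subjects(n_case=300, n_control=1800, seed=0)
cases = subjects[subjects.label == "case"]
controls = subjects[subjects.label == "control"]
print(f"before matching: case mean age {cases.age.mean():.1f}, "
      f"control mean age {controls.age.mean():.1f}")

pairs = match_cohorts(cases, controls, threshold=0.3)
age = subjects.set_index("id").age
print(f"{len(pairs)} matched pairs (of {len(cases)} cases); "
      f"matched case age {age.loc[pairs.case_id].mean():.1f}, "
      f"matched control age {age.loc[pairs.control_id].mean():.1f}; "
      f"max pair distance {pairs.distance.max():.3f}")

split = split_tandem(pairs, fractions=(0.64, 0.16, 0.20), seed=1)
print(split.split.value_counts().to_dict())
# The ~6-year age confound disappears after matching (a few cases go
# unmatched at the 0.3 threshold), and both members of each pair always
# land in the same train/validation/test split.
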