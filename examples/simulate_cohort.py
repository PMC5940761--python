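"""Generate a synthetic lesion/survival cohort and inspect its structure.

The generator links each patient's lesion texture (true mean attenuation and
heterogeneity) to disease-free survival through a known proportional-hazards
model, so the printed event fraction and covariate balance are design
choices, not accidents.
"""

import numpy as np

from texturesurv import SyntheticConfig, generate_cohort, records_to_frame

config = SyntheticConfig(n_patients=88, seed=42)
lesions, records = generate_cohort(config)
cohort = records_to_frame(records)

sizes = [lesion.roi_size for lesion in lesions]
means = [lesion.in_mask_values().mean() for lesion in lesions]

print(f"patients:               {len(cohort)}")
print(f"events (recurrence):    {cohort.event.sum()} "
      f"({100 * cohort.event.mean():.1f}%)")
print(f"node-positive:          {(cohort.nodal_status == 'positive').sum()}")
print(f"ROI pixels (median, range): {np.median(sizes):.0f} "
      f"({min(sizes)}-{max(sizes)})")
print(f"stored-intensity mean (median): {np.median(means):.1f} "
      "(HU + 1024 convention; ~1088 = 64 HU)")
print(f"follow-up months (min-max): {cohort.dfs_months.min():.1f}-"
      f"{cohort.dfs_months.max():.1f}")
# ~80% of patients recur; texture drives hazard through the known coefficients.
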