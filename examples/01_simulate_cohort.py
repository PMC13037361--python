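"""Generate a synthetic actigraphy cohort and look at its diurnal structure.

Builds a 2000-participant cohort with the default study conditions (10%
daytime attenuation for cases, July-peaked seasonality, BMI-linked
activity) and prints the group mean profiles at a few key hours.
"""

import numpy as np

from actikoa import SyntheticConfig, generate_population

config = SyntheticConfig(n_participants=2000, seed=1)
records = generate_population(config)

is_case = np.array([r.diagnosis_offset_years is not None for r in records])
profiles = np.array([r.profile for r in records])

print(f"cohort: {len(records)} participants, {is_case.sum()} KOA cases")
print(f"{'hour':>6} {'control mean':>14} {'case mean':>12}")
for hour in (3, 8, 10, 12, 16, 22):
    print(f"{hour:>6} {profiles[~is_case, hour].mean():>14.2f} "
          f"{profiles[is_case, hour].mean():>12.2f}")

# The nocturnal hours are indistinguishable between groups; during the
# attenuated daytime window (09:00-16:00) cases sit a few percent lower,
# the same subtle gap the classifier has to pick up.
months = np.array([r.month for r in records])
day = profiles[:, 9:17].mean(axis=1)
print(f"\nseasonality: July daytime mean {day[months == 7].mean():.1f} "
      f"vs January {day[months == 1].mean():.1f}")
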