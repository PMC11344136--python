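"""Simulate a small cohort's depth profiles and compute the local measures.

Generates a 60-parcel sphere and a 120-subject cohort, plants a sex effect
(Cohen's d = 0.4) on the profile mean of five parcels, and computes the
profile mean and skewness tables.
"""

import numpy as np

import profilespace as ps

geom = ps.make_sphere_parcellation(n_vertices=1000, n_parcels=60, seed=1)
cohort = ps.simulate_cohort(n_female=200, n_male=200, seed=2)

d_map = np.zeros(60)
d_map[[3, 11, 25, 40, 52]] = 0.4
effects = ps.GroundTruthEffects(d_map, np.zeros(60), np.zeros(60))
profiles = ps.simulate_profiles(geom, cohort, effects, n_depths=12, seed=3)

mean_t, skew_raw, skew_scaled = ps.profile_measures(profiles)
print(f"profiles: {profiles.values.shape} (subjects x parcels x depths)")
print(f"profile mean, subject 0, parcels 0-4: "
      f"{np.round(mean_t.to_array()[0, :5], 3)}")
print(f"scaled skewness range: [{skew_scaled.to_array().min():.2f}, "
      f"{skew_scaled.to_array().max():.2f}]  (min-max within subject)")

# the planted effect is recovered by the covariate-adjusted GLM
contrast = ps.fit_parcel_glm(mean_t.values, cohort)
print(f"estimated Cohen's d at planted parcels (true 0.4): "
      f"{np.round(contrast.cohen_d[[3, 11, 25, 40, 52]], 2)}")
print(f"mean |d| over unplanted parcels: "
      f"{np.abs(contrast.cohen_d[d_map == 0]).mean():.3f}")
print(f"FDR-significant parcels: "
      f"{sorted(np.flatnonzero(contrast.fdr_mask).tolist())}")
# The five planted parcels carry d-hat near 0.4 and are the ones passing
# FDR; unplanted parcels fluctuate around zero at the sampling-noise scale.
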