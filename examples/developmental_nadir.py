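"""Localize the transient developmental nadir of a synthetic cohort.

Generates a 70-pup cohort (7 per day, P5-P14) whose feature mean follows a
quadratic with vertex at postnatal day 8.5, selects the trajectory model by
LOOCV, and bootstraps the location of the first interior extremum within
each day against an across-day null.
"""

from spindlekit import bootstrap_nadir, fit_trajectory
from spindlekit.synth import CohortSpec, generate_cohort

spec = CohortSpec(
    ages=tuple(range(5, 15)),
    animals_per_age=7,
    coeffs=(1.0, -17.0, 80.0),  # vertex at 8.5
    noise_sd=9.0,  # 0.3 x the trajectory's range
)
cohort, true_nadir = generate_cohort(spec, seed=0)
best, candidates = fit_trajectory(cohort)
print(f"true nadir: P{true_nadir}; selected model: {best.family} degree {best.degree} "
      f"(LOOCV MSE {best.loocv_mse:.1f})")

nad = bootstrap_nadir(cohort, degree=2, n_boot=2000, seed=1)
print(f"{'age':>4} {'within':>7} {'null':>6}")
for age, w, nl in zip(nad.ages, nad.within_mass, nad.null_mass):
    print(f"{age:4.0f} {w:7.3f} {nl:6.3f}")
print(f"mode at P{nad.mode_age:.0f}; within/null mass ratio at mode: {nad.exceedance:.1f}")

# The within-day resampling concentrates the extremum-location mass at P8-9
# around the true vertex; the across-day null (age structure destroyed)
# spreads it, so a mode ratio well above 1 certifies a genuine interior nadir.
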