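"""The flexibility index and its use as an age marker.

Part 1 plants a regime-switching phase coupling (alpha1 vs beta3,
alternating every few seconds) and shows that the flexibility index — the
rate of coupling-mode label changes between consecutive windows — rises
with the switching rate.  Part 2 samples a 178-member cohort whose FI
follows a quadratic age curve, fits the five candidate model families,
and compares a reading-disability-like group against controls.
"""

import numpy as np

from dicmflex import (
    CohortPlan,
    CouplingEntry,
    CouplingPlan,
    compare_groups,
    fit_fi_age,
    gen_cohort,
    gen_switching_recording,
)
from dicmflex.aggregation import flexibility
from dicmflex.preprocessing import filterbank, make_windows
from dicmflex.surrogate_stats import dicm_pipeline

# --- Part 1: flexibility tracks the planted switching rate ---------------
modes = [
    CouplingPlan([CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9)]),
    CouplingPlan([CouplingEntry((0, 1), "iplv", "beta3", strength=0.9)]),
]
print("flexibility of the planted pair vs regime dwell time:")
for dwell in (12.0, 6.0, 3.0):
    rec = gen_switching_recording(2, 170.0, 24.0, modes, dwell_s=dwell, seed=5)
    tensor, _ = dicm_pipeline(filterbank(rec), make_windows(rec),
                              estimators=(2,), n_surr=200, seed=6)
    fi = flexibility(tensor)
    print(f"  dwell {dwell:4.0f}s -> FI = {fi.fi_pairs[0]:.3f}")
print("shorter dwell = more regime changes = higher FI\n")

# --- Part 2: cohort modeling ---------------------------------------------
cohort = gen_cohort(CohortPlan(n=178, n_features=0), seed=30)
fits = fit_fi_age(cohort["age"].to_numpy(), cohort["fi"].to_numpy(),
                  n_perm=500, seed=31)
print("FI-age model comparison (AIC, lower is better):")
for f in fits:
    print(f"  {f.family:<16} AIC={f.aic:8.1f}  r2={f.r2:.3f}")
best = fits[0]
a, b, c = best.params
print(f"winner: {best.family}; FI peaks near age {-b / (2 * a):.1f} years "
      f"(permutation p = {best.perm_p:.3g})\n")

rd = gen_cohort(CohortPlan(n=25, fi_offset=-0.1, group="RD", n_features=0,
                           age_sampler=lambda rng, size: rng.uniform(8, 16, size)),
                seed=32)
hp = gen_cohort(CohortPlan(n=25, n_features=0,
                           age_sampler=lambda rng, size: rng.uniform(8, 16, size)),
                seed=33)
stat, p = compare_groups(hp["fi"].to_numpy(), rd["fi"].to_numpy())
print(f"rank-sum test, controls vs FI-deficit group: U={stat:.0f}, "
      f"p={p:.2e}")
print("the planted 0.1 FI deficit is detected far below the 0.01 level")
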