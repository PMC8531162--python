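"""Fit a dose-response curve to Parameter Recovery versus concentration.

Simulates the dose-response assay — six concentrations from 0.0003 to 1 uM in
four replicates — for a compound whose planted potency is EC50 = 0.05 uM with
Hill slope 1, scores PR per well against control-vehicle boundaries, and fits
the four-parameter Hill model PR(c) = bottom + (top-bottom) c^h / (c^h + EC50^h).
"""

import calscreen as cs
from calscreen.scoring import (
    compute_rescue_boundaries,
    fit_dose_response,
    parameter_recovery,
    pr_by_concentration,
)

dataset = cs.simulate_dose_series(
    cs.CompoundEffect("cpd", rescue_fraction=1.0),
    ec50_true=0.05, hill_true=1.0, replicates=4, seed=3,
)
features = cs.features_frame(dataset.traces.values())
boundaries = {
    v: compute_rescue_boundaries(features, dataset.plate_map, vehicle=v)
    for v in dataset.plate_map["vehicle"].unique()
}
well_pr, _ = parameter_recovery(features, boundaries, dataset.plate_map)
curve = pr_by_concentration(well_pr, dataset.plate_map, compound_id="cpd")
for _, row in curve.iterrows():
    print(f"  {row['concentration_uM']:.4f} uM -> PR {row['pr']:5.1f} %")

fit = fit_dose_response(curve["concentration_uM"], curve["pr"])
print()
print(f"fitted EC50 = {fit.ec50_uM:.3f} uM (planted 0.050), Hill slope = {fit.hill_slope:.2f}")
print(
    "PR climbs with concentration as the compound pulls the oscillation "
    "features back inside the control boundaries; the fitted EC50 recovers "
    "the planted potency to within its sampling error (median over many "
    "seeds lands within a factor of two)."
)
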