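"""Collinearity-based identifiability screen on a synthetic cohort.

Fits each patient by least squares, builds the scaled local sensitivity
matrix at the fitted point, computes the collinearity index of every
parameter subset (threshold 20), and selects the largest subset identifiable
for the most patients — the subset the mixed-effects calibration lets vary.
"""

from drinkdyn.calibration import patient_data, per_patient_fit
from drinkdyn.identifiability import select_common_subset, sensitivity_matrix, subset_screen
from drinkdyn.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_patients=6, sigma2=0.25, missingness=0.1, seed=3))
reports = []
for s in cohort:
    pdat = patient_data(s)
    est, resvar, _ = per_patient_fit(pdat)
    S = sensitivity_matrix(est, pdat.ics, pdat.days_a, pdat.days_d)
    rep = subset_screen(S, patient_id=s.patient_id)
    reports.append(rep)
    full = rep.index_of(("a1", "a2", "a3", "d1", "d2", "d3"))
    four = rep.index_of(("a2", "a3", "d2", "d3"))
    print(
        f"{s.patient_id}: index(all six) = {full:6.1f}   "
        f"index(a2,a3,d2,d3) = {four:5.2f}"
    )

subset, n_ok = select_common_subset(reports)
print(
    f"\nselected subset: {{{', '.join(subset)}}} "
    f"(identifiable in {n_ok} of {len(reports)} patients)"
)
print("indices above 20 flag subsets whose members can compensate one another")
print("almost exactly; letting only the selected subset vary keeps every")
print("estimated parameter pinned down by the data.")
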