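"""Simulate nightly drinking-desire dynamics and classify their behavior.

Runs the coupled recursion at the published population parameter estimates
from the median initial conditions of the reference cohort, prints the first
week of the trajectory, the qualitative behavior label, and the equilibrium
structure of two nearby parameter points.
"""

from drinkdyn import classify_behavior, classify_equilibrium, simulate
from drinkdyn.references import MEDIAN_ICS, POPULATION_PARAMS, SUBJECT_PARAMS

traj = simulate(POPULATION_PARAMS, MEDIAN_ICS, horizon=84)
print("First week at the population parameter point (A = drinks, D = desire):")
print(traj.to_frame().head(7).round(3).to_string(index=False))

out = classify_behavior(POPULATION_PARAMS, MEDIAN_ICS)
print(
    f"\nBehavior: {out['label']} "
    f"(dominant eigenvalue modulus {out['dominant_eigenvalue_modulus']:.4f} < 1: "
    "the cohort-average patient relaxes toward abstinence, slowly)"
)

print("\nEquilibrium structure:")
print(" population point:", classify_equilibrium(POPULATION_PARAMS).note)
s1677 = SUBJECT_PARAMS["1677"].replace(a2=1.0)
rep = classify_equilibrium(s1677)
print(" subject 1677 with a2 -> 1:", rep.note)
print(
    f"   e.g. sustaining A* = 2.6 drinks/night pairs with D* = {rep.dstar_for(2.6):.2f} "
    "desire units (moderation rather than abstinence)"
)
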