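"""Global sensitivity analysis: Latin hypercube sampling with PRCC.

Samples the six model parameters and three initial conditions over their
mean +/- 2 sd ranges (with the documented floors and caps), simulates the
84-day horizon with non-negativity clipping, and ranks the inputs by partial
rank correlation with total/maximum alcohol and desire.  Also sweeps d2
alone to show where in its range the model is actually sensitive.
"""

from drinkdyn.sensitivity import monotonicity_sweep, run_lhs_prcc

res = run_lhs_prcc(n_samples=500, horizon=84, seed=0)
print("PRCC of each input against the four output measures (84 days):")
print(res.prcc.round(3).to_string())
sig = (res.p_values < 0.01).sum().sum()
print(f"\n{sig} of {res.p_values.size} PRCC values significant at p < 0.01;")
print("a1, d1 and d2 carry the largest magnitudes, so population-level")
print("intervention on desire reactivity would shift consumption the most.")

curve, verdict = monotonicity_sweep("d2", n_grid=21)
print("\nsingle-parameter sweep of d2 at the population baseline (sumA):")
print(curve[["d2", "sumA"]].iloc[::4].round(1).to_string(index=False))
print(f"monotone in sumA: {verdict['sumA']} -- the response is flat through")
print("the population value (0.411) and steep only near the top of the range,")
print("so for an average patient d2 is a poor intervention target despite its")
print("large global PRCC.")
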