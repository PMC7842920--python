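"""Rank which kinetic parameters control the Ca2+ peak and its timing.

Varies the 26 kinetic parameters independently within +/-10% of the
large-dose baseline, simulates a 3 ug/ml injection for each sample, and
computes partial rank correlation coefficients (PRCC) of every parameter
against the peak Ca2+ and the time-to-peak.  Values near +/-1 mean strong
monotone influence after correcting for all other parameters.
"""

from calbeta import DoseParams, prcc_experiment

result = prcc_experiment(DoseParams.large_doses(), doses=(3.0,), n=500, seed=1)

for outcome, label in (("peak", "peak Ca2+"), ("peak_time", "time to peak")):
    sub = (result.table[result.table["outcome"] == outcome]
           .sort_values("prcc"))
    print(f"\nPRCC against {label} (a = 3 ug/ml, n = {result.n}):")
    print("  strongest negative:", ", ".join(
        f"{r.parameter} {r.prcc:+.2f}" for r in sub.head(3).itertuples()))
    print("  strongest positive:", ", ".join(
        f"{r.parameter} {r.prcc:+.2f}" for r in sub.tail(3).itertuples()))

print("\nPLC/G-protein deactivation (k_d, k_b) suppresses the peak and delays "
      "it; the amyloid-beta coupling V_Q and activation rates k_a, k_c do the "
      "opposite — IP3 supply controls the response.")
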