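"""Simulate the Ca2+ response to increasing amyloid-beta doses.

Runs the large-dose parameter regime for injections of 1, 3, 10 and
30 ug/ml and prints the peak cytosolic Ca2+ and the latency from injection
to peak.  The hallmark dose-response behavior is that the peak grows and
the latency shrinks as the dose increases.
"""

from calbeta import DoseParams, InjectionProtocol, integrate, peak_metrics

params = DoseParams.large_doses()
print("dose (ug/ml)   peak c (uM)   latency to peak (s)")
for dose in (1.0, 3.0, 10.0, 30.0):
    proto = InjectionProtocol(a=dose)  # injected at t1 = 2 s, slow decay r = 0.001/s
    trace = integrate(params, proto, t_end=600.0, dt_out=0.1)
    pm = peak_metrics(trace, "c", t1=proto.t1)
    print(f"{dose:12.0f}   {pm.peak_value:11.4f}   {pm.latency:19.1f}")
print("\nPeak rises and latency falls with dose: more amyloid-beta drives "
      "faster, larger IP3-mediated Ca2+ release.")
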