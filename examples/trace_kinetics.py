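"""Fit dithionite fluorescence-quench traces for plateau, rate and drift.

Simulates six replicate quench traces at typical assay conditions (2 Hz,
300 s, noise SD 0.005) and fits each to
F(t) = (1 - Plateau) exp(-K t) + Plateau - S t, summarizing the half-life
(0.69/K) and drift slope the way a kinetics table would report them.
"""

from scramblefit import endpoint_reduction, fit_trace
from scramblefit.io import trace_summary_frame
from scramblefit.synthetic import simulate_dithionite_trace

fits = [
    fit_trace(simulate_dithionite_trace(f_end=82.5, seed=seed))
    for seed in range(6)
]

summary = trace_summary_frame(fits, label="high-PPR")
print(summary.to_string(index=False))
print(
    f"\nend-point reduction from the fitted plateau: "
    f"{endpoint_reduction(fits[0]):.1f}% "
    "(the F fed to the occupancy analysis)"
)
print(
    "half_life_s tracks the dithionite chemistry (~20 s) regardless of "
    "protein load;\nonly the plateau varies with the amount of scramblase."
)
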