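"""Single-molecule photobleaching step counting on simulated spot fields.

Simulates five movies of surface-immobilized monomeric protein (80%
labeling, 8% spot coincidence, SNR 8, 20 Hz), counts bleaching steps per
spot by change-point detection with movie-wide step-height quantization,
and infers the oligomeric state from the step distribution.
"""

from scramblefit import count_movie_steps, infer_oligomer, step_distribution
from scramblefit.synthetic import simulate_spot_movies

movies = simulate_spot_movies(5, 200, seed=17, n_mer=1)
counts = [count_movie_steps(m.traces) for m in movies]
dist = step_distribution(counts)

for k in range(1, 5):
    print(f"{k}-step fraction: {dist.fractions[k]:.3f} +/- {dist.sem[k]:.3f}")
print(f"uncountable:      {dist.uncountable_fraction:.3f}")

inference = infer_oligomer(dist, label_eff=0.8, coincidence_p=0.08)
print(
    f"\nbest-matching oligomer: {inference.n_mer}-mer "
    f"(squared distance {inference.distance:.4f})"
)
print(
    "a ~90% 1-step fraction with a small coincidence-driven 2-step tail "
    "is the signature of a monomer."
)
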