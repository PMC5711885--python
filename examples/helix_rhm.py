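"""Residual hydrophobic mismatch of a transmembrane helix in a slab bilayer.

Builds an ideal hydrophobic helix protruding above a 30-Angstrom
membrane-core slab and computes its RHM energy (0.0028 kcal/mol per A^2 of
mismatched accessible surface).  A variant with tryptophans at the
interfacial positions — the rational-design strategy for suppressing a
dimerization interface — shows how the interfacial-Trp exemption lowers
the penalty.  Replicate energies are summarized with the small-resample
bootstrap and compared by unpaired t-test.
"""

import numpy as np

from scramblefit import MembraneSlab, bootstrap_sd, compare_constructs, rhm_profile
from scramblefit.synthetic import toy_helix_structure

slab = MembraneSlab(-15.0, 15.0, headgroup_margin=3.0)

plain = toy_helix_structure("LIVLAILVALIVLAILVALI", z_offset=6.0, helix_name="TM4")
# tryptophan substitutions at the residues that sit near the upper boundary
quad_seq = "LIVLAILVALIVLAILWWWW"
quad = toy_helix_structure(quad_seq, z_offset=6.0, helix_name="TM4")

e_plain = rhm_profile(plain, slab)[0]
e_quad = rhm_profile(quad, slab)[0]
print(f"plain helix RHM: {e_plain.energy:.3f} kcal/mol over {e_plain.n_res} residues")
print(f"Trp-substituted: {e_quad.energy:.3f} kcal/mol")

# pseudo-replicates: jitter the helix position slightly, as structural
# snapshots would
rng = np.random.default_rng(3)
reps = {"plain": [], "trp": []}
for _ in range(4):
    dz = rng.normal(0.0, 0.4)
    reps["plain"].append(rhm_profile(plain.translated(dz=dz), slab)[0].energy)
    reps["trp"].append(rhm_profile(quad.translated(dz=dz), slab)[0].energy)

print(f"bootstrap SD (plain): {bootstrap_sd(reps['plain'], seed=0):.3f} kcal/mol")
table = compare_constructs({"TM4": reps["plain"]}, {"TM4": reps["trp"]})
print(table.to_string(index=False))
print(
    "\ndelta < 0: the tryptophan substitutions relieve residual "
    "hydrophobic mismatch,\nreducing the energetic drive to bury the "
    "helix face in a protein-protein interface."
)
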