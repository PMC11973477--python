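"""pH-dependent speciation of a two-site base with interacting sites.

Populations follow grand-canonical Boltzmann weights: state s is weighted by
exp(-[G(s) - n_s * mu_H(pH)]/RT). The pH where adjacent charge-state
populations cross equals the Boltzmann-mode macroscopic pKa.
"""

import numpy as np

from macropka import (
    SiteInteractionModel,
    macro_pka_ladder,
    speciation_curves,
    surrogate_free_energies,
    titration_midpoints,
)

model = SiteInteractionModel(
    intrinsic_pk=[9.0, 5.0], interaction=np.array([[0.0, 1.5], [1.5, 0.0]])
)
table = surrogate_free_energies(model)

ladder = macro_pka_ladder(table, mode="boltzmann")
profile = speciation_curves(table)

print("boltzmann ladder:", [round(p, 3) for p in ladder.pkas])
print("charge-fraction crossings:")
for (donor_c, acceptor_c), ph in titration_midpoints(profile):
    print(f"  charge {donor_c:+d} -> {acceptor_c:+d} at pH {ph:.2f}")

for ph_probe in (3.0, 7.0, 11.0):
    i = int(np.argmin(np.abs(profile.pH - ph_probe)))
    top = profile.fractions.iloc[i].idxmax()
    frac = profile.fractions.iloc[i].max()
    print(f"dominant microstate at pH {ph_probe:4.1f}: {top} ({frac:.2f})")
# The crossings reproduce the ladder steps; between them a single microstate
# dominates, switching as each site titrates.
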