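"""Enumerate the protonation microstates of a tetra-protic macrocycle.

A molecule with four basic nitrogen sites, fully protonated at charge +4,
spans 2^4 = 16 microstates over five charge states. The deprotonation graph
connecting them is the 4-dimensional hypercube: 32 single-proton-loss edges.
"""

from macropka import deprotonation_edges, enumerate_microstates

ms = enumerate_microstates(["N1", "N2", "N3", "N4"], reference_charge=4)
print(ms.to_frame().to_string(index=False))

counts = {c: len(v) for c, v in sorted(ms.by_charge().items(), reverse=True)}
print(f"\nprotomers per charge state: {counts}")
print(f"deprotonation edges: {len(deprotonation_edges(ms))}")
# The 1/4/6/4/1 histogram is the binomial structure of removing protons in
# all combinations; symmetry-equivalent protomers are deliberately retained.
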