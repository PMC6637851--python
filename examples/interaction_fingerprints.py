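"""Per-residue interaction fingerprints over a synthetic ligand series.

Generates a 20-compound congeneric series plus a toy pocket (glutamate
facing the ligand ammonium, leucine near the hydrophobic side, stacked
phenylalanine, tryptophan), fingerprints every complex and prints the
occurrence profile: the percentage of complexes in which each residue
shows each interaction chemotype.
"""

from fieldsar import ComplexPose, compute_ifp, detect_salt_bridge, occurrence_profile
from fieldsar.synthetic import SyntheticSpec, generate_pocket, generate_series

mols, table, _ = generate_series(SyntheticSpec(n_compounds=20, seed=11))
pocket = generate_pocket(mols, include_trp=True)

bridged = sum(detect_salt_bridge(ComplexPose(pocket, m), "E170") for m in mols)
print(f"salt bridge to E170 satisfied by {bridged}/{len(mols)} poses\n")

profile = occurrence_profile([compute_ifp(ComplexPose(pocket, m)) for m in mols])
print(profile.to_string())
print()
print("E170 shows charged (Ch), polar (P) and acceptor (A) contacts in 100% of")
print("complexes - the conserved ionic anchor. The stacked phenylalanine is")
print("aromatic (Ar) throughout; hydrophobic contacts (H) dominate elsewhere.")
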