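"""Assign Protein Blocks to a synthetic backbone and map them to secondary structure.

Builds an ideal 12-residue helix followed by a 12-residue strand, recomputes
its backbone dihedrals, assigns the nearest Protein Block letter per
pentapeptide window, and prints the three tracks.
"""

from hybridfold.fixtures import make_pb_backbone
from hybridfold.pb_alphabet import assign_pb, backbone_dihedrals, pb_string_to_ss

chain = make_pb_backbone("m" * 12 + "d" * 12)
pbs = assign_pb(backbone_dihedrals(chain))

print("sequence:", chain.sequence)
print("PB      :", pbs)
print("SS      :", pb_string_to_ss(pbs))
print()
print("The PB track recovers core helix (m) and core strand (d) letters at")
print("every complete window; the first/last two residues are Z because their")
print("five-residue window is incomplete, and the helix-strand junction shows")
print("transition letters. The SS line maps PBs onto H/E/C for display.")
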