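"""Codewords, Hamming decoding and clinical tie-breaking.

The reference ensemble {A, B, G, H, I} (all decompensations; hypoglycemia;
hypo + severe hyper; all hyperglycemia; moderate + severe hyper) induces a
5x5 codeword matrix. A case's five binary votes are decoded to the class
with minimal Hamming distance; ties go to the clinically more severe class
(mild hyperglycemia last, to curb false alarms).
"""

from bgdecomp import build_codewords, decode
from bgdecomp import binary_models as bm

lib = {s.label: s for s in bm.enumerate_candidate_specs()}
ensemble = [lib[c] for c in "ABGHI"]
C = build_codewords(ensemble)

names = ["nondecompensated", "hypoglycemia", "mild hyper",
         "moderate hyper", "severe hyper"]
print("ideal codewords (columns = models A B G H I):")
for k, row in enumerate(C):
    print(f"  class {k} ({names[k]:16s}): {tuple(int(b) for b in row)}")

for bits in [(1, 1, 1, 0, 0), (1, 0, 0, 0, 0), (1, 0, 1, 1, 0)]:
    cls = decode(list(bits), C)
    print(f"votes {bits} -> class {cls} ({names[cls]})")
# (1,1,1,0,0) matches the hypoglycemia codeword exactly. (1,0,0,0,0) ties
# classes 0 and 2 at distance 1 and resolves to nondecompensated;
# (1,0,1,1,0) ties classes 2 and 4 and resolves to severe hyperglycemia.
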