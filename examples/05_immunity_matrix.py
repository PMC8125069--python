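"""Toxin/immunity cooccurrence across genomes, with caveat flags.

Each toxin-domain family is paired with its cognate immunity protein
(found immediately downstream of the toxin gene); both representatives
are then searched against every proteome at >= 40 % identity over >= 90 %
of the reference.  A toxin without its immunity partner is annotated:
either the toxin gene sits at a contig end, or immunity homology fell
short.
"""

from effectornet import generate_community, immunity_demo_spec
from effectornet.context import ToxinImmunityPair, cooccurrence_matrix, \
    cooccurrence_frame

community = generate_community(immunity_demo_spec(seed=11))
pairs = [ToxinImmunityPair(f"P_{fam}",
                           community.assets.toxin_seeds[fam],
                           community.assets.immunity_seeds[fam])
         for fam in sorted(community.assets.toxin_seeds)]

cells = cooccurrence_matrix(pairs, community.genomes)
frame = cooccurrence_frame(cells)
print(frame.to_string(index=False))
print("\nRows with a caveat (toxin present, immunity not):")
print(frame[frame["caveat"] != "none"].to_string(index=False))
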