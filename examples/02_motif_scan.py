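"""Build a scoring model from a seed alignment and scan proteins with it.

Constructs the Rhs-core PSSM from the community's seed alignment,
calibrates its bit threshold on shuffled decoys, then scans one planted
full-length Rhs protein and one decoy.  The hit span on the Rhs protein
sits at the end of the conserved core, just before the DPxG anchor.
"""

import numpy as np

from effectornet import generate_community, immunity_demo_spec
from effectornet.motifs import (build_pssm, calibrate_threshold, make_decoy,
                                scan_protein)

community = generate_community(immunity_demo_spec(seed=11))
seeds = [s for _, s in community.assets.motif_seed_alignments["rhs_core"]]

model = build_pssm(seeds, name="rhs_core")
rng = np.random.default_rng(0)
decoys = [make_decoy(seeds[i % len(seeds)], rng) for i in range(1000)]
threshold = calibrate_threshold(model, decoys, target_fpr=0.001)
print(f"rhs_core model: width {model.width}, max score "
      f"{model.max_score:.1f} bits, decoy-calibrated threshold "
      f"{threshold:.1f} bits")

truth = community.truth
rhs_pid = truth.loc[truth["kind"] == "rhs_full", "protein_id"].iloc[0]
decoy_pid = truth.loc[truth["kind"] == "decoy", "protein_id"].iloc[0]
proteins = {p.id: p for g in community.genomes for p in g.proteome}

for pid in (rhs_pid, decoy_pid):
    hits = scan_protein(model, proteins[pid])
    kind = truth.loc[truth["protein_id"] == pid, "kind"].iloc[0]
    if hits:
        h = hits[0]
        print(f"{pid} ({kind}): hit {h.start}..{h.end}, "
              f"{h.score:.1f} bits")
    else:
        print(f"{pid} ({kind}): no hit — below threshold, as a decoy "
              "should be")
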