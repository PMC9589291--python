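"""Compare pCREs to known TF binding motifs and cluster them by similarity.

Motif similarity is the best-alignment Pearson correlation between PWMs
(both orientations, ungapped offsets with >= 5 overlapping columns).  A
pCRE matches a TFBM when the PCC exceeds the 95th percentile of pairwise
PCCs within that TFBM's family.  pCREs are clustered by UPGMA on 1 - PCC
with the tree cut at 0.39.
"""

import numpy as np

from coldcre import (
    PWM,
    TFBMRecord,
    distance_matrix,
    family_background,
    kmer_to_pwm,
    match_tfbm,
    pwm_pcc,
    upgma_cut,
)

# --- pairwise PCC ---------------------------------------------------------
r = pwm_pcc(kmer_to_pwm("GATTACA"), kmer_to_pwm("GATCACA"))
print(f"GATTACA vs GATCACA: pcc={r.pcc:.4f} "
      f"(one mismatch of 7: (4*6-7)/21 = {(4*6-7)/21:.4f})")
r = pwm_pcc(kmer_to_pwm("GATTACA"), kmer_to_pwm("TGTAATC"))
print(f"GATTACA vs its reverse complement: pcc={r.pcc:.4f} ({r.orientation})")

# --- TFBM matching with family background --------------------------------
rng = np.random.default_rng(0)
library = [
    TFBMRecord("CAMTA_like_0", "CAMTA", kmer_to_pwm("CCGCGT", "CAMTA_like_0")),
    TFBMRecord("CAMTA_like_1", "CAMTA", kmer_to_pwm("CCGTGT", "CAMTA_like_1")),
    TFBMRecord("decoy_0", "DECOY", PWM(rng.dirichlet(np.ones(4), 8), "decoy_0")),
    TFBMRecord("decoy_1", "DECOY", PWM(rng.dirichlet(np.ones(4), 8), "decoy_1")),
]
print(f"\nCAMTA family background p95: "
      f"{family_background(library, 'CAMTA'):.4f}")
hits = match_tfbm("CCGCGT", library)
top = hits[0]
print(f"query CCGCGT -> best match {top.target} (family {top.family}), "
      f"pcc={top.pcc:.3f}, significant={top.significant}")

# --- UPGMA clustering at 1 - PCC < 0.39 ----------------------------------
pcres = ["GATTACA", "GATCACA", "CCACGTG", "CCACGTC", "TTTTTAA"]
dist = distance_matrix(pcres)
clusters = upgma_cut(dist, cutoff=0.39, labels=pcres)
print("\nclusters at distance cutoff 0.39:")
for c in clusters:
    print(f"  cluster {c.cluster_id}: {c.members}")
# near-identical motifs (one mismatch, distance 1 - 17/21 ~ 0.19) co-cluster;
# unrelated motifs stay apart
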