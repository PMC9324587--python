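"""Bipartite reconstruction and decay-penalized path scoring on a toy network.

Two miRNAs, two diseases, one confirmed association, one strong miRNA
similarity edge: reconstruction hands the isolated miRNA a weighted edge,
and the path model turns similarity chains into penalized association
evidence.
"""

import numpy as np

from tripath import (
    AssociationMatrix,
    EntityIndex,
    PathParams,
    SimilarityMatrix,
    normalize_global_max,
    reconstruct_bipartite,
    threshold_neighbors,
    two_layer_path_scores,
)

mirnas = EntityIndex(["mir-a1", "mir-a2"], "mirna")
diseases = EntityIndex(["dis-c1", "dis-c2"], "disease")

S_mirna = SimilarityMatrix(np.array([[1.0, 0.9], [0.9, 1.0]]), mirnas)
S_disease = SimilarityMatrix(np.eye(2), diseases)
A = AssociationMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), mirnas, diseases)

params = PathParams(T=0.7, beta=7.0)
S_m = threshold_neighbors(S_mirna, params.T)
S_d = threshold_neighbors(S_disease, params.T)

A_recon = normalize_global_max(reconstruct_bipartite(S_m, S_d, A))
print("reconstructed miRNA-disease matrix (mir-a2 inherits 0.9 from its neighbor):")
print(A_recon.values)

W = two_layer_path_scores(S_m, S_d, A_recon, params)
print("\npath weights W (direct term + length-2 paths decayed by exponent "
      f"{params.beta} * 2 = {params.beta * 2:g}):")
print(W.values)
print(f"\nW(mir-a2, dis-c1) - A''(mir-a2, dis-c1) = "
      f"{W.values[1, 0] - A_recon.values[1, 0]:.4f}  (= 0.9^14: the "
      "similarity-then-association path, heavily penalized but nonzero)")
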