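"""Disease semantic similarity from MeSH-style tree numbers.

Builds the three-disease chain universe (a child disease below a parent
below a top-level root), computes the geometric-decay (Model 1) and
information-content (Model 2) similarities, and their fused average.
"""

from tripath import disease_similarity_matrices

tree_numbers = {
    "hepatocellular carcinoma": {"C04.588.274"},  # child
    "liver neoplasms": {"C04.588"},               # its parent
    "neoplasms": {"C04"},                         # top-level root
}

dds1, dds2, fds, index = disease_similarity_matrices(tree_numbers, phi=0.5)
child = index.position("hepatocellular carcinoma")
parent = index.position("liver neoplasms")

print(f"diseases: {list(index.names)}")
print(f"Model 1 (geometric decay)      DDS1(child, parent) = {dds1[child, parent]:.4f}")
print(f"Model 2 (information content)  DDS2(child, parent) = {dds2[child, parent]:.4f}")
print(f"fused                          FDS(child, parent)  = {fds[child, parent]:.4f}")

# Model 1 weights shared ancestors by distance from the disease term;
# Model 2 discounts ancestors common to many diseases (the root contributes
# nothing). The fused value, their mean, is the disease-layer similarity
# used by the predictor.
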