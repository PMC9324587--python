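# Methods

## Problem and model

`tripath` scores candidate miRNA–disease pairs on a heterogeneous network
with three node layers (miRNA, drug, disease). The working assumptions are
(i) functionally similar miRNAs associate with semantically similar
diseases, and (ii) drugs form an informative bridge: a miRNA whose
expression a drug perturbs, and a disease that drug treats, are indirect
evidence for the miRNA–disease pair. The pipeline is fully deterministic;
randomness enters only through the synthetic generator and the
cross-validation fold partitions, both seeded.

### Disease semantic similarity

Each disease is expanded into the DAG of itself and all ancestors obtained
by truncating its dot-separated MeSH tree codes. Two per-ancestor weights
are computed:

* **Model 1 — geometric decay.** The disease term contributes 1; an
  ancestor contributes Φ times the best contribution among its children in
  the DAG, i.e. Φ^(min hop distance). Φ defaults to 0.5, the conventional
  choice; it is exposed in `PathParams`.
* **Model 2 — information content.** Term *a* contributes
  `−log(DAG(a)/N)`, where `DAG(a)` counts the disease DAGs containing *a*
  and N is the universe size. Counts are taken over the *supplied* disease
  set, not all of MeSH: the package never downloads, and the ratio is then
  interpretable as in-study frequency. The log base only rescales both the
  numerator and denominator of the pairwise ratio and cancels; natural log
  is used (a test verifies base invariance).

Pairwise similarity under either model is the shared-term contribution
mass divided by the sum of both totals; the fused disease similarity is
the arithmetic mean of the two models, with the diagonal fixed at 1 (this
also covers the 0/0 case of a disease all of whose terms are universal
under Model 2). A term occupying several tree positions is a single node
(term identity, not code identity). Diseases lacking tree codes are
excluded with a warning by default; a hard-error mode exists.

### Threshold pruning and reconstruction

Off-diagonal similarities below T are set to 0. An entity whose neighbors
would all be pruned keeps its most similar neighbor(s) — all argmax ties,
and only if positive (a zero edge is no edge). The matrix is then
re-symmetrized by keeping an edge if either endpoint kept it, preserving
the symmetric-similarity invariant.

Reconstruction propagates each raw bipartite matrix through the filtered
similarities, `A′ = S_row · A · S_colᵀ`. The diagonal self-similarity of 1
is included deliberately: known associations survive as a baseline, and
identity similarities make reconstruction a no-op. Normalization divides
by the single global maximum; an all-zero matrix passes through unchanged.

### Path scoring

Only paths of at most L = 2 edges are scored: longer paths both multiply
error-prone edges and admit closed loops, and the decay exponent makes
their contribution negligible anyway; L is therefore hard-fixed and other
values are rejected. The two admissible length-2 shapes are
similarity-then-association and association-then-similarity. Enumeration
is a bounded depth-first traversal over nonzero edges; a dedicated test
battery checks it against exhaustive loop enumeration.

The decay `f_decay = β·len(path)` is used as an **exponent** on the path
product. With edge weights in (0, 1], exponentiation attenuates — at the
default β = 7, a length-2 product of 0.9 contributes 0.9¹⁴ ≈ 0.229 — which
is the only reading consistent with treating longer paths as less
reliable; a multiplicative reading would amplify them.

Integration sums the mediated term over **all** drugs. W2 and W3 are first
rescaled by their global maxima so the mediated products stay in [0, 1]
and the exponent remains a decay; the rescale is a documented switch
(`rescale_mediated`) since the summed path weights are otherwise
unbounded. A consequence worth noting: the mediated term involves no
similarity edge, so identity similarity matrices reduce the output to the
raw associations only when no miRNA→drug→disease chain exists; the
end-to-end identity test uses an empty miRNA–drug layer for exactly this
reason. Likewise the large-β limit `Score → A″` holds per cell only where
every feeding path product is strictly below 1; after rescaling, the
argmax drug's product touches 1, and the tests mask such saturated cells.

### Evaluation protocol

Five-fold CV partitions the known positives, zeroes one fold, re-runs the
entire pipeline, and scores held-out positives against all pairs never
known positive. One AUC is computed per repeat by pooling: positives
contribute the score from the fold that hid them; never-positive pairs
contribute their score from every fold run (positives hidden in other
folds are thus never miscounted as negatives). Global LOOCV hides one
positive at a time and averages single-positive AUCs. AUC is the
Mann–Whitney rank form (ties count ½), computed via scikit-learn and
cross-checked against a quadratic pairwise-comparison oracle. Per-repeat
fold partitions derive from `(seed, repeat)` sub-seeds, so results are
reproducible and repeats are independent. Repeats default to 100,
matching the standard protocol; tests and the acceptance script use 5
(and 2 inside the 36-point sweep) to keep runtimes in seconds at the
synthetic problem size.

## Synthetic data

The generator plants the exact structure the method assumes: miRNAs, drugs
and diseases share `n_blocks` blocks; similarity is `within_sim` inside a
block and `between_sim` across (additive uniform ±`noise` jitter, clipped
to [0, 1], symmetrized, unit diagonal); associations are Bernoulli with
probability `assoc_density` in matched blocks and `noise × assoc_density`
across, so the noiseless limit is exactly block-structured. Defaults:
20 miRNAs / 10 drugs / 20 diseases, 4 blocks, 0.9 / 0.1 similarity,
density 0.3, noise 0.05. The default study bundle masks 20 % of the
planted miRNA–disease positives (ceiling) as recoverable truth.

What this emulates — and does not. The block model realizes
"similar-associates-with-similar" directly, which is the property the
pipeline exploits; passing the planted-recovery tests shows the machinery
ranks coherently under that assumption. Real association data differ in
ways the generator does not imitate: much larger and sparser matrices
(hundreds of entities, <3 % density), heavy-tailed degree distributions,
correlated annotation biases, and name-matching noise across source
databases. Recovery AUCs here (≈0.90 at the default seed, with a spread
of roughly ±0.07 across generator seeds at this small size) therefore
validate the implementation, not clinical performance.

## Numerical choices and edge cases

* Similarity matrices: symmetry enforced at 1e-9 (construction) / repaired
  below 1e-6 (file loading); diagonal forced to 1; entries clipped to
  [0, 1] within 1e-6 tolerance, rejected beyond.
* Zero-weight cells are absent edges; the DFS never traverses them (a
  0^exponent term would be 0 anyway, but the adjacency lists also keep the
  traversal sparse).
* Ranking ties in score tables break by miRNA index order (stable sort),
  so output is deterministic even for all-zero scores.
* Entity names are lowercased, trimmed, and internal whitespace collapsed
  before matching; duplicate edges count once (raw matrices are binary).
  Any alignment against heterogeneous source databases is a convention of
  this package, not a reproduction of any particular curation.
* Delimiters auto-detect between tab and comma; explicit override
  available everywhere.

## Known limitations

* Only L = 2 path search; general-L is out of scope by design.
* The disease-similarity pair loop is O(r²) over profile dictionaries —
  fine for hundreds of diseases, not tuned for tens of thousands.
* LOOCV re-runs the full pipeline once per positive; at real scale
  (thousands of positives over a 495×383 grid) that is hours, and the
  repeated-FCV path is the practical choice.
* No negative-association handling and no learned edge weights.
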