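# Methods

## Problem and model

`dewalk` predicts unobserved microbe–disease associations from a curated
binary association matrix `A` (N_d diseases × N_m microbes, `A[i,j]=1`
for a known association) and, optionally, a disease × symptom
co-occurrence table. The working assumption is the standard one for
this family of methods: functionally related microbes tend to associate
with phenotypically similar diseases, so proximity in a joint
similarity network is evidence for an unobserved association.

The pipeline has four stages.

**1. Similarity blocks.** The Gaussian interaction profile (GIP) kernel
compares binary profiles (rows of `A` for diseases, columns for
microbes):

    K(i,j) = exp(-γ ‖VP_i − VP_j‖²),   γ = γ′ / ( (1/n) Σ_i ‖VP_i‖² )

with γ′ = 1 by default. Normalizing the bandwidth by the mean squared
profile norm makes the kernel scale-free in the overall association
density. If all profiles are zero the bandwidth is undefined and the
kernel raises an error rather than returning NaN. Symptom-based disease
similarity (SDM) is the cosine between TF-IDF-weighted symptom vectors:
each raw count is multiplied by `log(N/n_i)` where `n_i` counts diseases
with a strictly positive count for symptom i (the standard
document-frequency reading; "presence" is not otherwise defined). The
IDF logarithm base is immaterial — a base change rescales every vector
uniformly and cancels in the cosine — and we assert this as a property
test; natural log is used. Pairs where either weighted vector is
all-zero get similarity 0 off the diagonal (the cosine is 0/0 there;
zero encodes "no evidence of similarity") and 1 on the diagonal. The
integrated disease similarity is SD = (KD + SDM)/2; with no symptom
table SD falls back to KD, which is itself a complete, self-contained
configuration (`disease_similarity: kd` selects it explicitly).

**2. Heterogeneous network.** Nodes are diseases (indices 0…N_d−1) then
microbes. The raw adjacency is the block matrix `[[SD, A], [Aᵀ, KM]]`.
By default the similarity entries are kept as edge weights; a
`binarized` mode thresholds them instead (retained for sensitivity
analysis — weighted walks on similarity-weighted networks are the
established practice and degrade gracefully). The kernel diagonal of 1
gives self-loops; a `drop_self_loops` flag removes them. The matrix is
column-normalized: `A′[i,j] = A[i,j] / Σ_k A[k,j]`. Zero columns are
left zero and logged; the restart term keeps the iteration bounded
regardless, but mass conservation is only claimed for networks without
zero columns. Normalization always applies to the assembled block
matrix, whatever the mode.

**3. Double-ended restart walk.** The seed for a query node is the
uniform distribution over the node itself and its known association
partners (self-plus-neighbors: the minimal reading of "related diseases
and microbial collections"; an optional similarity-thresholded seed
extension is deliberately not a default because no threshold is
principled here). The walk iterates

    P_{t+1} = (1 − r) A′ P_t + r P_0,   r = 0.7

until the L1 change is below 1e-6 (L1 matches probability-vector
semantics). Because columns of A′ sum to ≤ 1, the map contracts at
rate 1 − r, so convergence is geometric and the analytic fixed point
`p = r (I − (1−r) A′)^{-1} p0` exists; it is used as an independent test
oracle, never as the production path. A `max_iter` cap of 1000 is a
generous safety net; hitting it flags the result instead of failing
silently, and the scoring layer refuses flagged walks unless told
otherwise. One walk is run per node (N_d+N_m walks, batched as a single
matrix iteration) and cached; results are identical to per-pair walks
by determinism of the iteration. The pair score reads the counterpart
node's stationary probability and combines the two ends linearly:

    S[i,j] = β · score_m + (1 − β) · score_d,   β = 0.7

where score_d is the disease-seeded walk read at microbe node j and
score_m the microbe-seeded walk read at disease node i. Scores are
convex combinations of probabilities, hence in [0, 1], and linear in β.
Candidate rankings exclude known pairs and break score ties by microbe
label so output is reproducible.

**4. Evaluation.** Global LOOCV removes one known pair at a time;
k-fold CV (default k = 5) removes a random fold of the known-pair list
(uniform permutation under `rng_seed`, split into near-equal blocks).
In every round the kernels, network and seeds are rebuilt from the
masked matrix. This is the default because scoring a held-out pair with
kernels computed from the full matrix leaks the answer: on the default
synthetic data the leakage-permissive mode (`recompute_similarity:
false`, kept for exactly this probe) reaches AUC 1.0 versus ≈ 0.75 for
the honest protocol. Each held-out pair is ranked against all pairs
with no known evidence of association ("global" ranking); the reported
AUC is the mean candidate quantile, which equals the Mann–Whitney
statistic with tie-counting and the trapezoidal area of the step ROC
the result carries. The standalone `roc_auc` uses average-rank ties and
is checked against a brute-force pairwise count and scikit-learn.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `r` | restart probability | 0.7 | locality of the walk; sweepable 0.1–0.9 |
| `beta` | weight of the microbe-seeded walk | 0.7 | β=1/0 reduce to single-ended walks |
| `gamma_prime` | GIP bandwidth numerator | 1.0 | conventional |
| `tol` | L1 convergence threshold | 1e-6 | with r=0.7 reached in ~12 iterations |
| `max_iter` | iteration cap | 1000 | non-convergence is flagged, not hidden |
| `disease_similarity` | `sd` or `kd` | `sd` | which block enters the network |
| `mode` | `weighted` or `binarized` | `weighted` | similarity edges |
| `k`, `rng_seed` | CV folds and fold seed | 5, 0 | folds partition the known pairs |

## Synthetic data

The generator plants a co-clustering: diseases and microbes are
assigned uniformly to `n_clusters` latent groups; `A[i,j] ~
Bernoulli(p_in)` when the groups match and `Bernoulli(p_out)` otherwise;
disease symptom vectors carry Poisson(0.3) background counts plus
Poisson(5) bursts on a cluster-specific symptom block, each signature
symptom expressed with probability `symptom_signal`. Defaults (n_d=30,
n_m=100, n_clusters=4, p_in=0.3, p_out=0.02, 60 symptoms, signal 0.8)
give a sparse matrix — ≈ 270 known pairs, ~2.5% cross-cluster density —
at a scale where full LOOCV with per-round retraining runs in seconds.
The symptom defaults were picked so the symptom signal mirrors but does
not duplicate the association clusters (background noise and the 0.8
expression rate keep SDM informative rather than an oracle).

What the generator does **not** emulate: real taxonomies and symptom
vocabularies, hub diseases with hundreds of partners, correlated
evidence (multiple records per pair are exercised only in I/O tests),
and annotation biases of curated databases. Passing tests on this data
demonstrate that the implementation recovers planted structure under
its own assumptions, not that the method attains any particular AUC on
real curated data; published figures on the real download (≈ 0.87
5-fold, ≈ 0.89 LOOCV at the reference scale of 39 diseases × 292
microbes, 450 distinct pairs from 483 records, 331 network nodes)
additionally depend on protocol choices (SD vs KD block, seed
definition, in-fold recomputation) that the source description leaves
open, so they are documented expectations, not shipped assertions.
One further inconsistency in the source description is worth recording:
it reports 10,038 unknown pairs at that scale, but 39·292 − 450 =
10,938; the package always computes the candidate count from the data.

## Numerical choices and degenerate inputs

- Squared profile distances are computed as ‖x‖²+‖y‖²−2x·y (exact for
  binary profiles), the kernel symmetrized and its diagonal pinned to 1.
- Zero-column networks: columns stay zero; the walk loses mass there
  and conservation is asserted only on zero-column-free networks.
- Isolated query (no known partners): seed = indicator on the node
  itself. CV rounds that isolate a disease or microbe are survivable by
  this rule, not fatal.
- Empty symptom table (0 rows) is valid but degenerate; SDM is refused
  and the pipeline falls back to SD = KD with a logged warning.
- Ties in rankings break by label; ties in AUC count one half.
- Fold assignment, generator draws and null scorers all derive from
  explicit integer seeds; identical configuration yields byte-identical
  reports.

## Problem sizes used in checks

Oracle-agreement checks run on 50 random networks (n ≤ 20), 20 random
6×8 binary matrices and 20 random score vectors (n ≤ 200). Calibration
and signal-recovery checks use the default generator scale (30×100, ≈
270 pairs), where the leakage-free 5-fold AUC is ≈ 0.75, LOOCV ≈ 0.77,
null-scorer LOOCV ≈ 0.50, and ≈ 96% of each disease's top-10 candidates
come from its own planted cluster. These sizes were chosen so the whole
battery re-runs from scratch in a few seconds on one core while keeping
every estimate comfortably away from its decision boundary.

## Known limitations

- The kernel-only similarity stack is simplistic; richer similarity
  sources (sequence, ontology) would slot into the SD/KM blocks but are
  out of scope.
- The per-pair score reads one counterpart node per walk; variants that
  teleport across the bipartite boundary are deliberately not
  implemented.
- Global CV ranks all held-out pairs against the same candidate pool;
  per-disease (local) evaluation is available but secondary.
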