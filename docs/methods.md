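# Methods

## Scope and data model

strucnet analyses case-control cohorts of weighted structural connectomes
on a fixed 82-region parcellation (68 Desikan-Killiany cortical regions +
14 subcortical structures, 41 per hemisphere, left hemisphere indexed
first). A connectome is a symmetric nonnegative matrix with zero diagonal;
weights are dimensionless. Upstream image processing (segmentation,
tractography, fMRI activation mapping) is out of scope: the package starts
from per-pair streamline counts/lengths and per-region volumes, or from
ready connectivity matrices, and from pre-extracted activated voxel counts
for the laterality index.

## Connectome construction

Weights are streamline counts corrected for fiber length and ROI volume,
w_ij = (2/(V_i+V_j)) · n_ij / l̄_ij. The count threshold (default 3) is
applied to the raw count before correction, since its purpose is to remove
spurious low-count streamline bundles regardless of geometry. The
correction is switchable (`raw`, `length`, `length_volume`) because
different toolchains realise the "corrected streamline count" differently;
the length+volume form is the default as the most widely used streamline
density. Mean length per pair (rather than per-streamline averaging) is
used; at the summary level the two are indistinguishable.

## Graph metrics: numerical conventions

Choices that the metric definitions leave open are fixed as follows:

- **Weight-to-length map.** Shortest paths use edge length 1/w, the
  standard choice for streamline-density weights (stronger = shorter).
- **Disconnected pairs** have infinite path length and contribute 0 to
  efficiency sums (1/∞ = 0). The characteristic path length is defined as
  L_p = 1/E_glob (harmonic-mean convention) and is never computed as an
  arithmetic mean of finite distances; an edgeless graph has E_glob = 0
  and L_p = +∞.
- **Clustering** uses the Onnela geometric-mean form with weights
  normalised by the matrix maximum, so C_i ≤ 1 and unit-weight graphs are
  unchanged; nodes with fewer than 2 connections have C_i = 0 and
  contribute 0 to local efficiency.
- **Betweenness** sums over ordered pairs with the 1/((N−1)(N−2))
  prefactor, giving values in [0, 1]. The implementation delegates the
  Brandes accumulation to networkx (whose `normalized=True` reproduces
  exactly this convention); tests check it against an independent
  exhaustive simple-path enumeration.
- **Vulnerability** V_i = (E_glob − E_glob^(i))/E_glob recomputes global
  efficiency on the (N−1)-node deletion subgraph. V_i ≤ 1 always; it can
  be slightly negative when removing a weakly attached node raises mean
  efficiency — the value is reported unclamped.
- All metrics agree with brute-force oracles (Floyd-Warshall, triple-loop
  clustering, exhaustive path enumeration, delete-and-recompute) to 1e-10
  on hundreds of random graphs with ≤ 8 nodes; this is enforced in the
  test suite.

## Small-worldness null model

σ = γ/λ with γ = C_p/⟨C_p^rand⟩ and λ = L_p/⟨L_p^rand⟩, means taken over
an ensemble (default 100) of surrogate networks with identical node count,
edge count, and degree sequence. Surrogates are produced by Maslov–Sneppen
double-edge swaps — 10 × edge-count attempted swaps per realisation,
rejecting self-loops and duplicate edges — after which the original weight
multiset is permuted uniformly onto the rewired edges. Permuting weights
preserves the weight distribution while matching only topology/degree,
which is what a degree-matched null claims; strength-preserving nulls are
deliberately out of scope. Rigid topologies admitting no valid swap (e.g.
a triangle) are returned unchanged with permuted weights, so γ = λ = σ = 1
there by construction. A fixed seed makes the whole ensemble, and hence σ,
bit-reproducible.

## Permutation inference

All group tests are one-tailed permutation tests of the group coefficient
in y ~ group + age + sex. Nuisance covariates are handled by
Freedman–Lane: the reduced model (intercept + age + sex) is fitted, its
residuals are permuted and added back to the reduced fit, and the full
model t statistic is recomputed per permutation. p-values use the add-one
estimator (1 + #{t* ≥ t}) / (1 + B), which is valid at finite B and never
exactly zero. When no direction is specified both one-tailed tests are
reported from a single shared permutation stream.

Node-wise comparisons share one permutation stream across all nodes;
family-wise error is controlled by the max-statistic distribution (the
permutation maximum across nodes for the "greater" tail, minimum for
"less"), so p_fwe ≥ p_uncorrected and FWE rejections nest inside
uncorrected ones by construction.

**NBS.** Edges enter testing when nonzero in ≥ 50% of either group (a
configurable inclusion rule that avoids rank-deficient edge fits). Edge
screening uses the parametric t-distribution one-tailed p against the
initial threshold (0.005 strict / 0.05 lenient by default) — standard NBS
practice and cheap at 10 000 permutations — while final component
inference is purely permutational: the null distribution of the maximum
component extent (edge count). Component size is extent, not intensity.
Decrease and increase contrasts are separate one-tailed analyses sharing
the permutation stream.

**Hubs.** The criterion (group-mean B_i ≥ across-node mean + 1 SD, sample
SD with n−1) is applied to the across-subject mean betweenness profile,
giving one hub set per group; a per-subject voting mode is not provided.
Zero across-node SD makes the criterion unattainable and returns an empty
table with a warning.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not diffusion images: one backbone topology per cohort (default
Watts-Strogatz ring lattice, 82 nodes, k = 8 neighbors, rewiring
probability 0.1 — small-world by construction, density ≈ 0.1, like
thresholded structural connectomes), log-normal backbone weights,
multiplicative log-normal subject noise (scale 0.2), and planted effects
that scale a designated connected edge set in patients only (default
attenuation factor 0.7). Cohort sizes default to 27 controls / 14
patients; ages are drawn near 25 ± 4 (controls) and 27 ± 7 (patients)
years and sex is ≈ 56% female, matching a typical young-adult clinical
cohort. The weight scale (log-location −9.7) is chosen so that inverting
weights into streamline summaries yields per-edge counts in the tens and a
whole-brain streamline budget of a few thousand, as real tractography
produces.

What the generator does **not** emulate: spatially correlated noise,
distance-dependent weight profiles, hemispheric asymmetries, topological
variation between subjects (all subjects share one backbone), or lesion
mass effects. Passing calibration and recovery tests therefore shows the
statistics are correct under the stated generative model, not that real
acquisitions meet that model.

`simulate_streamline_summary` inverts a connectome into counts, lengths,
and volumes such that reconstruction reproduces the weights up to integer
count rounding (relative error ≤ 0.5/count); implied counts below the
threshold of 3 are reconstructed as zero, by design.

## Problem sizes and reproducibility

Calibration and recovery checks in the test suite run at reduced but
statistically meaningful sizes chosen for a desk-scale machine: 500 null
datasets at 1 000 permutations for scalar type-I error, 200 datasets at
500 permutations for nodal FWE and for NBS null calibration, 50 seeds for
recovery rates, and 10+10-subject cohorts with 100-network null ensembles
for small-worldness. Production analyses default to 10 000 permutations
and 100 random networks. All randomness flows from user seeds through
numpy Generators (the pipeline fans one seed out per stage via
SeedSequence), so every result table is reproducible byte for byte.

## Known limitations

- Binary-graph metric variants, directed networks, FDR edge-wise
  inference, intensity-weighted NBS, and exchangeability blocks in the
  permutation scheme are not implemented.
- The hub rule is betweenness-based only (no degree/participation
  alternatives).
- The NBS edge-inclusion rule and the parametric screening p are
  conventions; with very small groups the parametric screen can be
  liberal, but final component p-values remain exact permutation
  p-values.
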