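# Methods

## Data model

The mesoscale connectome is a directed, weighted, labelled graph. A *region*
carries an abbreviation, a hemisphere (`left`, `right`, `midline`), a lesion
flag, and a stereotaxic centre-of-gravity coordinate in millimetres; node ids
are `<abbrev>_<L|R|M>`, so a bilateral region contributes two nodes. Lesioned
regions are restricted to the left (ipsilesional) hemisphere, matching the
unilateral occlusion model. Edge weights live on a continuous ordinal scale
with conventional semiquantitative anchors — 0.5 (very light), 1 (light),
2 (moderate), 3 (strong), 4 (very strong) — and the weight filter keeps edges
with weight ≥ threshold (the conventional "at least moderate" cut is 1.5).
Contralateral coordinates are the ipsilateral coordinates with the
medio-lateral axis negated (stereotaxic mirror symmetry); self-loops are
rejected unless explicitly enabled, since the clustering and HITS definitions
used here are loop-free.

The bilateral analysis network is the induced subgraph on the left and right
instances of each activation-mapped region plus the lesioned regions. With
the packaged nomenclature (38 bilateral Fos-expressing regions, 6 left-sided
lesion regions) this yields the 82-node composition of the reference
analysis.

## Fos statistics

Densities are Fos-immunopositive cells/mm² organized by region, side
(`ipsi`/`contra` to the occlusion), surgery (`sham`/`mcao`) and environment
(`home`/`expl`). For a contrast with test and reference groups, the package
reports `D = mean(test) − mean(reference)`, `Dr = D / mean(reference)` and
`Dσ = D / dispersion(reference)`. The source material conflates σ and SEM in
its verbal description; the default dispersion is the SEM with a switch to
the SD, and both are carried in the group-means table. Reference groups are
the home-cage animals for exploration contrasts and the sham animals for
stroke contrasts. A zero reference mean makes `Dr` a NaN sentinel; sentinels
propagate and are excluded pairwise downstream, never silently dropped.
Published sham means are not split by side, so sham cells are emitted for
both sides (sham hemispheres do not differ).

Region classification fits a per-region two-way ANOVA
(`density ~ surgery * environment`, type-II sums of squares, statsmodels)
on the per-animal densities of one side, Bonferroni-adjusts each p-value
family across the regions tested, and labels regions `interaction`,
`explorationActivated` (environment effect, exploration higher),
`strokeHypoactive` (surgery effect, dMCAO lower) or `unchanged`. The
published per-animal counts were never deposited, so this stage runs on
synthetic per-animal data; the packaged table supports means-only analyses
(`D`/`Dr` but not `Dσ` or classification).

## The local-parameter registry

One row per region, ~49 columns, in `unweighted` (counts, hop distances) or
`weighted` mode (strengths for degree-type measures, edge length `1/w` for
path-type measures, the weighted adjacency for spectral measures). Undefined
cells are NaN sentinels. Conventions that were genuinely open and the choices
made:

* **Clustering.** `CluCOut`/`CluCIn` are the directed link densities within
  the out-/in-neighbourhood; `CluCAll` is the directed link density within
  the union neighbourhood; `CluCTriag` is the Fagiolo directed-triangle
  coefficient (networkx); `CluC2` applies the density construction to the
  set of nodes at undirected hop distance exactly 2. On a uniform random
  digraph the expectation of `CluCAll` is the edge density, which is what
  makes the random-baseline clustering value interpretable.
* **Closeness.** Wasserman–Faust scaled, over reachable sets:
  `(r/(n−1)) · (r/Σd)` with `r` the reachable count. The unscaled form
  rewards fragmentation and would invert the vulnerability sign convention.
* **Laterality.** `(ipsilateral − contralateral)/(ipsilateral +
  contralateral)` over the relevant connection class (outputs, inputs, all,
  reciprocal); midline neighbours count to neither side, midline nodes get
  the sentinel.
* **Paths.** Betweenness and stress from shortest-path multiplicities
  (Dijkstra with path counting); `IN` counts ordered neighbour pairs
  `s → i → t` with no direct `s → t` edge (shortest two-step paths);
  eccentricity, radiality (`Σ(diam+1−d)/(n−1)`) and the Scardoni centroid
  value use the same distance matrices; `LCircle` is the shortest directed
  cycle through the node. The abbreviation gloss for `LCircle` in the source
  material ("shortest path to a node") contradicts its name; the cycle
  reading is implemented.
* **Spectral.** Eigenvector centrality is the dominant eigenvector of the
  in-adjacency, max-normalized to 1; Katz uses attenuation `0.9/spectral
  radius`; PageRank damping is 0.85; subgraph centrality is the diagonal of
  the matrix exponential. Hub/authority scores come from an explicit
  Kleinberg iteration with L2 ("squares sum") normalization, tolerance
  1e-10, at most 1000 iterations; connection weights do not enter it.
* **Modules.** Within-module degree z-scores and participation coefficients
  (out/in/all) are computed against a greedy-modularity partition of the
  symmetrized graph; the partition is recorded in the table attributes for
  reproducibility.
* **Shapley.** The coalition value of a node set is the number of strongly
  connected components of its induced subgraph; the Shapley value is exact
  (2^n subset enumeration) for n ≤ 8 and a seeded Monte-Carlo permutation
  estimate (default 5000 permutations, coalition values memoized by bitmask
  for n ≤ 24) otherwise. More negative = more integrative.
* **Knotty centre.** Greedy maximization of (captured betweenness fraction)
  × (internal edge density) over node subsets — prefix scan of the
  betweenness ordering followed by add/remove refinement; the reported value
  is centre membership (1/0).
* **Vulnerability.** `V = C̄(G) − C̄(G−i)` with `C̄` the mean out-closeness;
  positive when removing the region lowers average closeness.
* **AvgRang** is owned by the ranking step: per parameter, regions are
  sorted by importance under that parameter's orientation (rank 1 = most
  important, ties broken by region id — "row numbering") and the per-region
  mean rank is written back. Orientations default to larger-is-more-important
  except the distance-like quantities (eccentricities, `LCircle`, `AvgRang`)
  and the Shapley value.

## Global parameters and the random baseline

Average pathlength is the mean hop distance over *reachable* ordered pairs
(no infinite-distance imputation); average clustering is the mean of
`CluCAll`; reciprocity counts unordered pairs connected in both directions.
The null model is the ensemble of uniform directed graphs with the same node
and edge counts (no self-loops, no duplicates; edges drawn by uniform
sampling of ordered-pair slots without replacement), per the reference
analysis — not a degree-preserving rewiring null. Small-worldness is
`S = (C/C_rand)/(L/L_rand)` on ensemble means. Plugging the printed reference
values (C = 0.466, L = 2.083, C_rand = 0.183, L_rand = 1.87) into the
identity gives 2.286; the residual against the printed 2.293 is attributable
to the rounding of the printed inputs.

Lesion deltas report `(after − before)/before` for edge count, reciprocal
pairs, pathlength, clustering and small-worldness; both graphs are scored
against one ensemble matched to the post-lesion size, which makes the empty
lesion exactly the identity.

## Synthetic data generator

The generator encodes the study conditions. Connectome: per hemisphere a
directed ring lattice (each region linked to its k nearest ring neighbours,
k derived from the edge budget), pairs realized reciprocally with probability
`reciprocity_bias` (default 0.7) and as a random single direction otherwise,
5 % of within-hemisphere edges rewired to random same-hemisphere targets;
cross-hemisphere edges take 1/(1+ratio) of the budget (ratio default 4),
half of it homotopic; weights are drawn from the ordinal categories with
probabilities (0.15, 0.25, 0.30, 0.20, 0.10). Coordinates sit on two
mirrored ~4 mm shells; lesioned regions are clustered around a lateral
cortical focus so lesion distance is a meaningful covariate. Defaults give
82 nodes and ≈1215 edges, small-worldness > 1, and reciprocity far above the
random-baseline expectation.

Fos tables: a per-region lognormal baseline (log-mean 5, log-SD 1, spanning
the orders of magnitude seen in real group means), a region-jittered
multiplicative exploration effect (fold 3, the sham-group figure), an
ipsilesional multiplicative hypoactivation `1 − depth·exp(−d/λ)` (depth 0.8,
λ = 2 mm, d = distance to the nearest lesioned region) and a homotopic
contralesional compensation `1 + 0.3·exp(−d/λ)`, both applied to the dMCAO
groups; per-animal densities are the group mean times mean-one lognormal
noise (log-SD 0.1, 10 animals/group). Lognormal rather than Poisson noise
reflects the large inter-animal variability of real densities; the
exponential kernel is the simplest monotone choice consistent with a
distance-decaying lesion effect, and it is pluggable.

What the generator does **not** emulate: the true anatomical topology
(ontology structure, hubs of the real rat connectome), region-specific noise
levels, side-asymmetric sham activation, or any biophysical activity
propagation. Passing recovery tests therefore demonstrates that the
estimators recover the planted statistical structure at realistic scale and
noise — not that the reference study's specific anatomical conclusions are
reproduced.

## Numerical choices and problem sizes

Shortest paths use scipy's sparse Dijkstra/BFS; weighted ties in path
counting use a relative tolerance of 1e-9. The acceptance suite runs 50
random-graph replicates at the reference size (82 nodes, 1215 edges) for the
baseline means, 200 for the reciprocity sampling distribution, 25 seeded
graphs with n ≤ 8 for the oracle suite, 20 seeds for planted-effect
recovery, and 1000 null regions for type-I control; the full-pipeline
defaults (e.g. 500 Shapley permutations in `RunConfig` versus 5000 in the
library function) are chosen so a desk-scale end-to-end run completes in
seconds and are documented where they differ.

## Known limitations

Exact numeric parity with the original analysis software is not claimed: its
parameter definitions defer to an unpublished reference, and the curated
connectome and per-animal counts are unavailable. Whether the printed global
parameters used weighted or unweighted edges is unstated — both modes are
provided. The published figure of 17 contralesionally increased regions is
significance-based and cannot be reproduced from group means alone. Partial
correlations and multiple-testing control over the 43 parameter–Fos
correlations are out of scope (the reference reports raw r only), as are
edge-lesion simulation and dynamic connectome models.
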