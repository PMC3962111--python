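# Methods

## Model

The classifier is a counter-propagation artificial neural network (CP ANN):
a Kohonen self-organizing map whose neuron grid is duplicated in a
supervised output layer. The Kohonen layer holds one weight vector per
neuron in descriptor space; the output layer holds one response vector of
the same grid layout. Competitive training assigns each object to the
neuron with the smallest Euclidean distance to its descriptor vector and
moves the weights of all neurons inside the current neighbourhood — in both
layers — toward the object's inputs and targets. The approach assumes that
(i) descriptors are commensurate (hence the mandatory [0, 1] scaling),
(ii) structural similarity in descriptor space is informative about the
response, and (iii) a 2-D topology-preserving projection is an acceptable
compression of the descriptor space; the model's appeal is that each
descriptor's grid slice ("weight level") and the output surface remain
directly readable after training.

Exact schedule, with `t = 0 … T−1` counting object presentations over
`T = epochs · n`:

- learning rate `η_t = η_max + (η_min − η_max) · t/(T − 1)` (linear decay);
- radius `r_t = (max(nx, ny)/2) · (1 − t/T)` (reaches the winner-only
  regime near the end of training);
- grid distance: Chebyshev (square neighbourhoods) on a planar grid by
  default; city-block and toroidal variants selectable;
- neighbourhood factor: triangular `h(d) = 1 − d/(r_t + 1)` for `d ≤ r_t`,
  else 0; a Gaussian option `exp(−(d/(r_t+1))²)`, truncated at the radius,
  is provided;
- presentation order: dataset order each epoch (exactly reproducible);
  seeded shuffling is available.

With inputs in [0, 1] and `η_max ≤ 1` every update is a convex combination,
so Kohonen weights can never leave [0, 1] (asserted during training in the
tests) and output weights stay inside the hull of the initial weights and
the targets. Winner ties break toward the smaller (row, column) index.
Weights initialize uniform in [0, 1] from a seeded generator; fixed seed +
fixed data gives bit-identical models, which the test suite exploits by
comparing the vectorized trainer bit-for-bit against an independent
loop-based reference.

Defaults follow the study architecture: 35 × 35 grid, 200 epochs. The
learning-rate bounds (0.5 → 0.01) and the schedule above are this package's
documented choices — classical CP ANN practice, exposed in
`TrainingConfig` — since only grid size and epochs are externally fixed.
Class coding is 1 = non-carcinogen (NP), 2 = carcinogen (P); the numeric
decoder thresholds the single output level at the 1.5 midpoint. The
structural-alert-group model variant uses the same Kohonen layer with a
ten-level one-hot output decoded by argmax.

## Descriptors

All twelve descriptors operate on the H-depleted graph of the largest
covalent fragment (salt counterions are dropped with a log message, since
topological distances are undefined across components). Aromaticity, ring
perception (SSSR) and substructure matching all use RDKit's default model,
so fragments and alerts see the same chemistry. Conventions that are not
externally pinned, and are therefore explicit package choices:

- **Spectral moments** (`ESpm11x`, `ESpm09d`) are reported as
  `ln(1 + tr(E^k))`; the raw trace grows combinatorially with size. The
  transform is switchable (`raw`).
- **Edge-degree weighting**: off-diagonal entries of the edge adjacency
  matrix are `1/sqrt(δ_i δ_j)` for adjacent edges, with `δ` the edge degree
  (number of adjacent edges); diagonal zero.
- **Dipole weighting** places bond-dipole moments (Debye; shipped as a
  reviewable CSV of approximate literature bond dipoles) on the diagonal of
  the edge adjacency matrix, off-diagonal 1 — the usual weighted-edge-matrix
  convention. Unknown bond types contribute 0 with a warning.
- **Eigenvalue ranking** (`EEig10x`): descending by absolute value, ties
  resolved toward the larger signed eigenvalue; graphs with fewer bonds
  than the requested rank return 0.
- **Detour matrix**: exact longest simple paths by exhaustive search,
  guarded at 30 atoms (configurable) because the problem is exponential;
  the `D/Dr06` index sums `D_ij/Δ_ij` over unique atom pairs sharing a
  six-membered SSSR ring.
- **Moran autocorrelation** uses atomic polarizabilities (shipped CSV,
  10⁻²⁴ cm³); zero-variance weights or an empty lag shell return 0 by
  convention.
- **Fragment counts** are counted per central atom (the nitroso/amine N or
  the P), which makes symmetric environments count correctly (azobenzene
  has two Ar-N=N centres).

Numeric parity with any commercial descriptor engine is *not* claimed; the
formulas, weights and conventions are fully specified here instead, and
each calculator is pinned by hand-derived small-molecule values (ethane,
propane, benzene, hexane, 1-chloropropane) and by brute-force enumeration
oracles in the tests.

## Structural alerts

The rulebase ships 33 Benigni–Bossa carcinogenicity alerts as SMARTS,
authored from the published alert definitions; every alert record carries a
mechanism tag (genotoxic / non-genotoxic — the non-genotoxic set is SA_17,
SA_20, SA_31a/b/c) and an example molecule that must match it. Authoring
choices worth knowing: SA_8 (aliphatic halogens) excludes halogens on
polyhalogenated ring carbons, which belong to SA_20; SA_10 excludes
quinones (SA_12); SA_13 (hydrazine) excludes N-nitro and N-nitroso
nitrogens; SA_31a is restricted to non-fused benzene rings so halogenated
PAHs and dioxins fall to SA_31b/c. Matching a molecule returns the full
alert set plus a GA/nGA/GA+nGA/NA mechanism summary.

The ten map groups are assigned with explicit precedence: {SA_13, SA_27} →
group 4 and {SA_27, SA_28} → group 7 first (in that order), then the six
single-alert families (SA_7→1, SA_8→2, SA_13→3, SA_21→5, SA_27→6, SA_28→8)
when exactly one of the six matched, then 9 for any other non-empty set and
10 for no alert. Every possible alert set maps to exactly one group.

## Scaling and selection

Descriptors are min-max scaled to [0, 1] per column on the training set
only; new data is clipped into the fitted range and constant columns map to
0.5 (warned). Clipping rather than extrapolation keeps the CP ANN
weight-range invariant valid for external sets. Descriptor pre-selection is
greedy: rank by Fisher ratio `(m₁ − m₂)²/(s₁² + s₂²)` (sample variances;
capped at 10¹² when both variances vanish with distinct means), walk the
ranking and drop candidates correlated above 0.9 (|Pearson r|, default)
with an already-kept column; ties break by column order, and
variance-inflation factors on the kept set are reported warn-only.

## Validation

Class 2 is the positive class for all confusion-matrix rates.
"Leave 20 % out" cross-validation is implemented as stratified 5-fold CV
(each fold held out once, fresh model per fold) reporting both the pooled
and the fold-averaged accuracy, since the phrase does not disambiguate the
two; a repeated stratified-subsampling mode is also provided. External
evaluation reuses the model's stored normalization without refitting.

## Synthetic data and fixtures

The numeric generators emulate exactly what the CP ANN consumes — a
normalized descriptor table with class structure — as isotropic Gaussian
clouds whose mean separation is expressed in units of the within-class SD:
two clouds for the class model (default n = 100/class, p = 12,
separation 4) and ten clouds for the alert-group model, with the two
combination groups (4 and 7) placed midway between their parent clusters.
For the group-map demonstration the separation default is 10 SD: at that
distance between-cluster misassignment is negligible (< 10⁻³), which is the
"well-separated families" regime in which compact single clusters on the
top map are the expected qualitative outcome; at separations below ~6 the
midpoint groups genuinely overlap their parents and strays fragment the
occupied-neuron sets. What the Gaussians do **not** emulate: discrete
fragment-count columns, heavy-tailed and correlated descriptor
distributions, class imbalance, and activity cliffs — so passing recovery
tests demonstrates the learner and pipeline mechanics, not real-data
accuracy. The chemical test surface is separate: 43 curated fixture
molecules with hand-derived alert sets, group labels and fragment counts
(including chlordecone → SA_20, 4-nitroaniline → group 7,
2,4-dinitrophenylhydrazine → group 4, and an unalerted alkane).

Test and demonstration problem sizes were chosen to keep the whole suite in
tens of seconds on one CPU: oracle-equivalence instances at n ≤ 20, p ≤ 5,
grids ≤ 3 × 3; recovery experiments at 10 × 10 / 100 epochs; one full-scale
35 × 35 / 200-epoch run on 800 synthetic rows.

## Map analytics

"Influential zone" is operationalized as the neurons at or above a quantile
(default 0.9) of a weight level — the notion is inherently a thresholding
of a continuous field, so the quantile is exposed rather than hidden.
Constant layers yield an empty zone with a warning, and overlap between
zones is Jaccard similarity (defined 0 when both are empty). Separation of
carcinogens and non-carcinogens inside one alert family is summarized by
two scalars: neuron purity (fraction of occupied neurons holding a single
class) and the Jaccard overlap of the P- and NP-occupied neuron sets.
Cluster compactness on the top map is counted by 4-connected components of
a group's occupied neurons. All map functions are pure views; CSV export is
the contract and PNG rendering (red/yellow high → dark blue low) is
optional.

## Known limitations

- The descriptor implementations are convention-complete but not
  numerically identical to commercial engines; models trained on externally
  computed descriptor tables should keep using those tables at prediction
  time.
- The detour matrix is exact and therefore exponential; very fused systems
  beyond the atom guard need the guard raised consciously.
- SMARTS alerts approximate the published alert definitions; borderline
  chemistry (tautomers, charged species, organometallics) may match
  differently than the original expert system.
- The linear radius/learning-rate schedule is one of several reasonable
  CP ANN schedules; accuracy on real datasets is sensitive to it, and no
  claim of matching any particular published accuracy is made.
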