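# Methods

## Alignment handling

Sequences are encoded over a fixed 21-state alphabet: state 0 is the gap,
states 1–20 the amino acids in alphabetical one-letter order
(`ACDEFGHIKLMNPQRSTVWY`). Both `-` and `.` read as gaps; ambiguity codes
(B, J, O, U, X, Z) carry no family-level coevolutionary information and
also map to the gap state, which keeps the alphabet at exactly 21 states
as the Potts model requires. Writing and re-reading an alignment
round-trips the states exactly (ambiguity codes are not preserved, by
design).

Two filters precede inference, gap filter first by default
(config-overridable, since the order is a genuinely open choice):

* **Gap filter** — keep rows whose gap fraction is ≤ 0.25 (boundary kept).
* **Identity filter** — a deterministic greedy pass in input order: a row
  is kept iff its pairwise identity to every already-kept row is ≤ 0.90.
  Pairwise identity is defined as identical states over columns where both
  rows are non-gap (0 when no such column exists). External redundancy
  filters implement close variants of this rule; the greedy-in-input-order
  choice makes the survivor set reproducible and the pass idempotent. The
  alternative — keeping all rows and down-weighting by similarity — is
  known to give nearly identical inference results, so the exact survivor
  set is not critical.

Taxon labels (`bacteria` / `eukaryote` / `other`) come from a two-column
sidecar table, not from FASTA headers. The taxon-conditional weighting
assigns total weight fraction W_E to eukaryote rows (uniformly within the
clade), 1 − W_E to bacteria rows, 0 to `other`, rescaled so
M_eff = M_E + M_B. At the natural fraction W_E = M_E/(M_E + M_B) every
used row has weight exactly 1, so that grid point reproduces the
unweighted analysis bitwise.

## Potts inference

The family is a 21-state pairwise Markov random field; parameters are
fitted by symmetric pseudo-likelihood maximization (one shared coupling
block per unordered column pair, so J_ij(a,b) = J_ji(b,a) holds by
construction rather than by penalty).

`neg_log_pseudolikelihood` exposes the raw weighted objective

    f(h, J) = − Σ_r w_r Σ_i log P(s_i | s_{\i}) + λ_h Σ‖h‖² + λ_J Σ_{i<j}‖J_ij‖²

with its exact analytic gradient (verified against central finite
differences to < 10⁻⁴ relative error in the tests). At h = J = 0 the
conditionals are uniform, so f = M_eff · L · log 21 — a useful anchor.

**Regularization convention.** `fit_plm` minimizes the per-sequence
averaged objective, `f_data/M_eff + λ_h‖h‖² + λ_J Σ‖J_ij‖²`, which is the
scale at which λ_h = λ_J = 0.01 is the established default for this
method. Applying λ = 0.01 to the *unnormalized* sum would make the
penalty vanish relative to thousands of rows and let pure sampling noise
produce O(1) coupling scores; under the averaged convention, iid uniform
columns at M = 10⁴ yield max |APC| < 0.05, as they should. The two forms
are equivalent up to λ_eff = λ · M_eff.

Optimization is L-BFGS (memory 10) from the all-zero model — deterministic,
so refitting the same input is bitwise reproducible. Convergence is a
projected-gradient tolerance of 10⁻⁵ *on the per-sequence scale* (the same
normalization as the objective); judging the gradient on the raw sum would
make the stopping rule depend on M. Hitting the iteration cap (default
2000) raises an error that carries the last iterate. Free parameters are
h (L×q) plus one q×q block per pair, expanded to the symmetric (Lq)×(Lq)
block matrix for the vectorized kernel (a sparse one-hot design matrix
turns both the conditionals and the gradient into two sparse–dense
products, which keeps a 40-column, 5000-row fit around ten seconds on one
core).

**Scoring.** Potts parameters are gauge-redundant; the Frobenius norm is
not gauge-invariant, so every block is first shifted to the zero-sum gauge
(row and column means zero, the standard convention for this score), with
the a-dependent part of the shift absorbed into the fields so the
conditionals — and hence the pseudo-likelihood — are unchanged. The score
is S_ij = ‖J_ij‖_F over the full 21×21 block: the gap state is included,
keeping the score faithful to the fitted 21-state model. The average
product correction subtracts S̄_i S̄_j / S̄ (row means exclude the diagonal;
an all-zero matrix passes through unchanged). Predictions are the top-N
pairs at column separation ≥ 5 (local pairs reflect secondary structure,
not tertiary contacts), sorted by score with lexicographic tie-breaking
for full determinism.

## Structures and backmapping

Contact maps use the minimal heavy-atom (non-hydrogen) distance between
residues, with a strict `< 8.5 Å` contact rule — a boundary-exact distance
is a non-contact. PDB parsing keeps ATOM records of standard amino acids
only (first model of multi-model entries; altloc resolved by highest
occupancy, ties alphabetically; waters, heteroatoms, H and D dropped).
Residues with missing side-chain atoms participate with whatever heavy
atoms they have.

Alignment columns correspond to structure residues through a global
sequence alignment (match +1, mismatch −1, gap −2) between the ungapped
reference row and the chain sequence; the mapping is rejected below 90%
aligned identity, since a poor alignment would silently scramble the
contact map. Projection into column space marks unmapped columns with
+inf distances; when two conformers are compared, only columns mapped in
both are informative, and the union map is the elementwise minimum of the
two distance matrices (a pair is a union contact iff it is a contact in
either conformer).

Inter-chain interfaces use the same 8.5 Å heavy-atom rule; the interface
is the set of residue pairs spanning the two chains, K its size, projected
onto the shared column axis through the per-chain mappings.

## Topology and statistics

The SP graph has one node per mapped column and one edge per native
contact — *including* local |j−i| < 5 contacts: the separation filter is a
property of the prediction list, while the graph measures the topology of
the structure. SP is plain BFS; disconnected pairs get +inf. Classes:
SP = 1 true positive, SP = 2 near (sharing a contacting neighbour),
3 ≤ SP ≤ 5 mid, SP ≥ 6 incompatible with the conformer; thresholds are
overridable. For two-conformer appraisal the union SP is the per-pair
minimum of the two single-state SPs (by definition — not BFS on the union
graph, which can only be shorter or equal; the tests check that
inequality). TP rates keep unmapped predictions in the denominator; the
mapped-only variant is reported alongside since either counting is
defensible.

Interface enrichment is the exact hypergeometric upper tail
P(X ≥ k) for n predictions, k interface hits, K interface pairs, and
N candidate pairs, summed from log-pmf values so family-scale N ≈ 2×10⁵
is exact. N defaults to *all* unordered column pairs L(L−1)/2 — a
conservative null, since predictions are actually drawn from the smaller
separation-filtered set and are mostly correct in the monomer; the report
also prints the separation-filtered alternative.

The weight sweep refits the model along a W_E grid. The interface pair
set and the normalization set (the reference run's top predictions) are
*fixed* across the sweep, so the relative interface strength
(mean APC score of interface pairs ÷ mean over the fixed top set) tracks
how the same contacts fare as clade weights shift; each grid point also
reports the TP rate of its own top predictions against a fixed reference
map.

## Synthetic data

Generators are fully seeded and bit-reproducible.

* `planted_model`: h = 0; each planted pair gets an independent
  zero-sum-projected standard Gaussian 21×21 block times `coupling_scale`
  (default 1.0 — strong enough for clean recovery at the study sample
  sizes, weak enough that single-site Gibbs mixes well).
* `gibbs_sample`: one chain of single-site Gibbs sweeps in fixed site
  order, default 200 burn-in sweeps and thinning 5 (chosen so the lag-1
  agreement of a flat-model chain sits at the independence level ≈ 1/21;
  `sweep_autocorrelation` monitors this per run). Uniform and
  independent-field marginals match their closed forms within Monte-Carlo
  error in the tests.
* `two_state_scenario` (defaults L = 40, 12 pairs per state, 4 shared):
  couples the *union* of two partially overlapping contact sets; the two
  synthetic "conformer" maps expose each set separately (plus backbone
  |i−j| = 1 edges so the SP graph is connected, as in a real chain).
* `clade_scenario` (defaults L = 30, 10 core + 6 interface pairs, 1500
  rows per clade): core blocks identical in both clades; interface blocks
  added to the bacterial model only — the simplest mechanism that makes an
  interface signal clade-borne.
* `toy_structure`: residues are four-heavy-atom pseudo-amino-acids whose
  centers are placed by constraint relaxation (contacts pulled below 7 Å,
  non-contacts pushed beyond 12 Å, retried on divergence) so that
  requested pairs read back below 8.5 Å and all others above 10 Å —
  exactly, which makes file → parse → contact-map round-trips assertable
  with equality. The geometry is deliberately synthetic: non-contacting
  sequence neighbours sit > 10 Å apart, unlike a real backbone.

What the synthetic families deliberately do **not** emulate: phylogenetic
correlation between rows (rows are Gibbs samples, not a tree), realistic
gap patterns (planted families are gap-free), amino-acid composition bias,
and alignment-construction artifacts. Passing tests therefore demonstrate
the correctness of the inference and appraisal machinery under the model's
own assumptions, not robustness to real-data pathologies such as strong
phylogenetic bias — on real families those effects are exactly why APC,
identity filtering, and taxon reweighting exist.

## Study sizes and defaults

The benchmark conditions are: contact recovery at L = 40, 25 planted
pairs, M = 5000 samples, three seeds (measured PPV of the top-25:
1.00 on every seed, against a ≥ 0.8 bar); the two-conformer study at the
same scale (exclusive-pair recovery 100% per state); the clade study at
L = 30, 10 + 6 pairs, 1500 rows per clade, with the sweep on a 3–5 point
W_E grid. A single fit at the benchmark scale takes ~10 s on one core,
so the full acceptance recomputation stays within a few minutes.

## Known limitations

* The fitter materializes the (Lq)×(Lq) coupling matrix (~1.4 GB at
  L = 624), and per-iteration cost grows as M·(Lq)²; family-scale fits
  (L ≈ 600, M ≈ 3700) are hours-long single-core jobs and are not part of
  the automated studies here.
* The identity filter is O(M²·L) in the worst case; for very deep
  alignments the reweighting alternative is preferable.
* Crystallographic symmetry mates are not generated; an interface
  requires both monomers present as chains in the input file.
* mmCIF is not parsed; inputs are PDB-format text.
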