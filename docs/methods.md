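# Methods

## Contact definition and extraction

A residue pair across the two sides of a complex is a contact when the
Euclidean distance between the residues' representative atoms is strictly
below 6.0 Å; a pair at exactly 6.0 Å is a non-contact. The representative
atom is Cβ, except glycine, which has no Cβ and uses Cα. Parsing fixes the
conventions the input format leaves open:

* only the first model of a multi-model (e.g. NMR) file is read;
* alternate locations resolve to the highest-occupancy conformer, ties
  broken by altloc identifier order;
* HETATM records and non-standard residues (MSE, unknowns) are excluded —
  the 20-letter alphabet is the domain of every downstream matrix;
* a non-glycine residue lacking a Cβ is skipped with a logged warning
  rather than given an invented coordinate.

Contacts accumulate into a 20×20 frequency matrix indexed in fixed
alphabetical one-letter order (A, C, D, …, Y). Each unordered contact is
counted once and mirrored into both symmetric cells; a same-type contact
increments the diagonal once. The mirrored convention is a documented
choice — the ordered-pair alternative is obtainable by halving off-diagonal
cells — and all statistics downstream are computed from whichever table is
supplied.

## Adjusted standardized residuals

The residual of cell (i, j) with margins r, c and total N is Haberman's
adjusted standardized residual,

    d_ij = (o_ij − e_ij) / sqrt( e_ij (1 − r_i/N) (1 − c_j/N) ),
    e_ij = r_i c_j / N.

This margin-corrected form is approximately N(0, 1) under independence, so
the conventional 1.96 threshold marks 95%-confidence enrichment/depletion;
the inequalities are strict, a residual exactly at ±1.96 is "irrelevant". A
plain standardized residual (o − e)/√e is available (`kind="standardized"`)
for sensitivity analysis. Cells whose expectation or variance is zero (an
unobserved residue type makes a whole row/column degenerate) get residual 0
plus an `undefined` flag, keeping the matrix complete for the decomposition
while excluding those cells from significance classes. No multiple-testing
correction is applied across the 400 cells; the threshold is per-cell.

## Decomposition, projection, re-projection

Rows of the residual matrix are observations, columns variables. Columns
are centered by their means; the sample covariance (divisor n − 1; the
divisor affects reported eigenvalues only, not loadings or scores) is
eigendecomposed. No variance scaling is applied — the residuals already
share one statistical scale, which is the point of converting counts to
residuals before the decomposition. Column centering (rather than row or
double centering) is the convention that reproduces the package's worked
example exactly.

Projection of row i on component m is (row_i − μ)·v_m; per-component scores
sum to zero. Re-projection is the outer product scores ⊗ v_m *without*
re-adding the means, so each re-projected matrix is exactly rank 1 and
isolates the structure its component carries; the sum of all re-projected
matrices plus the replicated mean row reconstructs the input to machine
precision (asserted at 1e-8).

Eigenvector sign is arbitrary. The package fixes each component so its
largest-magnitude loading is positive, making artifacts comparable across
runs; quantities that depend on the global sign are compared up to sign
against external references, and the re-projection is sign-invariant. Ties
between eigenvalues fall back to the symmetric eigensolver's deterministic
ordering; degenerate subspaces should be compared by subspace, not by
individual vectors.

Six components are retained by default — the leading handful of components
carries the interpretable structure while trailing components are
dominated by sampling noise — and the count is configurable (1..20).

## Feature encoding

A candidate pair (i, j) with k neighbors per side (default k = 3) is
encoded in 18(2k+1) features (126 at the default):

* **Block 1** — for each of the 2k+1 window residues of side A then side
  B, the six component scores of that residue type (residue-major layout).
* **Block 2** — the windows are aligned antiparallel (position p of window
  A against position 2k − p of window B, so the centers pair and the
  strands read toward each other), and each aligned type pair contributes
  the symmetric average (M[a,b] + M[b,a])/2 of every re-projected matrix M
  (pair-major layout). The ordered entry is available behind a flag.

Window positions past a terminus, and non-standard letters (X, B, Z),
carry a pad symbol and contribute zeros — padding invents no statistics
and keeps the dimension fixed. Any fixed permutation of the layout is
learner-equivalent for the tree ensemble; the layout above is frozen so
feature files are interpretable.

## Predictor and evaluation

The classifier is scikit-learn's `ExtraTreesClassifier` with 1000 trees
(default parameters otherwise), seeded for determinism; the score of a
pair is the fraction of trees voting for the contact class. All negative
pairs are kept by default — the class imbalance is real and the ranking
metric handles it — with optional per-complex negative subsampling at a
stated ratio and seed.

Ranking quality is the area under the ROC curve in its Mann–Whitney
formulation (tie-corrected). Leave-one-complex-out cross-validation refits
*everything* per fold — contact table, residuals, decomposition, features,
ensemble — from the training complexes' positives only, so no statistic of
the held-out complex leaks into its own evaluation; the per-row complex
provenance is asserted disjoint at run time. Complexes whose candidate
pairs are single-class are skipped with a warning. Because "±" dispersion
conventions vary, reports carry both the standard deviation and the
standard error of per-complex AUCs. Top-N selection marks exactly N pairs
positive, ties broken by stable input order, and the derived confusion
metrics use the 0-by-convention rule for zero denominators.

## Synthetic worlds: what they emulate and what they do not

The generators exist so the full pipeline is testable without structure
downloads.

* `worked_example_matrix()` is a 3×3 matrix whose projection (4.16, 3.19,
  −7.35 on PC1) and re-projection coordinates are known to two decimals;
  it pins the centering, eigendecomposition and re-projection conventions.
* `generate_pdb_fixture` / `generate_geometric_complex` write fixed-column
  PDB text with hand-placed or random representative atoms, exercising
  parsing and distance labeling against brute-force geometry.
* Planted-preference worlds draw uniform random sequences and label each
  cross pair a contact with probability base_rate × factor[a, b]. Two
  presets are provided. `planted_preferences()` enriches eight isolated
  charge/hydrophobic pairings 5-fold over a 5% base rate; at 10,000
  sampled contacts those cells reliably exceed the 1.96 residual level
  (the recovery check runs 20 seeds and requires ≥19 successes — with
  ~380 null cells, a few chance exceedances per seed are expected and
  intentional). `interface_preferences()` is block-structured (hydrophobic
  5×, polar 3×, opposite charges 6×, like charges 0.2×, C–C 20×): a
  probability-optimal ranker on that world reaches AUC ≈ 0.68, chosen so
  that a learner recovering most of the signal clears 0.6 with margin
  while label-shuffled nulls sit at 0.5. The cross-validation check uses
  10 complexes of 30×20 residues, a size that keeps the full refit-per-fold
  protocol at a few minutes on one CPU.

What passing these tests shows: the statistics, decomposition, encoding and
evaluation machinery recover planted residue-type preferences end to end.
What they do not show: performance on real interfaces. Real contacts are
spatially clustered (an interface patch, not independent Bernoulli pairs),
sequence neighbors are strongly correlated with spatial neighbors (the
window features carry far more signal in real data), and real preference
structure is denser and weaker per cell. Numbers obtained on planted worlds
are therefore lower bounds on mechanism, not estimates of benchmark
performance.

## Numerical choices and degenerate inputs

* Distances are exact Euclidean on 3-decimal coordinates (PDB precision);
  round-trips are asserted at 1e-3 Å.
* Residual/PCA identities are asserted at 1e-8; significance thresholds
  and the 6.0 Å cutoff are strict inequalities.
* An all-zero contact table has no expectation and is an error, as are
  empty chain groups, single-class training sets and single-class labels
  for AUC.
* All randomness (world generation, subsampling, ensemble) flows from
  explicit seeds; identical seeds give identical reports end to end.

## Known limitations

* Sequence-only prediction ignores conformation; the method learns type
  preferences and local sequence context, not geometry.
* The 20-letter alphabet discards chemically informative non-standard
  residues (selenomethionine is simply dropped).
* The contact-counting convention and the antiparallel window alignment
  are conventions; both are documented and the latter is frozen by the
  package's reference pair list (P-E, V-F, K-A, A-V, A-L, F-T, V-I for the
  PVKAAFV/ITLVAFE windows).
* mmCIF input, solvent accessibility, secondary structure, evolutionary
  profiles and docking are out of scope by design.
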