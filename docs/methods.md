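# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions that were genuinely open, in the order the
pipeline runs.

## Structure model

PDB input is reduced to a single-conformer model: among alternate
locations of an atom the highest-occupancy conformer is kept, ties
resolved toward altloc `A` (the standard single-conformer convention);
only the first `MODEL` of a multi-model file is read; waters are dropped;
non-water `HETATM` groups are kept as ligands, outside the chains.
Nonstandard residues with a standard parent (MSE→M, SEC→C, PTR→Y, …) map
through a fixed table; everything else becomes `X`. Author numbering and
insertion codes are preserved, but all loop windows are 0-based half-open
offsets into a chain's residue list, which keeps window arithmetic
independent of numbering gaps. The writer emits coordinates at the
format's native 1e-3 Å precision; parse(write(s)) is exact at that
precision, and atom serials wrap at 100000.

## Loop features

Per loop position the pipeline records:

* **Backbone dihedrals** φ(C₋₁,N,CA,C) and ψ(N,CA,C,N₊₁) in degrees,
  undefined at chain termini and across chain breaks. A "bond" between
  consecutive residues is accepted when the peptide C–N distance is
  ≤ 2.0 Å, so breaks are detected geometrically rather than from
  numbering.
* **VdW contacts**: heavy-atom pairs within 5.0 Å. Pairs within one
  residue and pairs between sequence-adjacent residues are excluded —
  otherwise covalent geometry would dominate the counts.
* **Hydrogen bonds**: donor–acceptor heavy-atom pairs within 3.5 Å,
  distance-only. Donors and acceptors come from a fixed chemistry table
  (backbone N donates except in proline, backbone O accepts, side chains
  per residue type). Deposited structures generally lack hydrogens, so an
  angle term would require hydrogen placement; a single distance cutoff
  is the criterion the rest of the model is calibrated to.

Contacts internal to the loop and contacts to the rest of the protein
(all chains) are counted separately and both halves are stored; ligand
atoms are not counted. Positions with an incomplete backbone or undefined
dihedrals inside the window are *flagged*, not rejected: they are
excluded from descriptor fits and score neutrally (see below).

## Profile search

The loop family's sequence side starts as a gapless alignment of
fixed-length fragments, turned into a pseudocounted frequency matrix
(freqs = (counts + pc·background)/(n + pc), default pc = 1, uniform
background). A window of a database sequence scores
Σᵢ log₂(wᵢ[aa]/bg[aa]) bits; windows at or above the threshold are kept,
non-overlapping per sequence, best-score-first (ties to the smaller
offset) so one sequence cannot flood the profile. The expansion loop
re-scans, pools matched segments with the seeds and rebuilds the matrix
until the matched set stops changing, the max-norm frequency change drops
below tolerance, or the iteration cap is reached. A matched segment
identical to a seed consumes that seed in the pooling, so seeds present
in the database are not double-counted and a database equal to the seeds
is an exact one-iteration fixed point. If the first scan finds nothing
the seed profile is returned flagged `unconverged-empty`. Threshold,
pseudocount and background are configuration, not claims about any
particular historical run.

## Descriptor

Per position the descriptor pools raw amino-acid frequencies over the
contributing instances (no pseudocount here: a fully conserved position
must show weight 1), clusters the defined (φ, ψ) points, and fits the
count spreads.

**Dihedral clustering.** Angles are unwrapped around their per-dimension
circular mean before fitting, so clusters straddling ±180° stay together;
points are sorted before the fit so assembly is invariant to instance
order. A diagonal-covariance Gaussian mixture is fitted by EM for
K = 1…max_K (default 3) and K selected by BIC. Variances are floored at
(1°)² — also the EM regularization — so perfectly conserved positions
cannot acquire infinite precision. The model stores means, variances,
mixture weights, the training-point responsibilities, and a per-dimension
median absolute deviation (floored at 1°) used to normalize displacements
at scoring time.

**Half-normal spreads.** `fit_halfnormal_sigma` is the closed-form MLE
σ̂ = √(mean x²). For count features it is applied to |x − mean(x)| (the
counts' spread); for the dihedral feature to the Euclidean norm of the
wrap-aware displacement from the circular mean, in degrees.

**Weights.** The sequence feature weight is the summed frequency of the
two most frequent residues. The four structural feature weights are the
fitted σ of each feature multiplied by a per-feature scale factor
(default 1.0; the scale factors exist because the features return spreads
in different natural units). Position weights are the row sums normalized
over the descriptor, so Σᵢ Wᵢᴾ = 1 exactly.

*Direction of the spread weights.* Taking Wᶠ = σ literally means
variable positions weigh more, although position weights are meant to
reflect conservation. Both behaviours are useful — σ up-weights positions
whose structural context carries signal spread, 1/(σ+1) up-weights
conserved ones — so the literal form is the default and
`invert_spread_weights` switches to 1/(σ+1). The recovery results in the
test suite hold under the default.

Descriptors serialize to versioned JSON losslessly (scores after a
save/load round trip are bit-identical), including the provenance loop
instances, which the grafting planner needs.

## Objective

All feature scores are similarities in [0, 1]:

* sequence: frequency-weighted expected BLOSUM62 score of the query
  residue, rescaled by the matrix's global min/max (−4, 11). Comparing to
  the consensus residue instead is a configuration switch. The expected
  score is the default because it uses the whole profile column rather
  than one letter.
* dihedrals: S = 1 − erf(Σₖ πₖ Dₖᵀ Λₖ Dₖ), D the wrap-aware displacement
  from component k's mean divided per dimension by the median normalizer,
  Λ the diagonal precision, πₖ the mixture weight (the mean training
  responsibility). With K = 1 this is 1 − erf of a normalized squared
  Mahalanobis distance: 1 at the mean, strictly decreasing outward. The
  absolute scale of the erf argument is set by the median normalization;
  it is a calibration choice, and only the ordering of candidates depends
  on it in practice.
* counts: S = 1 − |x−y|/max(x,y) with S = 1 when both are zero; the
  printed ratio itself is a mismatch, so the similarity is its
  complement, keeping "larger is better" uniform across features. The
  reference y is the rounded mean of the position's pooled
  (intra + external) totals — one reference per feature, matching the
  single δ per feature in the score; the intra/external split is kept in
  the descriptor for reporting.

Undefined data — flagged query positions, no-data descriptor positions,
unknown residues — scores a neutral 0.5 so missing data neither rewards
nor penalizes. F is the doubly weighted sum; the breakdown object
reproduces it exactly from its stored terms.

## Grafting

The planner compares each provenance loop to the target window *pairwise*
per position (BLOSUM62 residue-vs-residue; dihedral displacement
source→target under the position's total precision Σₖ πₖ Λₖ; pairwise
count ratios), weighted by the descriptor's weights. Pairwise comparison
makes "the target's own loop is its best source" an identity rather than
a hope, which is the correct fixed point for grafting. Unresolved target
positions are invalid: excluded from seeding, carried through extension
with the current source (no score evidence can justify a switch there)
at zero contribution.

The 7-residue seed is the exhaustive maximum over (source, window) pairs
(ties: smaller start, then lexicographic source id). Extension grows the
covered interval one position at a time from whichever end offers the
higher next score, switching sources only on strictly higher score plus a
configurable hysteresis margin (default 0). With margin 0 the plan total
equals seed sum + the per-position ceiling outside the seed, which is the
planner's exact optimum given the seed. A known consequence of seeding by
cumulative 7-score: enlarging the library can relocate the seed and very
occasionally lower the total slightly; the seed rule is kept because it
is the defined search behaviour.

Placement superposes each segment's backbone (Kabsch) on the *original*
target coordinates of the three residues flanking the segment on each
side — scaffold flanks at the window edges, in-window junction residues
at internal boundaries. Using original coordinates keeps the identity
graft an exact fixed point and makes segment placements independent of
each other. Side chains are carried from the source unchanged; junction
Cα–Cα and C–N distances and a heavy-atom clash count (< 2.0 Å to the
retained scaffold, bonded neighbours excluded) are reported instead of
any refinement, which is out of scope by design.

## Synthetic data

The generators exist so every stage is testable without downloads.

* `build_peptide` constructs backbones with ideal bond lengths
  (N–CA 1.458, CA–C 1.525, C–N 1.329 Å), standard angles, ω = 180°, and
  places O and Cβ; requested torsions are recovered by the dihedral code
  to < 1e-4°, which makes the pair a round-trip oracle.
* `generate_motif_family` plants a 30-residue motif (fixed signature
  letters, shared (φ, ψ) template with per-position Gaussian jitter,
  default σ = 5°) inside random flanks drawn from helix/strand/PPII-like
  basins. The few flank residues adjacent to the motif share the motif's
  entry/exit conformation across the family — real functional loops
  splice into conserved secondary structure, and anchor-based grafting
  relies on exactly that. Families default to 30 members, the scale at
  which the recovery tests run.
* `sample_sequences` draws profile-distributed windows in uniform flanks.

What the synthetic families do **not** model: side chains beyond Cβ (so
side-chain H-bond chemistry is exercised only by the unit-level tables),
ligands, packing quality, and real evolutionary covariation. Passing the
recovery tests therefore demonstrates that the statistics and search are
implemented correctly and are discriminative under controlled conditions,
not that descriptors derived from real structures will transfer between
folds at any particular rate.

Problem sizes used by the test suite and the acceptance script — families
of 8–30 structures of ~60 residues, databases of tens of sequences,
10⁴-draw distribution fits, 10³ random planner matrices — were chosen as
the smallest sizes at which the checked properties are meaningful.

Junction-geometry checks run on zero-jitter (ideal-geometry) families:
with shared backbones, spliced junctions must come out at the ideal
peptide bond length, so the band is a sharp correctness check. Under
torsion jitter ≥ 1° the members' segments genuinely diverge (lever-arm
accumulation over 15 residues) and rigid anchor placement leaves junction
strain — visible in the reports, and the reason refinement exists in
grafting pipelines generally; modelling it is explicitly not attempted
here.

## Known limitations

* Distance-only H-bonds over-count at grazing geometries; acceptable for
  spread statistics, not for per-bond accuracy.
* The EM expansion is hard-assignment (scan/pool/rebuild), not a
  soft-posterior EM; with degenerate thresholds it can oscillate between
  match sets, bounded by the iteration cap.
* Fixed-length (N-to-N) replacement only; no insertions/deletions in
  descriptor realizations.
* The erf argument's scale, the count reference statistic, and the scale
  factors are calibration choices; rankings are robust to them in the
  tested settings, absolute F values are not comparable across different
  choices.
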