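# loopcraft

Descriptors of elementary functional loops, and the machinery to use them
in protein engineering: derive a per-position statistical description of a
~30-residue functional loop family from structures, score how well any
candidate loop realizes it, and graft the best — possibly recombinant —
realization into a target scaffold.

## The problem

Many biochemical functions decompose into elementary steps carried by
closed loops of roughly 25–35 residues (phosphate binding by Gly-rich
GxGxxG and P-loop GxxGxG motifs, calcium binding by the EF-hand, and so
on). The same elementary function recurs across unrelated folds, with a
conserved sequence signature but fold-dependent structure and
interactions. To treat such loops as reusable building blocks, one needs
more than a sequence motif: a **descriptor** that captures, position by
position, the sequence preferences, the backbone geometry, and the
interaction load the loop carries in its native contexts — and an
objective that says how well a concrete loop in a concrete scaffold
realizes it.

## The model

A descriptor of length *N* stores per position *i*:

* amino-acid frequencies *w<sub>k</sub>* pooled over the contributing loop
  instances (the sequence profile);
* a diagonal Gaussian mixture over wrap-adjusted backbone dihedrals
  (φ, ψ), the component count selected by BIC;
* half-normal spread parameters of the van-der-Waals contact count
  (heavy-atom pairs within 5.0 Å) and of the hydrogen-bond donor and
  acceptor counts (donor–acceptor heavy-atom pairs within 3.5 Å), with
  intra-loop and loop-to-fold contacts recorded separately.

A candidate loop is scored with

&nbsp;&nbsp;&nbsp;&nbsp;F = Σ<sub>i</sub><sup>N</sup> Σ<sub>j</sub><sup>M</sup> W<sub>i</sub><sup>P</sup> · W<sub>ij</sub><sup>F</sup> · S<sub>ij</sub>

over features j ∈ {sequence, dihedrals, VdW, H-bond acceptors, H-bond
donors}. S<sub>i,a</sub> is the profile-weighted BLOSUM62 log-odds of the
query residue (min–max rescaled to [0,1]); S<sub>i,d</sub> = 1 −
erf(Σ<sub>k</sub> π<sub>k</sub> D<sub>k</sub><sup>T</sup> Λ<sub>k</sub>
D<sub>k</sub>) with D the median-normalized wrap-aware displacement from
each mixture component and Λ = σ<sup>−2</sup> its precision; the count
scores are 1 − |x−y|/max(x,y). The sequence feature weight is the summed
frequency of the two most frequent residues; the structural feature
weights are the half-normal σ of each feature's spread (times a
configurable scale factor), and W<sub>i</sub><sup>P</sup> =
Σ<sub>j</sub>W<sub>ij</sub><sup>F</sup> / Σ<sub>i</sub>Σ<sub>j</sub>W<sub>ij</sub><sup>F</sup>,
so position weights sum to one.

For grafting, every provenance loop of the descriptor is scored
position-by-position against the target window, a 7-residue seed segment
with the best cumulative score is placed, and the seed is extended
greedily — switching to another source loop where it fits strictly better,
which yields recombinant replacements. Segment coordinates are placed by
least-squares (Kabsch) superposition on three flanking anchor residues per
side and the target residues are replaced.

## Worked example

`examples/` holds one short script per capability. Deriving a descriptor
from a synthetic 12-member glycine-rich loop family
(`python examples/derive_descriptor.py`) prints, per position, the
sequence weight, the number of dihedral clusters and the position weight:

```
profile converged in 2 iteration(s), 40 matched segments
12 structural loop instances extracted
pos  aa_weight  K  W_i^P
  0     0.333  2  0.0235
  ...
  5*    1.000  3  0.0243
  6*    1.000  1  0.0243
```

Starred positions are the fixed signature letters: their two most frequent
residues exhaust the profile (aa_weight = 1.0). Scoring a held-out family
member (`python examples/score_loops.py`):

```
fam000: best window at offset 15 (true 15), F = 11.968; true window beats 100% of the others
```

the descriptor's objective ranks the true motif window above every other
window of the structure. Grafting (`python examples/graft_recombinant.py`)
replaces a member's loop with segments from two other members and reports
the junction geometry:

```
recombinant graft: [('fam001/A:15', 0, 15), ('fam002/A:15', 15, 30)]
  junction 0: C-N 1.329 A, CA-CA 3.804 A
```

C–N distances of ~1.33 Å mean the spliced peptide bonds are geometrically
intact.

The same pipeline is available from the shell:

```sh
loopcraft derive --seeds seeds.fasta --db db.fasta --pdb-dir pdbs/ --out desc.json
loopcraft score  --descriptor desc.json --target scaffold.pdb --chain A --offset 15
loopcraft graft  --descriptor desc.json --target scaffold.pdb --chain A --offset 15 \
                 --library-dir pdbs/ --out grafted.pdb
```

## Scope

Structures are read and written as single-conformer PDB (highest-occupancy
altloc, first MODEL, waters dropped, HETATM groups kept separately as
ligands). Hydrogen bonds are geometric (distance-only, fixed chemistry
table) — no energy model, no hydrogen placement. Grafting is rigid
fixed-length replacement with junction reporting; no repacking,
minimization or backbone refinement, and no insertions or deletions.
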