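# Methods

## Motif grammar and lexical sets

A consensus pattern is an ordered list of residue sets over the 20-letter
IUPAC alphabet: a bare upper-case letter is a singleton, `x`/`X` is the
full 20-residue set, `[...]` is the listed set, and a trailing `>` anchors
the motif to the C-terminus.  No other syntax is supported; in particular
there is no N-terminal anchor (none appears in the source conventions) and
no modification marks — phosphorylated residues are matched by parent
identity, and modified residues in structures (PTR, SEP, TPO, MSE, …) are
mapped to their parent amino acid before sequence matching.  The lexical
set of a pattern is the Cartesian product of its position sets; its size
is computed in exact integer arithmetic and enumeration is refused above a
caller-supplied cap (default 10⁶) so `x`-heavy patterns cannot exhaust
memory.  Scanning reports every window that satisfies all position sets,
including overlaps; anchored patterns are tested only at the final window.
Internally offsets are 0-based half-open; reports are 1-based.

## The centroid comparison score

For an atom set with coordinates x₁…x_n, the centroid c is the unweighted
mean and the distance spectrum V is the ascending sort of |xᵢ − c|.  For
two sets of equal size,

score(A, B) = Σᵢ wᵢ |V₁ᵢ − V₂ᵢ|, optionally divided by n.

Choices made where the procedure's verbal description is ambiguous:

- **Weights.**  The default is wᵢ = i/n ("rank_proportional"): since V is
  sorted ascending, increasing weights realise the stated intent that
  atoms far from the centroid gain significance.  The literal reading
  "inversely proportional to position" (wᵢ = 1/i) and uniform weights are
  available as configuration switches; scores and thresholds carry their
  scheme, and comparing across schemes is an error rather than a silent
  inconsistency.
- **Differences** are absolute values: a signed sum could cancel and break
  both nonnegativity and score(A, A) = 0.
- **Normalization** divides by the atom count and is on by default, so
  scores are comparable across window lengths; the binary match decision
  works identically either way as long as threshold and score agree.
- **Decision boundary** is inclusive: match iff score ≤ ε ("exceeds"
  means strictly greater).

Properties (all under test): identity, symmetry, nonnegativity; invariance
under rigid motion, reflection, and permutation of either input's atom
order; and a perturbation bound — moving every atom of one input by at
most δ changes the unnormalized score by at most 2δ·Σwᵢ (the centroid
moves ≤ δ, each distance changes ≤ 2δ, and sorting is 1-Lipschitz in the
max norm).  Reflection invariance means the score is *chirality-blind*: a
structure and its mirror image score 0.  The Kabsch superposition RMSD
(proper rotations only, det = +1; implemented with
`scipy.spatial.transform.Rotation.align_vectors`) is the chirality-aware
counterpart, and a chiral/mirror pair is kept as a test fixture
demonstrating score = 0 with RMSD > 0.

The printed score range of the original study (0.002–13.7) cannot be
reproduced bit-exactly because its exact weight function and
normalization constant are not published; the threshold *rule*
(ε = 1.10 × the maximum known-positive score) is exact arithmetic and is
reproduced, e.g. 0.142 → 0.1562 ≈ 0.16.

## Structure input and the completeness rule

PDB-format parsing is delegated to gemmi with these policies on top:
model 1 only (multi-model NMR handling is not specified upstream; the
choice is logged), hydrogens and waters ignored, one alternate location
per atom (highest occupancy, ties toward altloc A then first-seen),
residues ordered by chain, residue number, insertion code.  Malformed
fixed-width lines are skipped with a warning.  The default atom selection
for comparisons is N, CA, C, CB (glycine contributes three atoms and the
exception is recorded); carbonyl O is selectable but excluded by default.
An instance is scoreable only if it has *complete structural
information*: at least the CA atom per residue (minimal set), with
residues missing preferred atoms (N, CA, C, O, CB) reported; under the
active selection, any missing non-glycine selected atom excludes the
instance from scoring (it is retained, flagged incomplete).  mmCIF is not
supported in this version; the writer emits fixed-column PDB text and
round-trips all retained fields.

## The secondary-structure library

31 named categories plus random coil are registered (the literature count
of "32" versus 31-plus-coil is representable either way because the
registry is configuration-driven); the δ-turn is registered but
permanently unavailable because no structural example of it exists.
Canonical templates come from two sources:

- **Dihedral recipes** (default): ideal backbones built by NeRF extension
  with Engh–Huber geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
  CA–CB 1.521 Å; angles 111.2°/116.2°/121.7°; ω = 180°), CB placed at the
  standard L-configuration offset.  Helix/strand/polyproline and γ-turn
  φ/ψ values are textbook constants; β-turn types follow the
  Hutchinson–Thornton central-residue angles; α-turn subtypes follow the
  Pavone classification at representative angles; the coiled-coil-like
  "2–7 helix" and the π-turn subtypes use representative values fixed
  once in the default registry.  All recipes are editable via a YAML
  override, and built backbones reproduce their recipe dihedrals to
  < 0.5° under re-measurement.  Periodic recipes tile to any window
  length; turn recipes keep their core central and pad with extended
  flanks.
- **Registered exemplars**: users can supply real coordinate segments per
  category to reproduce a reference library; the canonical is then the
  medoid under the centroid score (minimum summed score to the others;
  "first registered" is the alternative), and templates are trimmed
  centrally to the query window.

The **variation limit** of a category is the maximum pairwise centroid
score among its examples, never below a floor of 0.05 score units
(single-example categories get exactly the floor) so zero-width
acceptance regions cannot occur.  Because the score requires equal atom
counts, templates are always realised at the query's window length and
glycine layout; this length-matching convention is the minimal consistent
choice where the source procedure is silent.

## Classification and statistics

Each complete instance is scored against every available canonical
template and, when the motif has solved known positives, against the
positive template under the motif's own ε (derived as 1.10 × the maximum
positive-vs-reference score).  The lowest score wins if within that
candidate's limit; otherwise the instance is random coil.  Ties break by
registry order and are logged.  Tabulation excludes instances flagged as
known-positive queries, and the per-category counts always sum to the
scored total.  The percentage of structured lexica uses lexica *observed
in the structure set* as its denominator (verified against the internally
consistent published rows; both denominators are reported), and the
percentage of structured instances uses all scored instances.  One
published row ([RK]xxK) is internally inconsistent (797/104,100 printed
as 0.008%); the pipeline reports full-precision ratios and does not
attempt to reproduce that cell.  Cross-motif summaries are unweighted
means and min–max ranges of the per-motif percentages.

## Order/disorder categorization

Disorder predictors are consumed, not reimplemented: tracks are binary
per-residue labels (or scores cut at a configurable threshold, default
0.5, the PONDR convention).  A window is structured / unstructured /
hybrid by the all/none/mixed rule, and unscored when its protein has no
track (predictors typically require ≥ 30 residues); the four categories
partition any instance set, and percentages are computed over scored
instances with activity classes below 75 instances suppressed.

## Synthetic data: what it emulates and what it does not

Generators emulate the statistical structure the analysis assumes:
instances spread across secondary-structure categories with only a
minority in the correct one; Gaussian coordinate noise around ideal
backbones; motifs planted at recorded windows in otherwise pattern-free
random sequences; disorder-window categories drawn at target proportions
(default 0.27/0.28/0.45 structured/unstructured/hybrid, the global
proportions reported for large motif collections).  Noise is isotropic
i.i.d. Gaussian per atom — the simplest perturbation consistent with the
score's perturbation bound; correlated backbone noise, sterics, and
database redundancy/bias are *not* modelled.  Random-coil fixtures are
self-avoiding random dihedral walks rather than point clouds so they stay
chain-like.  Every generator is seeded and byte-deterministic, and each
emits a manifest that downstream recovery tests treat as the only source
of truth.  Passing recovery tests therefore demonstrates internal
consistency of the pipeline under these idealised conditions, not
performance on real crystallographic data, where noise is correlated,
conformations are heterogeneous, and completeness failures are common.

## Problem sizes and numerical choices

The recovery study uses 300 six-residue instances (60 per category over
α-helix, β-strand, polyproline helix, 3–10 helix, β-turn I) at σ = 0.15 Å
against limits derived from 5 exemplars per category at the same σ; the
disorder study uses 5,000 windows.  Six-residue windows give the spectra
enough resolution to separate geometrically close categories (α vs 3–10
helix) at that noise level.  With only 5 exemplars the variation limit is
a maximum over 10 pairs and slightly underestimates the population
spread, so a few percent of genuine instances fall to random coil — the
expected behaviour of the published limit rule, not a defect.  Degenerate
inputs are handled explicitly: empty segments, single atoms, < 3-atom or
collinear superpositions (conditioning warning), unequal atom counts
(error, never truncation), and unavailable categories (skipped with a
log line).

## Known limitations

- Chirality-blindness of the score (by construction); use the Kabsch
  RMSD cross-check where handedness matters.
- PDB-format input only; no assemblies, symmetry operators, or element
  inference.
- Recipe templates are ideal conformations; for faithful reproduction of
  a historical library, register the original exemplar segments.
- The disorder module consumes external predictor output; windowing of
  motifs shorter than a predictor's minimum input is handled only as the
  explicit "unscored" bucket.
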