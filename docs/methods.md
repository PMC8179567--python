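# Methods

`macpep` implements target-templated de novo design of heterochiral
(mixed L/D) head-to-tail macrocyclic peptides: starting from a single fixed
hotspot residue docked on a protein surface, poly-glycine rings are closed
around it by analytic kinematic closure, filtered, sequence-designed under a
φ-sign chirality rule, ranked by interface metrics, and validated by
target-free conformational energy landscapes.  This note records the models,
parameter choices and their rationale, and the limits of what the test
fixtures demonstrate.

## Geometry model

Peptides are represented in internal coordinates and realized by sequential
NeRF-style chain extension.  Bond lengths and angles are fixed at
Engh–Huber-style ideal values (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å; N-Cα-C 111.2°, Cα-C-N 116.2°, C-N-Cα 121.7°); only torsions are
degrees of freedom.  All torsions follow the IUPAC convention (cis = 0°,
values in (−180°, 180°]).  ω is trans (180°) everywhere by default,
including D-Pro; cis sampling is off.  Side chains are built from per-residue
z-matrices; the Cβ improper dihedral N-C-Cα-Cβ is +122.6° for L residues and
−122.6° for D, which makes every D topology the exact mirror of its L
partner: building a D chain with sign-negated (φ, ψ, χ) reproduces the
mirrored L chain to machine precision (a property test asserts this).
Hydrogens are limited to the backbone amide H.  Superposition uses Kabsch
SVD with determinant correction, so mirror images can never be superposed —
chirality is preserved by construction.

## Ramachandran bins and the chirality rule

Torsion sampling is biased by coarse Ramachandran regions covering both
chiral halves of the plot.  Classification uses a disjoint, exactly
mirror-symmetric partition: `A` (φ<0, ψ∈[−75°, 50°)), `B` (the rest of the
φ<0 half), and their sign-negated mirrors `a`/`b` on the positive-φ half.
Two broader positive-φ regions, `G` (ψ∈[−100°, 100°)) and `E`
(ψ∈[100°, 260°) mod 360°), plus their mirrors `g`/`e`, are *sampling-only*
regions: they overlap the partition and are drawn from at half weight
(default weights: A/B/a/b = 1, G/E/g/e = 0.5), reflecting that the broad
turn/extended regions are allowed but not favored.  This separation —
disjoint bins for classification, overlapping regions for sampling — is the
package's own resolution of the tension between a partition and a weighted
sampling set; both are configurable through the TOML bin table.
Pro/D-Pro φ is restricted to [−75°, −55°]/[55°, 75°] when the identity is
known.

Chirality assignment is the φ-sign rule: positions with backbone φ < 0 are
designed as L-amino acids, φ > 0 as D; φ = 0 falls to L by a documented
tie-break.  Gly is achiral and allowed on either side.

## Kinematic closure

The ring is cut at the anchor residue and the closure problem is reduced to
the classic triaxial form: three pivot residues are chosen; their Cα atoms
span a triangle with fixed side lengths (the inter-pivot chain segments are
internally rigid once the non-pivot torsions are sampled, and the
prefix/suffix chains growing from the anchor fix the first and last pivot Cα
in space).  The two N-Cα-C angle conditions at the outer pivots are cone
equations solved in closed form (two branches each); the middle-pivot
condition leaves one scalar equation in the triangle hinge angle σ, whose
roots are bracketed on a dense grid (0.5° for target-templated sampling,
1° for target-free landscape sampling, 0.125° for solver verification) and
polished by Brent's method to ~1e-13.  The four branch
combinations × up to four hinge roots reproduce the ≤16 real solutions of
the degree-16 closure polynomial; an independent multistart-Newton oracle on
the raw six-torsion system confirms both counts and torsion values to
<1e-3°.  Accepted solutions must close with bond error ≤0.01 Å and angle
error ≤1°; in practice the residuals are ~1e-12 because the ring is rebuilt
from ideal geometry with the solved torsions.  Backbone sampling around a
target rejects poses with any heavy-atom pair closer than 0.6× the sum of
vdW radii (Bondi-style set: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å).
Ring sizes 7–12 are supported in the pipeline; the solver itself accepts
rings from 6 residues so that the cyclo-hexapeptide validation fixture can
be generated.  Pivots are drawn uniformly at random among non-anchor
residues each attempt; per-attempt child seeds make the sample set
independent of execution order.

## Energy function

A deliberately small, fully decomposable potential (arbitrary units on a
kcal/mol-like scale):

* **steric** — 6-12 Lennard-Jones per heavy-atom pair, well depth ε = 0.05,
  minimum at the vdW contact distance, 6 Å cutoff, linear ramp below 0.6×
  contact so clashes stay finite; pairs within 3 bonds (1-2, 1-3, 1-4) are
  excluded entirely (no scaled 1-4 term — a documented simplification).
* **hbond** — −0.5 per hydrogen bond scaled by a distance/angle falloff.
  Criteria: H···A ≤ 2.5 Å and D-H···A ≥ 120° where an amide H exists;
  donors without explicit hydrogens (side chains, target atoms) use a
  heavy-atom criterion D···A ≤ 3.3 Å with antecedent-D···A ≥ 90°.  Records
  are classified intramolecular-backbone / intramolecular-sidechain /
  intermolecular.
* **rama** — −log of the normalized sampling weight of the bin containing
  (φ, ψ), floored at 0.01.  With the default uniform classification weights
  this term is zero; it becomes active when users supply non-uniform bins.
* **composition** — +1.0 per Gly/Ala and −1.0 per Pro/D-Pro, applied only in
  the design context (it is a sequence prior, not a physical energy).

There is no solvation or electrostatics; the potential is achiral and
rigid-motion invariant (both are property-tested).  The interaction energy
of a complex is computed directly as the cross steric + intermolecular
H-bond sum, which equals E(complex) − E(peptide) − E(target) exactly because
all terms are pairwise decomposable.

The backbone-filter thresholds (discard E > 0; require ≥ 2 intramolecular
backbone hydrogen bonds) are on this potential's scale, not that of any
external force field, and are configurable.

## Interface metrics

SASA is Shrake–Rupley on a Fibonacci dot lattice (960 dots/atom, probe
1.4 Å); buried interface area is the two-sided total
SASA(a) + SASA(b) − SASA(a∪b).  Shape complementarity is the
Lawrence–Colman statistic on exposed vdW-surface dots: for each interface
dot (within 1.5 Å of the opposing surface) S = (n̂_a·−n̂_b)·exp(−0.5·d²)
with nearest-dot pairing; Sc is the mean of the two per-surface medians.
Dot-lattice metrics are exact under translation and invariant under rotation
only up to the lattice discretization (≲0.3% for SASA at the default
density, which is below the density-convergence error); tests assert at
those tolerances.  The in-package SASA implementation is cross-checked
against biotite's independent implementation in the test suite.

## Sequence design

Designable positions receive identities restricted by the φ-sign rule
(L codes at φ<0, D codes at φ>0, Gly anywhere); the default palette excludes
Cys and Met as synthesis liabilities.  The rotamer library is a compact
canonical set — χ ∈ {−60°, 60°, 180°} per sp³ bond, {−90°, 90°} for flat
aromatic χ₂ — with D rotamers as exact sign mirrors.  Metropolis Monte Carlo
over (identity, rotamer) moves runs on a geometric temperature ladder
(3.0 → 0.3 in 10 stages, 5000 moves by default).  The per-move objective is
local and cheap: ramped LJ of the moved side chain against target, backbone
and the other side chains (with bonded-pair exclusions), a polar-contact
reward (−0.3 per N/O pair within 3.2 Å — a stand-in for per-move H-bond
scoring), and the composition term.  Every inter-position pair enters the
tracked objective exactly once, so the best-so-far trace is a consistent,
monotone non-increasing function of the visited states.  After annealing, a
greedy local χ refinement (±10° in 2.5° steps, one pass) replaces
gradient-based side-chain minimization.  The final record is re-scored with
the full energy function, and carries buried SASA, Sc, H-bond counts and
interaction energy; ranking is a stable sort on interaction energy with
buried SASA, Sc and total H-bonds as tie-breakers.

## Energy landscapes and the funnel criterion

For a designed (or otherwise fixed) cyclic sequence, conformers are sampled
without the target by the same kinematic closure, with per-position bins
restricted to each position's design chirality (pivot torsions remain
unconstrained — they are solved, not sampled).  Side chains are repacked by
a short rotamer-only MC with identities fixed; there is no backbone
minimization of samples.  Each conformer is scored target-free and compared
to the design by backbone-heavy-atom RMSD (all-heavy selection is also
available).  The design conformation itself is injected as sample 0.  The
verdict passes when the lowest-energy sample lies within 1 Å of the design;
the median RMSD of the lowest-5%-energy samples is reported alongside.
2000 samples is the default working scale.  No Boltzmann-weighted
pre-organization score is computed — only the RMSD-of-minimum criterion.

## Synthetic fixtures

All tests run with zero downloads.  `make_toy_target` builds a three-strand
antiparallel β-sheet slab of Ala (ideal extended geometry, 0.03 Å coordinate
jitter per seed) with a designated hotspot site above the sheet face — a
geometric stand-in for a flat, sheet-dominated binding surface.  It emulates
rigidity, shape and clash geometry of such a surface but none of a real
epitope's chemistry (charge pattern, conformational change, bound waters),
so passing tests demonstrate algorithmic correctness, not binder quality
against any real receptor.  `make_ideal_macrocycle` generates exactly closed
rings with a requested chirality pattern: candidate conformers are sampled
with matching bins (2500 attempts by default), only those realizing the
pattern are kept, and a multi-start local optimization — torsion coordinate
descent with re-closure from the best candidate at each hydrogen-bond level
and from the overall lowest-energy candidates, followed by a Nelder–Mead
simplex polish over all free torsions — drives the winner onto its basin
floor; the deepest minimum that keeps the pattern and at least two backbone
hydrogen bonds is returned with its measured bond count declared.  The
alternating-chirality hexapeptide fixture lands in a fully
hydrogen-bonded ring roughly 1.5 energy units below the raw sampling tail,
so its funnel verdict is robust across seeds: the lowest-energy landscape
sample is the injected design itself — exactly the pre-organization
signature the landscape module is meant to detect.  The ring-size range is
6–12 here (the design pipeline uses 7–12).

## Reference-structure checks

Two acceptance checks measure the published PD-1/PD-L1 crystal complex
(PDB entry 4ZQK): the buried interface area (≈1970 Ų) and the buried
hotspot tyrosine's rotamer (χ1 = 59°, χ2 = 86°).  The entry is not
redistributed with the package; in offline environments those two tests
report the missing input as a failure rather than silently skipping, and
`scripts/acceptance.py` emits the corresponding values only when a copy is
present at `data/4ZQK.pdb` (`macpep fetch 4ZQK --dest data`).  Analogous
quantities computed on the synthetic complex are always reported under
`synthetic_*` names and are not comparable to the published numbers.

## Problem sizes and determinism

Default working scales — 10000 closure attempts per ring size in production
runs, 2000 in the verification battery; 2000 landscape samples; 5000 MC
moves — were chosen as desk-scale settings that exercise every code path
with stable statistics.  Every stochastic stage derives child seeds from the
run seed via `numpy` SeedSequence spawning keyed on (stage, ring size,
attempt index), so results are bit-reproducible and independent of execution
order; two identical runs produce byte-identical scorefiles.

## Known limitations

* The potential has no electrostatics, solvation or side-chain entropy; its
  E ≤ 0 filter scale is self-referential.
* Bond lengths/angles never move: no Cartesian minimization, no backbone
  relaxation of landscape samples.
* Hotspot placement on an apo surface requires an explicit user-provided
  site and normal; there is no automated binding-site detection.
* Sc and SASA are dot-lattice approximations (no analytic molecular
  surface).
* The manual triage step of real design campaigns (visual inspection of top
  poses) is outside the package; it reports ranked lists only.
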