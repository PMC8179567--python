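# macpep

Target-templated de novo design of **heterochiral head-to-tail macrocyclic
peptides** — rings of 7–12 residues mixing L- and D-amino acids, built to
bind a chosen protein surface.

Flat protein–protein interfaces (the motivating case is the PD-1/PD-L1
immune-checkpoint interaction) are poor targets for small molecules, and
natural all-L peptides are floppy and protease-sensitive. Cyclic peptides
containing D-amino acids combine a large contact surface with structural
rigidity and biological stability, but no natural template exists for such
topologies — they must be designed from scratch against the target. This
package implements that workflow for structural bioinformaticians and
peptide designers:

1. **Hotspot anchoring** — a single high-contribution residue is fixed on
   the target surface, either extracted from a bound partner in a complex
   (e.g. the buried interface tyrosine of a receptor/ligand crystal
   structure) or placed on a bare surface site by a rotamer scan
   (`--hotspot-mode scan`).
2. **Backbone sampling** — poly-Gly arms are appended to the anchor's
   termini and closed into a ring by *generalized kinematic closure*: the
   non-pivot torsions (φ, ψ) are drawn from Ramachandran bins spanning both
   chiral halves of the plot, and three pivot residues are solved
   analytically (triaxial closure, ≤16 real solutions) so the ring closes
   with ideal bond geometry — in the presence of the target, with
   hard-sphere clash screening.
3. **Filtering** — conformers with positive energy (E > 0) or fewer than
   two intramolecular backbone hydrogen bonds are discarded.
4. **Sequence design** — Metropolis Monte-Carlo over identities and
   rotamers under the **φ-sign chirality rule**: positions with backbone
   φ < 0 become L-amino acids, φ > 0 become D; Gly/Ala are penalized,
   Pro/D-Pro favored; the anchor never moves.
5. **Ranking** — by interaction energy, buried interface area
   (Shrake–Rupley SASA), Lawrence–Colman shape complementarity and
   hydrogen-bond counts.
6. **Landscape validation** — target-free conformational sampling of each
   designed sequence; a design is *pre-organized* when its energy-vs-RMSD
   scatter is a funnel whose lowest-energy sample lies within 1 Å of the
   designed conformation.

The scientific details (energy function, bin definitions, closure
reduction, fixture construction) are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the full pipeline against the built-in synthetic β-sheet target (no
downloads needed), designing 9-residue rings around a scanned Trp anchor:

```bash
macpep design --toy-target --ring-sizes 9 --attempts 500 --seed 7 \
              --out demo_run
```

which prints

```
ranked designs: 4
scorefile: demo_run/scorefile.tsv
```

and writes a tab-separated scorefile (`demo_run/scorefile.tsv`, columns
abbreviated here):

```
design_id  ring_size  sequence   total_E   interaction_energy  buried_sasa  sc      inter_hbonds  intra_hbonds  pdb
r9_c003    9          ShnhWqwwh  -12.2379  -3.5426             600.94       0.3260  1             7             designs/design_001_r9_c003.pdb
r9_c000    9          HPNwWWWyD  -19.7228  -3.0953             472.74       0.3046  1             7             designs/design_002_r9_c000.pdb
r9_c001    9          HwrkWrpeW  -15.6507  -2.7347             517.82       0.2986  0             3             designs/design_003_r9_c001.pdb
r9_c002    9          weDfWGyGH   -5.9326  -2.6024             436.88       0.3248  1             3             designs/design_004_r9_c002.pdb
```

Reading the top row: the sequence is one-letter with **D residues
lowercase** (`ShnhWqwwh` = Ser, D-His, Asn, D-His, the fixed Trp anchor,
D-Gln, D-Trp, D-Trp, D-His); `interaction_energy` is
E(complex) − E(peptide) − E(target) in the package's energy units (more
negative = better contact), `buried_sasa` the two-sided interface area in
Å², `sc` the shape complementarity in [−1, 1], and the PDB contains the
designed ring (with a head-to-tail LINK record) in complex with the
target. Designs are ranked by interaction energy with buried area, Sc and
H-bonds as tie-breakers.

To check pre-organization of any cyclic peptide model:

```bash
macpep landscape demo_run/designs/design_001_r9_c003.pdb --chain P \
       --samples 500 --seed 1 --out funnel --plot
```

which writes `funnel.tsv` (energy/RMSD per conformer), `funnel.png`, and a
verdict JSON; for this quick demo design it reports

```json
{"lowest_energy_rmsd": 2.71, "low_energy_median_rmsd": 2.32,
 "passed": false, "cutoff": 1.0}
```

`passed` would be true if the lowest-energy target-free conformer sat
within 1 Å backbone RMSD of the designed (target-bound) conformation — the
signature of a pre-organized design. Most raw designs fail this check
(exactly why the landscape stage exists: it is the last and most selective
filter of the workflow), so in practice the pipeline is run at full
sampling depth (`--attempts 10000`, `--landscape-top-k`) and only
funnel-passing candidates go forward.

Interface metrics for any two chain groups of a complex:

```bash
macpep metrics complex.pdb --chains-a A --chains-b P
```

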