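# Methods

## Conformation labels and the strand definition

Backbone torsions follow the IUPAC convention: φ is the C(i−1)–N–Cα–C
torsion, ψ is N–Cα–C–N(i+1), both in degrees on the half-open interval
(−180, 180]. A residue-frame is labelled α_R when −180 < φ < 0 and
−180 < ψ < 0, α_L when 0 < φ < 180 and 0 < ψ < 180, and *other*
otherwise. The inequalities are strict, so values exactly on a quadrant
boundary (0 or ±180) classify as *other*; the boundary set has measure
zero for simulation data, making the choice harmless in practice. The
first residue of a chain has no φ and the last no ψ; such residues are
*undefined* and are never imputed. Cap residues (ACE/NME) supply the
missing neighbour atom to the adjacent residue but receive no label
themselves. Residue numbering is always taken verbatim from the input
file, and numbering gaps are treated as chain breaks.

An α-strand is a maximal run of ≥ 3 consecutive residues whose labels
strictly alternate between α_R and α_L. Alternation is the defining
property, so a repeated helical label (α_R, α_R) terminates a run rather
than pausing it, as do *other*/*undefined* labels and numbering gaps. The
minimum length is configurable (the three- and four-residue patterns are
both of interest); by construction every segment found at minimum length
4 is also found at minimum length 3.

Region presence is deliberately strict: a frame counts as a strand frame
for a region only when one alternating run spans *every* residue of the
region. Occupancy is the percentage of all trajectory frames (including
frames with undefined dihedrals, counted absent) with the region present,
and the first-appearance time is the index of the first present frame
times the frame saving interval (default 10 ps, first frame at t = 0).

## Peptide-plane flips and superposition

Flip events are bookkept on the label series: one event per transition of
a residue between α_R and α_L on consecutive frames (a configurable gap
allows one intervening non-helical frame). This matches the dihedral-based
strand bookkeeping; the carbonyl C→O rotation angle between the two frames
is available separately as a descriptive magnitude. Frame superposition
uses the standard least-squares rigid-body (Kabsch/SVD) solution on the
region backbone N/Cα/C atoms, always returning a proper rotation.

## TIP3P pair energy and the water network

The water-water interaction is the rigid TIP3P pair potential: nine
site-site Coulomb terms plus one oxygen-oxygen Lennard-Jones term with
A = 582,000 kcal·Å¹²/mol, C = 595 kcal·Å⁶/mol, q_O = −0.834 e and
q_H = +0.417 e. The e²-to-kcal·Å/mol Coulomb factor is taken as 332.0636
and is exposed as a parameter. Two waters are hydrogen bonded when the
pair energy is ≤ −2.25 kcal/mol; the comparison is inclusive, another
measure-zero choice. Under periodic boundaries the partner molecule is
shifted rigidly by the minimum-image offset of the O–O separation.

The hydrogen-bond graph is built either over all pairs or with an O–O
distance prefilter (default 6 Å). The prefilter is purely an
optimisation: the worst-case dipole-dipole attraction of two TIP3P waters
at 6 Å is under 1 kcal/mol, far above the −2.25 criterion, and the
equivalence of the two construction modes is verified empirically on
random boxes in the test suite rather than assumed.

Three-membered rings are triangles of this graph. Ring counts near a
residue use a sphere centred on its Cα (the conventional residue point; a
mode using any heavy atom of the residue was considered but Cα keeps the
counts independent of side-chain composition). The default membership
rule selects the waters whose oxygen lies inside the sphere and counts
triangles among them only — equivalently, triangles of the full graph
with all three oxygens inside — excluding rings that straddle the sphere
boundary. An `any_in` mode that includes straddling rings is provided for
sensitivity analysis. Because edge existence depends only on the two
waters involved, selecting waters first and building the graph afterwards
gives identical counts to filtering a globally built graph.

The stratified summary mirrors the shape of a per-system comparison
table: frames are split into strand and non-strand strata by the region
presence mask, per-residue mean ring counts are taken within each
(stratum, radius) cell, and the total N is the row sum of the per-residue
means. A stratum with zero frames is reported as absent, not as zero.

## Synthetic data: what it emulates and what it does not

The generator reproduces exactly the observables the analyses consume.

*Labels.* Each residue runs an independent first-order Markov chain over
four canonical Ramachandran basins — α_R (−60, −45), α_L (60, 45), β
(−120, 130), PPII (−75, 150) — with a default self-transition probability
of 0.97 per 10 ps frame (mean dwell ≈ 330 ps, a realistic coil-state
persistence). Planted episodes overwrite the region rows with the
alternating pattern; their union is the exact ground-truth presence mask.
Outside episodes, any accidental full-region alternation produced by the
background chains is broken by setting the middle region residue to the β
state, so that planted occupancy is recovered *exactly* rather than
approximately. The default study conditions are 140 residues and 2000
frames at 10 ps (a 20 ns run) with the region at residues 72–74
(Thr-Gly-Val) and episodes totalling 300 frames (15% occupancy), the
first starting at frame 146 (1460 ps).

*Dihedrals.* Angles are drawn from wrapped Gaussians around the basin
means with per-state spreads (10° helical, 15° extended; a single
`spread_scale` rescales all of them, 0 giving the means exactly). The
fraction of helical-state samples whose noise crossed a quadrant boundary
is measured and reported, since it bounds the disagreement between
recovered and planted presence masks.

*Coordinates.* Backbones are rebuilt from (φ, ψ) by internal-to-Cartesian
chain extension (NeRF) with fixed ideal geometry (N–Cα 1.458 Å, Cα–C
1.525 Å, C–N 1.329 Å, standard angles, ω = 180° trans peptides, carbonyl
O in the peptide plane at torsion ψ − 180°). Recomputing the torsions
from the coordinates reproduces the inputs to ~1e-13°, and the 3-decimal
PDB round-trip perturbs angles far less than the distance from any basin
mean to a quadrant boundary, so presence masks survive file round-trips
unchanged.

*Waters.* Planted three-water rings use the planar C3-symmetric minimum
of the cyclic TIP3P trimer found by direct numerical minimisation of the
summed pair energies: oxygens on an equilateral triangle of side 2.758 Å,
each donated O–H rotated 14.65° outward in the ring plane, free hydrogens
in-plane (−5.81 kcal/mol per pair). Every planted ring is validated
against the −2.25 criterion at generation time. Background waters are
rejection-sampled to keep all O–O separations ≥ 5 Å and are additionally
validated to bond with nothing; at 5 Å the maximum dipole-dipole
attraction is ≈ 1.3 kcal/mol, so the validation essentially never
re-draws.

What the generator does *not* emulate: force-field dynamics (no energy
conservation, no correlations between residues, no protein-water
coupling), side chains (backbone-only residues with settable names), and
realistic solvation densities. Passing the recovery tests therefore
demonstrates the correctness of the measurement pipeline — classification,
detection, counting, statistics and file round-trips — not the physics of
any particular simulation.

## Numerical choices and degenerate inputs

Torsions of collinear atom triples raise a dedicated error in the scalar
API and propagate as NaN/undefined in the vectorised path. Coincident
water sites raise a singularity error. Superposition of fewer than three
atoms is an error; collinear selections warn and return the least-squares
solution. Writing an empty trajectory is an error; models with
inconsistent atom counts raise a topology error; malformed coordinate
records raise a parse error naming the line. Alternate-location atoms
keep the highest-occupancy conformer (first on tie). Occupancy of a
zero-frame trajectory is undefined and raises.

Problem sizes in the test-suite and acceptance script were chosen to keep
the full validation run at desk scale: the study-scale recovery uses the
full 140 × 2000 trajectory, the combinatorial oracles use 10,000 random
label strings (≤ 50 residues), 500 random graphs (≤ 60 nodes) and
100–200 random 50-water boxes, and the classifier grid is exhaustive at
1° spacing.

## Known limitations

Occupancies and appearance times reported for real 20-ns MD trajectories
of α-synuclein depend on the underlying simulations, which are not
distributable; this package validates the measurement layer on planted
ground truth and on in-table arithmetic identities instead. The PDB-wide
motif survey operation is provided, but corpus-level counts depend on the
database version and on search filters and are not reproduced here.
Rings of size other than three, protein-water hydrogen bonds and
α-sheet (inter-strand) hydrogen-bond detection are out of scope.
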