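# Methods

## Scope and model

The package analyzes backbone amide hydrogen bonding in protein structures
and its relation to helix geometry. Its working model is purely geometric:
a hydrogen bond is any N–H···O=C arrangement inside configurable distance
and angle cutoffs; secondary structure follows from the pattern of such
bonds, never from an energy function. This mirrors how large-scale archive
surveys of helical hydrogen bonding are done, and it is deliberately
permissive so that the weak second branch of a three-centered bond (one
N–H donating to both the i+3 and the i+4 carbonyl) is not excluded by a
linearity prior.

## Structure input

The PDB reader keeps model 1 only (X-ray entries are single-model),
collapses alternate locations to the highest-occupancy conformer with ties
broken by the lexicographically first altloc identifier, skips waters and
all HETATM groups except the ACE/NME peptide caps (which hydrogen-bond as
part of the backbone), and reads the nominal crystallographic resolution
from REMARK 2. Resolution bins are half-open 0.5-Å intervals [low, high)
tiling [0, 5): the half-open convention makes the bins a true partition,
so 1.50 Å falls in "1.50–1.99". Insertion-coded residues sort after their
base number alphabetically. No coordinate is ever modified on input.

## Hydrogen placement

Amide hydrogens are rarely present in X-ray models, so they are placed
geometrically: in the C(i−1)–N(i)–CA(i) plane, along the external bisector
of that angle, at 1.00 Å from N — the planar sp² nitrogen geometry.
Proline and chain-start residues receive no H; the NME cap is treated as a
donor with its methyl carbon standing in for CA. Placement is exact by
construction (in-plane deviation < 1e−9 Å), which the tests assert.

## Hydrogen-bond detection and categories

Default criteria: H···A ≤ 3.0 Å, D···A ≤ 3.9 Å, D–H···A ≥ 90°,
H···A=C ≥ 90°, all configurable. The H···A cutoff is set at 3.0 Å rather
than the 2.5 Å sometimes used for surface hydrogen bonds because the
second branch of a three-centered helical bond sits near 2.7–3.0 Å on
ideal helical geometry (and near 2.97 Å in solution-simulation averages);
at 2.5 Å the phenomenon this package exists to measure would be defined
away. Same-chain pairs with |register| < 2 are excluded as covalent
neighbours. Detection has no exclusivity constraint: every pair inside
the cutoffs is reported.

Categories are assigned by a deterministic ladder, in order: (1) register
+3/+4 inside an assigned helix segment → three_ten/alpha; (2) |register|
≥ 5 or interchain, with at least one ladder-consistent neighbouring bond
→ sheet; (3) isolated +3/+4 → turn; (4) register ±2 → bend; (5) remaining
intrachain bonds → coil; (6) an optional strict-audit pass re-detects with
angle cutoffs relaxed by 10° and labels the extra near-misses disallowed.
The ladder terms (bends/turns/coils/disallowed) reproduce the layout of
small-set survey reports; their precise definitions are this package's
own, documented choice since no standard exists.

A bond is **shared** (three-centered) iff its donor forms helical bonds at
both registers; both members are flagged, and a donor bonded at a helical
and a distant register is generic bifurcation, not a shared helical bond.
In survey tables shared bonds are counted both in their register column
and in the shared column by default; a flag switches to
shared-column-only, since published tables do not state the convention
(their columns do not sum to the total under either reading).

## Helix assignment

Helical-register bonds whose acceptors occupy consecutive residues are
grouped into maximal runs; a run of length ≥ 2 becomes a helix segment
(shortest legal pattern: i→i+3 followed by i+1→i+4). Flavor is alpha if
all registers are +4, three_ten if all +3, else mixed. Isolated helical
bonds are re-categorized as turns.

## Ideal peptide builder

Peptides are built by sequential internal-coordinate extension (the
natural-extension reference frame): each atom is placed from a bond
length, bond angle and torsion relative to the three preceding backbone
atoms. Default covalent geometry is the Engh–Huber restraint set (N–CA
1.458, CA–C 1.525, C–N 1.329, C=O 1.231, N–H 1.00 Å; N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°, CA–C=O 120.8°); an alternative "pauling"
set with the alpha-carbon angle at 110.0° is provided because residues
per turn is sensitive primarily to that angle. CB is placed with the
+120° improper dihedral N–C–CA–CB (L-configuration, verified against an
ideal alanine template); the carbonyl O is placed anti to the next amide
nitrogen, making each amide group exactly planar when ω = 180°. ACE and
NME caps realize φ of the first and ψ of the last residue and provide an
acceptor-only and donor-only partner respectively. Recomputing torsions
on a built structure reproduces the inputs to < 1e−6°, a property the
tests exercise for arbitrary torsion lists. Dihedral signs follow the
IUPAC right-handed convention and are cross-checked against an
independent crystallographic library in the test suite.

The chain-break rule (C–N > 2.0 Å or Cα–Cα > 4.5 Å) undefines torsions
across gaps rather than raising, so partially damaged residues degrade
locally.

## Closed-form helical parameters and the screw oracle

The torsion → parameter mapping uses the half-sum/half-difference form
given in the README; θ, s, t are handled in radians internally and
degrees at every interface. The coefficients embed one fixed covalent
geometry, so the mapping is exact only for that geometry. Its independent
oracle is a screw-axis fit: the leading window of Cα positions (default
window 4, i.e. 6 points spanning more than one turn) is superposed onto
the trailing window by an optimal rigid transform (Kabsch/SVD); for a
regular helix that transform is the screw operation, giving the winding
angle from the rotation and the rise from the translation projected onto
the rotation axis. On mathematically exact helices the fit recovers both
to < 1e−9; on built ideal helices across φ ∈ [−80, −45], ψ ∈ [−60, −20]
with the 110° geometry, closed form and oracle agree within 0.2
residues/turn and 0.15 Å rise (measured maxima ≈ 0.05 and 0.09). The
domain guard |cos(θ/2)| ≤ 1 can never trigger for real torsions, since
the coefficients bound the expression by 0.862; it is retained for
defensive completeness, and the tests assert instead that every real
(φ,ψ) cell is valid.

The point-dipole energy is exposed in two algebraic forms: the bare
angular form −μ₁μ₂(cos θ₁₂ − 3 cos θ₁ cos θ₂) and the conventional
textbook form with a +μ₁μ₂/r³ prefactor. Under either, a grid scan over
all angle triples places the minimum at collinear arrangements (θ₁, θ₂ ∈
{0°, 180°}) — the analytic root of the linear-hydrogen-bond assumption.

## Survey statistics

Percentages use decimal half-up rounding (2 decimals for binned survey
tables, 1 for category reports), matching how printed tables round
(e.g. 246901/718464 → 34.37 %). The bifurcated tally counts donors, not
bonds: each three-centered donor contributes exactly one i+3/i+4 pair, so
donors = shared bonds / 2, a form that stays correct when bond lists from
many structures are concatenated. Ramachandran occupancy uses 1°×1°
bins over (φ,ψ) ∈ [−180, 180)² restricted by default to residues inside
assigned helix segments (switchable to all residues); Boltzmann
pseudo-energies are E = −kT ln(N/N_max) with k = 0.0019872 kcal/mol/K and
T = 300 K by default, zero at the modal bin, +inf for unoccupied bins,
and invariant to uniform scaling of the occupancies.

## Synthetic fixtures: what they do and do not show

The fixture generator emulates a miniature local structure archive: ideal
capped 12-residue poly-alanine helices built at stated (φ,ψ) points, with
assigned nominal resolutions spanning the bins, written as ordinary PDB
files. Being ideal and rigid, they have exactly uniform torsions, perfect
amide planarity, no thermal disorder, no side chains beyond CB, and no
solvent — so tests on them validate the *machinery* (detection, pattern
assignment, binning, arithmetic, parameter math) and the qualitative
geometry (bifurcation at the consensus torsions, none in extended
strands), not archive-scale statistics. Full-archive quantities (e.g. the
consensus torsion maximum measured over thousands of structures) require
the real archive and are outside desk scale; the acceptance script
therefore recomputes the *arithmetic* on the published counts and the
geometric claims on built fixtures.

## Problem sizes and determinism

Tests and the acceptance script use 12–14-residue fixtures, 72-point
(φ,ψ) scans at 5–8° steps, and 15° dipole-angle grids; the whole suite
runs in a few seconds. Every random element (rigid-body shuffles, random
analytic helices) is driven by a fixed or caller-provided seed; all
pipeline results are exactly invariant under the seeded rigid motions, so
the acceptance output is seed-independent by construction.

## Known limitations

- Geometric detection only; no DSSP-style energy, no side-chain or
  water-mediated bonds.
- The sheet rule is a minimal ladder-consistency test, adequate for
  surveys but not a full β-topology assignment.
- The builder does not energy-minimize; real helices relax a few degrees
  from ideal torsions.
- The closed-form coefficients are not refit for alternative covalent
  geometries; disagreement with the screw oracle grows away from the
  geometry they embed.
- mmCIF input and multi-model (NMR ensemble) handling beyond model 1 are
  out of scope.
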