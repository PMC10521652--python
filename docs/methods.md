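# Methods

## Barrel syntax and register arithmetic

A closed β barrel is summarized by its strand count `n` and shear number
`S`: traverse the hydrogen-bond ladder once around the barrel and you
return to the starting strand offset by `S` residues. A `Blueprint`
decomposes `S` into per-junction register shifts `r_j` (cyclic, one per
adjacent strand pair), so `S = Σ r_j`. The ovoid blueprint has, per
114-residue repeat, strands of length 5, 5, 7, 7 with shifts of 2 at the
junctions after strands 3 and 4 — a per-repeat shift of 4 and S = 8 with
n = 8 over the two repeats.

**Ladder coordinates.** Residue `j` (1-based in its strand) of strand `i`
gets `m = j − c_i`, where `c_i` is the cumulative shift before strand
`i`. Hydrogen-bonded partners share `m`; crossing junction `i → i+1` the
within-strand index advances by `r_i`. Core-facing parity is a function
of `m` alone: **even `m` faces the core**. The parity origin is not
dictated by the fold; we anchor it so that the design's documented
buried positions (residues 2, 60, 93 and their repeat partners 116, 174,
207) come out interior-facing under the default element lengths.

**Element lengths.** Only the strands (5,5,7,7), the three-residue αβ
turns and the 114-residue repeat budget are fixed by the design rules;
helix and βα-loop lengths are free. Defaults: helices 14,14,14,14 and βα
loops 8,4,7,3, which place the strands at residues 1–5, 31–35, 57–63,
88–94 of each repeat so the named positions C4, L34/148, I60/174,
A93/207 fall on strands. Both are constructor arguments; any combination
that closes the budget is accepted.

**Layers and strips.** With `S = n` the inter-strand step climbs exactly
one residue of rise, so core-facing positions with equal `m + i` lie in
one horizontal plane (a *layer*, the unit of the hollow-variant
ablations) and positions with equal `m` form a *Cβ strip* winding
perpendicular to the strands. Layers use the generic height
`m + i·S/n` with half-rise binning, so non-`S = n` blueprints group
correctly too.

## Parametric backbone generation

The wall is built on a sheared lattice in an unrolled plane
(circumferential `u`, axial `v`): per-residue strand step
`s = h(sin α, cos α)`, inter-strand step `t = d(cos α, −sin α)`, with the
classical tilt `tan α = −S·h/(n·d)`. This makes the seam close exactly
(strand n pairs back onto strand 1 offset by `S`) and fixes the
circumference `C = n·d·cos α − S·h·sin α`. The lattice is rolled onto an
ellipse of perimeter `C` whose a:b ratio follows the requested semi-axes
(defaults 13:9 for the ovoid preset, so the realized wall semi-axes are
the requested ones scaled to the perimeter). The adjacent strand pair
with the greatest combined length is centred on a flat (co-vertex) face —
long strands on the flat "major" faces, short strands on the tightly
curved "minor" faces.

Numerical parameters (Å): rise per residue 3.3, interstrand spacing 4.8,
pleat amplitude 0.8 (alternating radial Cα displacement, core positions
inward), helix radial offset 8, helix rise 1.5/radius 2.3, target Cα–Cα
3.8. These jointly satisfy the package's own geometric contracts:
consecutive Cα–Cα in [3.6, 4.1] Å, ladder partner distances in
[4.2, 5.4] Å, no backbone clash under 2.5 Å, and ellipse-fit eccentricity
within 0.05 of the generating value.

Backbone N/C/O atoms are placed in idealized local frames: strand
carbonyls aim along the in-wall ladder direction with alternating sign
(so O···N ladder distances land near 3 Å), helix carbonyls run along the
local helix axis, loop carbonyls along the turn binormal. Cβ is placed
1.53 Å from Cα along the facing direction (inward for core positions).
These are geometric idealizations, not physical peptide geometry; the
analysis code treats them only through distances and directions.

Helices are antiparallel to their preceding strand (85% axis blend with
the barrel axis), anchored angularly between the preceding strand's top
and the following strand's bottom — the two points their flanking loops
must reach — and slid along their axis so both loop gaps stay within the
loops' arc budgets. Loops are cubic Béziers with an outward/vertical
bulge sized by bisection so the equal-chord resampled path carries the
loop's residues at ~3.8 Å spacing; top loops bow up-and-out, bottom
turns straight down, single-wall crossovers radially.

Twofold blueprints come out *exactly* screw-symmetric (repeat RMSD at
float precision) because every step — elliptic arc mapping (quadrant
symmetries enforced analytically), frames, loop routing — is equivariant
under rotation about the barrel axis; the C-terminal tail is placed as
the screw image of the repeat-1 closing turn. The generated barrel is
therefore pseudo-cyclic: the tail ends where a peptide bond to residue 1
would be, and the clash check exempts that seam pair.

**Closure errors.** Odd total shear is rejected (the pleat parity cannot
close), as are blueprints where some junction's strands share no ladder
rung and loops that cannot span their gaps.

**Autoregressive search** is a generic greedy phase-wise argmax over
candidate element lengths with the prefix frozen, ties resolved to the
smallest length (warned). It equals exhaustive search for separable
scores and on single slots; nothing about it is specific to barrel
scoring.

## Structure analysis

**Strand assignment.** A residue is *extended* when its Cα(i−1)–Cα(i+1)
span is ≥ 6 Å. Ladder hydrogen bonds are O···N pairs ≤ 3.5 Å between
extended residues ≥ 6 apart in sequence whose N lies within 60° of the
carbonyl direction. Strands are maximal runs of H-bonding residues,
bridged across single extended gap residues; short remnants (a
register-shift-2 junction can leave a strand exactly one ladder
carbonyl) are rescued when they make ≥ 2 ladder bonds into an
established strand, padded with extended neighbours to the three-residue
minimum. Strands are ordered around the barrel by ladder connectivity;
a closed cycle marks a closed barrel. A user-supplied assignment
overrides detection.

**Axis and cross-section.** The axis is the mean of per-strand Cα line
directions (individual tilts cancel around the barrel; rigid-motion
equivariant). Strand Cα coordinates are projected onto the normal plane;
midpoints of consecutive Cα (which cancel the pleat) are filtered
against each strand's median radius (±1.2 Å, robust to frayed ends) and
fed to a direct least-squares ellipse fit. Eccentricity is
`√(1−(b/a)²)`; per-strand radius is the median radial distance of the
strand's Cα projections. Face labels follow curvature: the half of the
strands nearest (in parametric angle) the major-axis vertices — where
the radius of curvature `b²/a` is smallest — are *minor*-face strands,
the flat co-vertex arcs *major*. A quota rather than a fixed curvature
threshold is used because on a 13:9 ellipse with eight strands the tight
faces host one strand plus two shoulder strands each.

**Shear from structure.** For each junction the register offset is the
modal within-strand index difference between nearest-Cα partners
(≤ 5.6 Å); the shear is the sum over one full traversal. On generated
structures this equals the blueprint's `Σ r_j` for every preset.

**Small-residue enrichment.** Mean side-chain volume (standard mean
residue volumes) at minor-face strip positions versus all strip
positions; significance by one-sided label permutation (≥ 1000
permutations, seeded).

**Superposition.** Closed-form least-squares rigid superposition (SVD
with determinant correction). Repeat symmetry superposes repeat-1 Cα
onto repeat-2 Cα. Under isotropic Gaussian coordinate noise of sd σ the
RMSD approaches σ√3, which the tests use as a Monte-Carlo oracle.

## ILV clusters

Contacts are residue pairs (not atom pairs) of Ile/Leu/Val side-chain
heavy atoms within 4.5 Å; each carries a pairwise buried area from the
two-body solvent-accessible-surface difference
(SASA(i) + SASA(j) − SASA(i∪j), 1.4 Å probe, Shrake–Rupley with 960
sphere points, side-chain atoms only). Clusters are connected components
of the contact graph above an area threshold (default 10 Å², a
configuration point because reference contact-surface implementations
normalize differently). Totals obey
`area_per_contact = total_area / total_contacts`. Raising the threshold
never adds contacts or merges clusters. An extended mode adds
Ala/Met/Phe.

Generated fixtures carry idealized side-chain pseudo-atoms (CG/CD placed
tetrahedrally beyond Cβ) so cluster analysis has heavy atoms to work
with; absolute buried areas of these pseudo-side-chains are larger than
those of real rotamers, so only counts, connectivity and identities —
not absolute areas — are meaningful on fixtures.

## Two-state unfolding

Signal model (linear-extrapolation / Santoro–Bolen form):

    y(x) = [(a_f + b_f x) + (a_u + b_u x) K(x)] / [1 + K(x)],
    K(x) = exp(−(ΔG − m x)/RT)

with ΔG the folding free energy at 0 M (positive = stable), m the
denaturant dependence, Cm = ΔG/m the midpoint. Fits are nonlinear least
squares over all six parameters; standard errors from the covariance.
Initialization: baselines from the first/last three points, Cm₀ at the
half-signal point, m₀ = 4RT/(quarter of the sampled range). Temperature
fixed at 298.15 K (RT = 0.5925 kcal/mol), configurable. If the optimum
lands on the sign-degenerate branch (m < 0) it is flipped to the
cooperative one. Noiseless curves invert exactly; at 1% noise the median
over 20 seeds recovers ΔG and m within 5%. The fit is invariant to
affine rescaling of the signal axis.

Thermal melts report the fractional signal change to the final
temperature and fit an apparent midpoint only when the relative change
exceeds 20% of the signal scale — hyperstable designs that stay folded
to 95 °C report "no complete transition".

## Iterative-enrichment design

Position classes (hydrophobic / boundary / solvent-exposed) come from an
automatic surrogate combining self-normalized side-chain exposure
(in-context SASA over the isolated-residue reference; thresholds 0.25
and 0.55) with the Cβ direction relative to the fitted barrel axis
(strand residues aiming at the axis are hydrophobic class). Overrides
are accepted verbatim.

The loop interleaves (1) `n_traj` independent seeded Metropolis
trajectories (single-site proposals, T = 1, 100 steps per designable
position, spawned substreams) against a pluggable energy, (2) per-position
frequency profiling, and (3) alphabet restriction to residues observed
at frequency ≥ `min_frequency` (default 0: observed at least once),
intersected with the current alphabet so alphabets never grow. Phases
design hydrophobic+boundary first with exposed positions held constant,
then the exposed positions; a phase stops when the mean per-position
Shannon entropy changes by < 0.01 nats or the round limit is reached.
A curation predicate can filter sequences before profiling. The supplied
toy energy rewards hydrophobic complementarity on contacting position
pairs and penalizes volumes above per-position cavity budgets taken from
the generating model — the loop's logic, not the physics, is the point.

## Synthetic data: what it does and does not emulate

Presets (`ovoid`, `circular`, `zero_shear_toy`, `porin_like`) are
deterministic geometric idealizations with designed sequences: ILV cores
on the long-strand faces, small residues (with A93/A207-style alanines)
on the minor faces, Thr exteriors, Leu/Ala/Glu/Lys helices, Gly/Ser
loops, exactly twofold sequences on the ovoid preset. Decoys add
Gaussian coordinate noise, flip a strand's facing parity
(sequence/labels only — backbone untouched, so geometric classification
flags the mismatch), or delete a strand. Variant builders implement the
polar variants (PV1 = I60K+I174A, PV2 = I174E, PV3 = I60K+I174E,
PV4 = C4S, PV5 = A93K+L148A) and hollow variants (layer sets ablated to
Ala with the repeat partner auto-applied at offset 114). The exact layer
membership of the published hollow variants is figure-only data; the
builders take the blueprint's layer enumeration, with explicit position
lists accepted as overrides.

Passing tests on these fixtures demonstrates the *machinery* —
arithmetic, geometry, detection, fitting, statistics — not that real
crystal structures would give the same numbers: idealized backbones have
perfect ladders and symmetric repeats, pseudo-side-chains overstate
buried areas, and curve panels use homoscedastic Gaussian noise.

## Known limitations

- No physical energy function: generated models are geometric
  idealizations; designed toy sequences are not claimed expressible.
- Strand detection assumes parallel barrels with idealized O placement;
  heavily distorted or antiparallel sheets may need the assignment
  override.
- The porin-like preset is walls-only (no crossover loops); real porins
  are antiparallel, which the generator does not model.
- Cluster areas on fixtures are comparable within a run, not against
  experimental contact-surface numbers, whose normalization differs and
  would need threshold calibration against a reference structure.
- The fourfold circular preset uses shorter helices (10) and its own
  loop budget; it shares all invariants but is not a residue-accurate
  model of any published circular design.
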