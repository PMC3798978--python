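# Methods

## The system

Hin inverts a chromosomal DNA segment flanked by two 26-bp *hix* sites. The
reaction requires the 65-bp recombinational enhancer — two Fis dimer
binding sites with centers 47 bp apart — bound in *cis* on negatively
supercoiled DNA, normally ~100 bp from one *hix* site. The active complex
(the invertasome) assembles at a plectonemic branch: four Hin subunits
synapse the two *hix* sites while both Fis dimers contact the DBDs of the
two enhancer-proximal subunits through their β-hairpin arms, and the
helix-B basic patches of those same subunits clamp the enhancer DNA between
the Fis sites. Strand exchange proceeds by 180° rotation of one subunit
pair about the flat tetramer interface.

This package models that system at three levels: duplex DNA from base-pair
step parameters, rigid-body protein placement against distance constraints,
and closed-curve topology of the recombination substrate and products.

## DNA from step parameters

A base pair is an orthonormal frame (origin; x into the major groove, z
along helix advance). Step `i → i+1` applies the mid-step-triad
composition: rotation `Rz(ω/2−φ)·Ry(Γ)·Rz(ω/2+φ)` with `Γ = √(ρ²+τ²)`,
`φ = atan2(τ, ρ)` (ω twist, ρ roll, τ tilt), and the (shift, slide, rise)
displacement expressed in the half-way frame. The scheme is exactly
invertible; `analyze_duplex(build_duplex(P)) = P` to numerical precision,
except within ~1e-7 rad of zero bend where the ZYZ split is
ill-conditioned and the step is reported as unbent.

Defaults: twist 34.2° (mean of protein-bound DNA), rise 3.4 Å. The
composition above is the documented convention implemented by the standard
DNA-rebuild tools. Backbone
geometry is reduced to one pseudo-phosphate per strand per base pair at
cylindrical radius 8.9 Å, phase ±77° from the bp x-axis — enough for
distance and footprint logic without an all-atom model.

The enhancer is composed of two 21-bp site-parameter blocks inserted at the
configured centers with mean-B-DNA steps elsewhere. Two 21-bp blocks with
centers 47 bp apart necessarily overhang a 65-bp element by two steps per
end; the overhanging steps are clipped at the boundary (the 15-bp cores,
which carry all site-specific logic, lie fully inside). The synthetic site
block distributes the configured per-site bend (default 65°, a declared
parameter, not a measured value) as roll/tilt phased against the
accumulated twist, so each site bends in a plane; the ~167° phase
difference between the two sites (47 bp × 34.2° mod 360°) makes the built
element S-shaped rather than U-shaped.

## Assembly construction

Docking of this complex has historically been done by hand; here the pose
is constructed deterministically from the enhancer geometry and checked against hard
contracts (an alternative seeded hill-climbing refiner,
`refine_by_constraints`, handles perturbed inputs).

* Fis dimers sit on the concave faces of their bent sites (body center
  11 Å off the axis), arms toward the complex.
* The synapse frame is the enhancer's best-fit plane normal (the S is
  nearly planar); its sign is the choice that makes the trapped nodes
  negative, the configuration compatible with negative supercoiling.
* Each *hix* duplex runs from just above its Fis arm tip (where the DBD of
  the enhancer-proximal subunit grips half-site *hix1L* or *hix2R*) steeply
  across the element, so each duct crosses the enhancer in projection —
  the two (−) nodes.
* Hin subunits are toy domains (one point per landmark residue: DBD
  helix-1 region 146–160 around the grip point; catalytic domain with the
  helix-B row 47/48/51/54 about 56 Å away — the real subunit spans ~70 Å).
  The two enhancer-proximal subunits orient helix-B toward the enhancer;
  the assembly state moves the catalytic domain along that axis
  (0 / 8 / 20 Å for cleaved / pre-cleaved / dimer-docked), which gives the
  observed progression of helix-B–enhancer distances (~3 Å → ~10 Å →
  ~20 Å at residue 47).

Accepted assemblies must satisfy: arm-tip-to-DBD(155) ≤ 6 Å for exactly
the *hix1L*/*hix2R* subunits (the crosslinking asymmetry), Fis
DNA-binding landmarks on their sites, and >0.5 Å between all protein
components. The 6 Å landmark cutoff absorbs side-chain reach that a
residue-point model cannot represent; crosslink checks add a 3 Å
tolerance to the spacer length for the same reason. FeBABE scission reach
is tether (12 Å) + radical diffusion radius (10 Å, a declared free
parameter); predicted intensity is distance rank only — no chemistry.

## Topology

Writhe and linking numbers use the exact solid-angle formula per segment
pair, so values converge at the modeled resolution and linking integrals
round to integers with residuals ≪ 0.1. Nodes are transversal crossings of
labeled segments in a generic projection with right-handed signs;
degenerate projections are perturbed and retried. Knot determinants come
from the Gauss code of a generic diagram via the Alexander matrix at
t = −1 (crossing relation `2·x_over − x_in − x_out = 0`, one row and
column deleted); `reduced_crossing_number` applies Reidemeister I/II
reduction over several projections and is an upper bound that is tight for
the clean product curves used here.

### The branched substrate and subunit rotation

The substrate model is a closed labeled curve built around a vertical
synapse axis: two recombinase-bound columns (the *hix* sites) rise through
the cut plane; their upper halves continue through two leashes to the
invertible-domain loop (the head); the head wraps once around the static
enhancer stem at the branch base; the vector domain closes the circle
through explicit plectonemic coils. The head-around-stem wrap *is* the
pair of (−) nodes — and it is also the topological anchor that locks
rotation-injected twist into knots.

`simulate_rotation(s, n)` turns everything above the cut plane by n·180°
about the synapse axis; the winding is laid down as a helical sweep in the
leashes, and the ends reseal — recombinant for odd n (the invertible
domain, including the enhancer, is traversed in the reversed direction),
parental for even n. The rotation handedness and wrap handedness are fixed
to the supercoil-relaxing direction: the unique combination for which the
first exchange is unknotted and further rounds walk the twist-knot ladder
(determinants 3, 5, 7 = trefoil, figure-eight, 5₂), matching the
experimentally characterized processive products.

### Linking-number bookkeeping

`delta_linking` = round(Wr(product) − Wr(substrate)) (Gauss sums on the
modeled curves; the rigid-axis approximation takes the axis twist as
unchanged by the rigid-body sweep) plus the duplex-twist re-registration of
recombinant religation: when the half-sites reseal in the inverted
orientation, each of the two joints absorbs half a helical turn (+1 turn
total, sign set by the relaxing direction). For the single exchange this
gives ΔLk = +4 — loss of four negative supercoils — composed of the two
trapped branch nodes inverting with the invertible domain (+4), the
half-turn of interdomainal winding (−1), and the religation term (+1).

ΔLk of processive products is parity-resolved, not linear in n: every odd
(inverting) round shows the full +4 while even (parental) rounds return to
a constant small offset. This is forced by the geometry — the writhe
change of a cut-rotate-reseal surgery is an odd mutual-twist term plus
even sign-flip terms, so a linear law with increment 4 is impossible — and
it is consistent with the knot ladder, which traps only one additional
node per round. The mechanism test suite asserts the parity-resolved law.

### Problem sizes

Default curves use ~130 points (segment-pair sums are O(N²) but
millisecond-scale); duplex models are 21–65 bp; the mechanism suite runs
rotations n = 0..6. These sizes keep every computed invariant stable under
refinement (the writhe refinement test doubles the resolution tenfold).

## What the synthetic fixtures do and do not show

The generators emulate the *study conditions*: a 65-bp enhancer with
47-bp center spacing and 15-bp cores, 99-bp native enhancer–*hix* spacing
(the long-spacer substrate is the same geometry with different bp
bookkeeping, since curve shape carries no bp scale), per-site bend 65°,
and landmark residues at the positions probed by crosslinking
(Fis 16/19/20/21/22/71/98; Hin 28/47/48/51/54/101/107/146–160). Toy
components are residue-level point clouds whose internal geometry was
co-designed with the assembly so that the published contact pattern is
realizable; real structure templates can replace them through the landmark
sidecar without code changes. Passing tests therefore demonstrate the
internal consistency of the model-building and topology machinery against
the published constraint pattern — not that the toy coordinates reproduce
actual crystal structures, crosslinking efficiencies, or reaction rates.

## Known limitations

* No all-atom DNA or side chains; no energetics, electrostatics, or
  flexible docking.
* Exact docked poses are implementation-defined subject to the constraint
  contracts; the published pose is specified only qualitatively.
* Knot identification is limited to the determinant plus reduced crossing
  count — enough to separate the unknot/trefoil/figure-eight-class ladder,
  not a full polynomial table.
* bp lengths of substrate segments are bookkeeping, so loop-size effects
  on rotation processivity (torsional strain in the short loop) are out of
  scope.
* The enhancer sequence is a synthetic stand-in (the natural sequence is
  shown only graphically in the source data); A/T-richness of the central
  segment is emulated, position by position identity is not.
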