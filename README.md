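# invertasome

Structural modeling and DNA-topology analysis of the Hin/Fis invertasome —
the tripartite nucleoprotein complex in which a serine-recombinase tetramer
bound to two *hix* sites engages the Fis-bound recombinational enhancer at
the branch of a negatively supercoiled plasmid and inverts the intervening
DNA by 180° subunit rotation.

The package is a library for researchers modeling site-specific
recombination complexes against biochemical constraints. It provides:

* **DNA model building** from base-pair step parameters (shift, slide,
  rise, tilt, roll, twist) with the standard mid-step-triad composition,
  including the 65-bp two-Fis-site enhancer whose 21-bp site blocks bend
  the axis and fold the element into an S.
* **Constraint-guided docking**: Kabsch superposition, placement of protein
  units on DNA models, and a deterministic construction of the three
  invertasome assembly states (dimer-docked, pre-cleaved, DNA-cleaved),
  validated against crosslinker spacer-length constraints and
  tethered-nuclease (FeBABE) footprint geometry.
* **DNA topology**: writhe and linking numbers by exact per-segment Gauss
  integrals, signed node counting in planar projections, knot determinants
  |Δ(−1)| from Gauss codes, and a simulator of processive subunit rotation
  whose products reproduce the experimental knot ladder — unknotted
  inversion after one exchange, then trefoil, figure-eight, and the 5₂
  twist knot.

The core quantities follow the standard supercoiling calculus
Lk = Tw + Wr: writhe is the discretized Gauss double integral
Wr = (1/4π)∮∮ (t₁×t₂)·r̂/|r|² ds₁ds₂ over the modeled axis curve, nodes
are signed crossings under the right-hand convention, and the knot
determinant is the Alexander polynomial evaluated at −1, computed from the
crossing relations 2·x_over = x_in + x_out of a generic planar diagram.

## Worked example

```
$ python examples/rotation_topology.py
substrate: 2 hix/enhancer nodes, signs [-1, -1], writhe -0.72

 n orientation determinant   dLk
 0    parental           1    +0
 1    inverted           1    +4
 2    parental           3    -1
 3    inverted           5    +4
 4    parental           7    -1
```

The branched substrate traps two negative nodes where the *hix*-bearing DNA
crosses the enhancer — the signature of invertasome assembly at a branch on
negatively supercoiled DNA. One 180° rotation produces the unknotted
inverted circle (determinant 1) with a linking-number change of +4, i.e.
loss of four negative supercoils. Processive rotations trap one extra node
per round: determinant 3 is the trefoil, 5 the figure-eight, 7 the 5₂
twist knot.

The other example scripts cover enhancer building
(`build_enhancer.py`), state assembly (`dock_invertasome.py`), crosslink
scoring (`crosslink_scoring.py`) and footprint prediction
(`febabe_footprint.py`); each prints the numbers it computes and a line on
what they mean.

A thin CLI wraps the same library:

```
invertasome run --out results/ --state cleaved --rotations 4
invertasome topology --rotations 4
invertasome validate --config run.yaml
```

## Layout

```
src/invertasome/
  dna.py         step parameters, duplex building/analysis, enhancer layout
  structure.py   atom sets, rigid transforms, strict PDB + landmark sidecar I/O
  docking.py     superposition, site docking, invertasome assembly, refinement
  constraints.py crosslink scoring, FeBABE footprints, basic-patch contacts
  topology.py    writhe/linking/nodes/knots, subunit-rotation simulation
  synthetic.py   fixture generators (bent site blocks, toy components, substrate)
  pipeline.py    end-to-end driver; cli.py: command-line interface
docs/methods.md  the model, its assumptions, parameters, and limitations
examples/        one narrative script per capability
```
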