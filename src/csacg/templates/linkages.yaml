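# Glycosidic linkage terms inserted across every residue junction.
#
# "d:" refers to a bead of the donor residue (lower index), "a:" to the
# acceptor residue (higher index).  Bonds/angles harmonic; dihedrals a
# single periodic term.  Values are shipped defaults and editable.
beta13:                      # GLA(i) -> GAL(i+1)
  bond: {beads: ["d:GL1", "a:GA2"], length: 0.370, k: 7000.0}
  angles:
    - {beads: ["d:GL2", "d:GL1", "a:GA2"], theta: 108.0, k: 70.0}
    - {beads: ["d:GL1", "a:GA2", "a:GA1"], theta: 112.0, k: 70.0}
  dihedrals:
    - {beads: ["d:GL2", "d:GL1", "a:GA2", "a:GA1"], phi: 30.0, k: 5.0, mult: 1}
beta14:                      # GAL(i) -> GLA(i+1)
  bond: {beads: ["d:GA1", "a:GL2"], length: 0.360, k: 7000.0}
  angles:
    - {beads: ["d:GA2", "d:GA1", "a:GL2"], theta: 105.0, k: 70.0}
    - {beads: ["d:GA1", "a:GL2", "a:GL1"], theta: 118.0, k: 70.0}
  dihedrals:
    - {beads: ["d:GA2", "d:GA1", "a:GL2", "a:GL1"], phi: -40.0, k: 5.0, mult: 1}
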