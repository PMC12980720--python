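# Terminal ("w") glucuronic acid residue template.
#
# Cross-residue junction atoms are dropped and both glycosidic positions
# are capped with hydroxyls (O1/HO1 at the anomeric carbon, HO4 at O4).
# When mapping real chain-end coordinates, prune the cap that is absent
# on the linked side; this file is editable data, not fixed chemistry.
residue: GLA
variant: terminal
beads:
  - name: GL1
    type: SP4r
    size: small
    charge: 0.0
    atoms: [C1, H1, C2, H2, O2, HO2, O1, HO1]
    xyz: [0.000, 0.202, 0.000]
  - name: GL2
    type: SP1r
    size: small
    charge: 0.0
    atoms: [C3, H3, O3, HO3, C4, H4, O4, HO4]
    xyz: [-0.175, -0.101, 0.000]
  - name: GL3
    type: SQ5n
    size: small
    charge: -1.0
    atoms: [C5, H5, O5, C6, O61, O62]
    xyz: [0.175, -0.101, 0.000]
virtual_site:
  name: GLV
  type: TC4
  size: tiny
ring_beads: [GL1, GL2, GL3]
ring_atoms: [C1, C2, C3, C4, C5, O5]
constraints:
  - {beads: [GL1, GL2], length: 0.374, ring: true}
  - {beads: [GL2, GL3], length: 0.396, ring: true}
  - {beads: [GL1, GL3], length: 0.352, ring: true}
bonds: []
angles: []
dihedrals: []
ports:
  b13_donor: GL1
  b14_acceptor: GL2
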