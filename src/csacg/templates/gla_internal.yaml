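# Internal ("w/o") glucuronic acid residue template.
#
# Mapped atom names follow carbohydrate conventions (ring C1..C5, ring
# oxygen O5, carboxylate C6/O61/O62).  A leading "-"/"+" marks a junction
# atom owned by the previous/next residue: the beta-1,4 acceptor bead
# covers the anomeric C1/H1 of the preceding GAL so that the glycosidic
# junction is represented at full C-O-C resolution inside the bead.
# Coordinates (nm) are a local-frame starting guess, not a prediction.
residue: GLA
variant: internal
beads:
  - name: GL1          # C1-C2 ring fragment, beta-1,3 donor side
    type: SP4r
    size: small
    charge: 0.0
    atoms: [C1, H1, C2, H2, O2, HO2]
    xyz: [0.000, 0.202, 0.000]
  - name: GL2          # C3-C4 ring fragment, beta-1,4 acceptor side
    type: SP1r
    size: small
    charge: 0.0
    atoms: [C3, H3, O3, HO3, C4, H4, O4, -C1, -H1]
    xyz: [-0.175, -0.101, 0.000]
  - name: GL3          # C5/O5 ring fragment carrying the carboxylate
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
constraints:            # ring-internal: constraints, never harmonic bonds
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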