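# Terminal ("w") N-acetyl-galactosamine-4-sulfate residue template.
residue: GAL
variant: terminal
beads:
  - name: GA1
    type: SP4r
    size: small
    charge: 0.0
    atoms: [C1, H1, C2, H2, O1, HO1]
    xyz: [0.000, 0.202, 0.000]
  - name: GA2
    type: SP1r
    size: small
    charge: 0.0
    atoms: [C3, H3, O3, C4, H4, O4]
    xyz: [-0.175, -0.101, 0.000]
  - name: GA3
    type: SP4r
    size: small
    charge: 0.0
    atoms: [C5, H5, O5]
    xyz: [0.175, -0.101, 0.000]
  - name: GAS
    type: Q4n
    size: regular
    charge: -1.0
    atoms: [S, O41, O42, O43]
    xyz: [-0.350, -0.200, 0.000]
  - name: GAN
    type: SP3a
    size: small
    charge: 0.0
    atoms: [N, HN, C7, O7, C8, H81, H82, H83]
    xyz: [0.000, 0.532, 0.000]
  - name: GA6
    type: TP1
    size: tiny
    charge: 0.0
    atoms: [C6, H61, H62, O6, HO6]
    xyz: [0.426, -0.246, 0.000]
virtual_site:
  name: GAV
  type: TC4
  size: tiny
ring_beads: [GA1, GA2, GA3]
ring_atoms: [C1, C2, C3, C4, C5, O5]
constraints:
  - {beads: [GA1, GA2], length: 0.374, ring: true}
  - {beads: [GA2, GA3], length: 0.385, ring: true}
  - {beads: [GA1, GA3], length: 0.363, ring: true}
bonds:
  - {beads: [GA2, GAS], length: 0.360, k: 5000.0}
  - {beads: [GA1, GAN], length: 0.330, k: 5000.0}
  - {beads: [GA3, GA6], length: 0.290, k: 6000.0}
angles:
  - {beads: [GA1, GA2, GAS], theta: 100.0, k: 70.0}
  - {beads: [GA2, GA1, GAN], theta: 115.0, k: 60.0}
  - {beads: [GA1, GA3, GA6], theta: 120.0, k: 50.0}
dihedrals: []
ports:
  b13_acceptor: GA2
  b14_donor: GA1
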