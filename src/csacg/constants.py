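"""Physical constants and force-field wide defaults.

Units throughout the package: nm, degrees, kJ/mol, unified atomic mass
units, elementary charge, Kelvin, bar.
"""

#: Boltzmann constant in kJ/mol/K (CODATA 2018).
KB = 0.00831446261815324

#: Reference temperature of the parametrization ensemble, K.
DEFAULT_TEMPERATURE = 303.15

#: Virtual-site bond length b_v used in the characteristic ratio, nm.
#: This is the reference monomer-monomer spacing of the chain model.
BOND_LENGTH_VIRTUAL = 0.52

#: Van der Waals radii of the bead size classes, nm.
CLASS_RADII = {"regular": 0.264, "small": 0.23, "tiny": 0.191}

#: Solvent probe radius for accessible-surface calculations, nm.
PROBE_RADIUS = 0.191

#: Standard bead masses by size class, u.  Virtual sites are massless.
CLASS_MASSES = {"regular": 72.0, "small": 54.0, "tiny": 36.0}

#: Conversion: mol/L -> particles/nm^3.
PARTICLES_PER_NM3_PER_MOLAR = 0.602214076
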