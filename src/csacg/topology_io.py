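"""Serialization of chain topologies and starting coordinates.

The topology writer emits an itp-dialect text with fixed section order
([moleculetype], [atoms], [bonds], [constraints], [angles], [dihedrals],
[virtual_sitesn], [exclusions]); all indices in serialized output are
1-based.  Per-atom mapping lists and ring flags are preserved in
comments so that re-parsing reproduces the topology exactly.

The structure writer places beads from the template internal coordinates
along a helical repeat -- an extended starting guess, not a prediction.
"""

from __future__ import annotations

import math

import numpy as np

from . import __version__
from .errors import ValidationError
from .topology import BeadSpec, BondedTerm, ChainTopology, IonScheme

_MASS_TO_CLASS = {72.0: "regular", 54.0: "small", 36.0: "tiny"}


def extended_coordinates(chain: ChainTopology,
                         twist_deg: float = 180.0) -> np.ndarray:
    """Starting coordinates (nm) for a chain: helical repeat along z.

    Residue ``i`` sits at ``z = (i-1) * b_v`` with its local template
    frame rotated by ``(i-1) * twist_deg`` about the chain axis; ring
    virtual sites are the centroids of their ring beads.
    """
    from .topology import load_templates
    templates = load_templates()
    coords = np.zeros((chain.n_beads, 3))
    for i in range(chain.n_monomers):
        tpl = templates[(chain.residue_names[i], chain.residue_variants[i])]
        off = chain.residue_bead_offsets[i]
        ang = math.radians(twist_deg * i)
        c, s = math.cos(ang), math.sin(ang)
        for k, (x, y, z) in enumerate(tpl.local_xyz):
            coords[off + k] = (c * x - s * y, s * x + c * y,
                               z + chain.b_v * i)
    for site, parents in chain.virtual_site_rules:
        coords[site] = coords[list(parents)].mean(axis=0)
    return coords


# -- itp dialect -------------------------------------------------------------

def write_itp(path, chain: ChainTopology, scheme: IonScheme | None = None):
    lines = [f"; generated by csacg {__version__}"]
    if scheme is not None:
        lines.append(f"; ion scheme: {scheme.electrostatics_hint} "
                     f"{scheme.ion_type_label} q=+-{scheme.ion_charge_magnitude}")
    lines += ["", "[ moleculetype ]", f"{chain.name} 1", "", "[ atoms ]"]
    for i, b in enumerate(chain.beads, start=1):
        res = chain.bead_resids[i - 1]
        atoms = ",".join(b.mapped_atoms)
        lines.append(
            f"{i:5d} {b.type_label:>6s} {res:5d} "
            f"{chain.residue_names[res - 1]:>4s} {b.name:>5s} {i:5d} "
            f"{b.charge:10.6f} {b.mass:10.6f} ; atoms: {atoms}")

    def section(header, kind, fmt):
        rows = [t for t in chain.terms if t.kind == kind]
        if not rows:
            return
        lines.extend(["", f"[ {header} ]"])
        for t in rows:
            lines.append(fmt(t))

    section("bonds", "bond", lambda t: (
        f"{t.bead_indices[0]+1:5d} {t.bead_indices[1]+1:5d} 1 "
        f"{t.equilibrium:10.6f} {t.force_constant:12.4f}"))
    section("constraints", "constraint", lambda t: (
        f"{t.bead_indices[0]+1:5d} {t.bead_indices[1]+1:5d} 1 "
        f"{t.equilibrium:10.6f}" + (" ; ring" if t.ring else "")))
    section("angles", "angle", lambda t: (
        " ".join(f"{k+1:5d}" for k in t.bead_indices) + " 2 "
        f"{t.equilibrium:10.4f} {t.force_constant:12.4f}"))
    section("dihedrals", "dihedral", lambda t: (
        " ".join(f"{k+1:5d}" for k in t.bead_indices) + " 1 "
        f"{t.equilibrium:10.4f} {t.force_constant:12.4f} "
        f"{t.multiplicity or 1:d}"))

    lines.extend(["", "[ virtual_sitesn ]"])
    for site, parents in chain.virtual_site_rules:
        lines.append(f"{site+1:5d} 1 " + " ".join(f"{p+1:d}" for p in parents))
    lines.extend(["", "[ exclusions ]"])
    for site, parents in chain.virtual_site_rules:
        lines.append(f"{site+1:5d} " + " ".join(f"{p+1:d}" for p in parents))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_itp(path) -> ChainTopology:
    """Parse an itp file written by :func:`write_itp`."""
    section = None
    atoms, terms, vrules = [], [], []
    with open(path) as fh:
        for raw in fh:
            line, _, comment = raw.partition(";")
            comment = comment.strip()
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            parts = line.split()
            if section == "atoms":
                mapped = ()
                if comment.startswith("atoms:"):
                    payload = comment[len("atoms:"):].strip()
                    mapped = tuple(payload.split(",")) if payload else ()
                atoms.append(dict(
                    type_label=parts[1], resid=int(parts[2]),
                    resname=parts[3], name=parts[4],
                    charge=float(parts[6]), mass=float(parts[7]),
                    mapped=mapped))
            elif section == "bonds":
                terms.append(BondedTerm(
                    "bond", (int(parts[0]) - 1, int(parts[1]) - 1),
                    float(parts[3]), float(parts[4])))
            elif section == "constraints":
                terms.append(BondedTerm(
                    "constraint", (int(parts[0]) - 1, int(parts[1]) - 1),
                    float(parts[3]), ring=(comment == "ring")))
            elif section == "angles":
                terms.append(BondedTerm(
                    "angle", tuple(int(p) - 1 for p in parts[:3]),
                    float(parts[4]), float(parts[5])))
            elif section == "dihedrals":
                terms.append(BondedTerm(
                    "dihedral", tuple(int(p) - 1 for p in parts[:4]),
                    float(parts[5]), float(parts[6]),
                    multiplicity=int(parts[7])))
            elif section == "virtual_sitesn":
                vrules.append((int(parts[0]) - 1,
                               tuple(int(p) - 1 for p in parts[2:])))
    if not atoms:
        raise ValidationError(f"no [atoms] section found in {path}")

    beads, resids = [], []
    for a in atoms:
        virtual = a["mass"] == 0.0
        size = "tiny" if virtual else _MASS_TO_CLASS[a["mass"]]
        beads.append(BeadSpec(name=a["name"], type_label=a["type_label"],
                              size_class=size, charge=a["charge"],
                              mass=a["mass"], is_virtual=virtual,
                              mapped_atoms=a["mapped"]))
        resids.append(a["resid"])
    n_res = max(resids)
    resnames, variants, offsets = [], [], []
    prev = None
    for k, r in enumerate(resids):
        if r != prev:
            offsets.append(k)
            resnames.append(atoms[k]["resname"])
            variants.append("terminal" if r in (1, n_res) else "internal")
            prev = r
    return ChainTopology(
        n_monomers=n_res, residue_names=tuple(resnames),
        residue_variants=tuple(variants), beads=tuple(beads),
        bead_resids=tuple(resids), terms=tuple(terms),
        virtual_site_rules=tuple(vrules),
        residue_bead_offsets=tuple(offsets))


def topologies_equal(a: ChainTopology, b: ChainTopology,
                     tol: float = 1e-9) -> bool:
    if (a.n_monomers, a.residue_names, a.bead_resids,
            a.virtual_site_rules) != (b.n_monomers, b.residue_names,
                                      b.bead_resids, b.virtual_site_rules):
        return False
    if len(a.beads) != len(b.beads) or len(a.terms) != len(b.terms):
        return False
    for x, y in zip(a.beads, b.beads):
        if (x.name, x.type_label, x.size_class, x.is_virtual,
                x.mapped_atoms) != (y.name, y.type_label, y.size_class,
                                    y.is_virtual, y.mapped_atoms):
            return False
        if abs(x.charge - y.charge) > tol or abs(x.mass - y.mass) > tol:
            return False
    # serialized term order is by section, so compare order-insensitively
    key = lambda t: (t.kind, t.bead_indices)
    for x, y in zip(sorted(a.terms, key=key), sorted(b.terms, key=key)):
        if (x.kind, x.bead_indices, x.ring, x.multiplicity) != \
                (y.kind, y.bead_indices, y.ring, y.multiplicity):
            return False
        if abs(x.equilibrium - y.equilibrium) > tol:
            return False
        if (x.force_constant is None) != (y.force_constant is None):
            return False
        if x.force_constant is not None and \
                abs(x.force_constant - y.force_constant) > tol:
            return False
    return True


# -- coordinate files --------------------------------------------------------

def write_gro(path, chain: ChainTopology, coords: np.ndarray,
              box: tuple[float, float, float] | None = None,
              title: str = "csacg starting structure"):
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (chain.n_beads, 3):
        raise ValidationError("coords shape does not match topology")
    if box is None:
        span = coords.max(axis=0) - coords.min(axis=0) + 2.0
        box = tuple(span)
    with open(path, "w") as fh:
        fh.write(f"{title}\n{chain.n_beads:5d}\n")
        for i, b in enumerate(chain.beads):
            res = chain.bead_resids[i]
            resname = chain.residue_names[res - 1]
            x, y, z = coords[i]
            fh.write(f"{res:5d}{resname:<5s}{b.name:>5s}{i+1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def read_gro(path):
    """Minimal gro reader; returns (resids, resnames, names, coords, box)."""
    with open(path) as fh:
        fh.readline()
        n = int(fh.readline())
        resids, resnames, names, coords = [], [], [], []
        for _ in range(n):
            line = fh.readline()
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords.append([float(line[20:28]), float(line[28:36]),
                           float(line[36:44])])
        box = tuple(float(v) for v in fh.readline().split()[:3])
    return resids, resnames, names, np.asarray(coords), box


def write_pdb(path, chain: ChainTopology, coords: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write("TITLE     csacg starting structure\n")
        for i, b in enumerate(chain.beads):
            res = chain.bead_resids[i]
            resname = chain.residue_names[res - 1]
            x, y, z = coords[i] * 10.0            # nm -> Angstrom
            fh.write(f"ATOM  {i+1:5d} {b.name:<4s}{resname:>4s} A"
                     f"{res:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
        fh.write("END\n")
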