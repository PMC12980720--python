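"""Forward mapping of atomistic ensembles onto coarse-grained beads.

Bead positions are unweighted centers of geometry of their member atoms;
ring virtual sites are centers of the six ring atoms.  Bonded-term time
series use the minimum image convention for distances when a box is
present, arccos of the normalized dot product for angles, and the
signed-atan2 dihedral with the cis = 0 deg, right-handed-positive
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensembles import BeadEnsemble, minimum_image
from .errors import DomainError, MappingError, ValidationError
from .topology import BondedTerm, ChainTopology


@dataclass
class AtomEnsemble:
    """Atomistic coordinates keyed by (residue index, atom name).

    ``atom_ids`` is a sequence of ``(resid, name)`` pairs (1-based
    residue indices) matching the columns of ``coordinates``
    ``(n_frames, n_atoms, 3)``.
    """

    atom_ids: tuple[tuple[int, str], ...]
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or \
                self.coordinates.shape[1] != len(self.atom_ids):
            raise ValidationError("coordinates shape must be "
                                  "(frames, len(atom_ids), 3)")

    def column(self, resid: int, name: str) -> int:
        try:
            return self._index[(resid, name)]
        except AttributeError:
            self._index = {aid: k for k, aid in enumerate(self.atom_ids)}
            return self.column(resid, name)
        except KeyError:
            raise MappingError(f"atom {name!r} of residue {resid} not found")


@dataclass(frozen=True)
class MappingEntry:
    bead_label: str
    resid: int
    atoms: tuple[str, ...]        # "-X"/"+X" reference the prev/next residue
    is_virtual: bool = False


@dataclass
class MappingTable:
    """Ordered atom->bead assignments; row order defines bead order."""

    entries: tuple[MappingEntry, ...]

    def resolve(self, ens: AtomEnsemble) -> list[list[int]]:
        cols = []
        for e in self.entries:
            row = []
            for a in e.atoms:
                resid, name = e.resid, a
                if a.startswith("-"):
                    resid, name = e.resid - 1, a[1:]
                elif a.startswith("+"):
                    resid, name = e.resid + 1, a[1:]
                try:
                    row.append(ens.column(resid, name))
                except MappingError:
                    raise MappingError(
                        f"bead {e.bead_label!r} (residue {e.resid}): atom "
                        f"{name!r} of residue {resid} missing from input")
            cols.append(row)
        return cols


def mapping_from_chain(chain: ChainTopology,
                       templates: dict | None = None) -> MappingTable:
    """Mapping table matching the bead order of a built chain."""
    from .topology import load_templates
    templates = templates if templates is not None else load_templates()
    entries = []
    for i in range(chain.n_monomers):
        tpl = templates[(chain.residue_names[i], chain.residue_variants[i])]
        resid = i + 1
        for b in tpl.beads:
            if b.is_virtual:
                entries.append(MappingEntry(b.name, resid, tpl.ring_atoms,
                                            is_virtual=True))
            else:
                atoms = tuple(a for a in b.mapped_atoms
                              if not ((a.startswith("-") and resid == 1) or
                                      (a.startswith("+") and
                                       resid == chain.n_monomers)))
                entries.append(MappingEntry(b.name, resid, atoms))
    return MappingTable(tuple(entries))


def map_frames(atom_ens: AtomEnsemble, table: MappingTable) -> BeadEnsemble:
    """Center-of-geometry mapping of every frame onto the table's beads."""
    cols = table.resolve(atom_ens)
    n_frames = atom_ens.coordinates.shape[0]
    out = np.empty((n_frames, len(cols), 3))
    for b, row in enumerate(cols):
        out[:, b, :] = atom_ens.coordinates[:, row, :].mean(axis=1)
    return BeadEnsemble(out, box=atom_ens.box, provenance="mapped")


# -- bonded-term geometry ----------------------------------------------------

def _displacement(ens: BeadEnsemble, i: int, j: int) -> np.ndarray:
    d = ens.coordinates[:, j, :] - ens.coordinates[:, i, :]
    if ens.box is not None:
        d = minimum_image(d, ens.box[0])
    return d


def distances(ens: BeadEnsemble, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(_displacement(ens, i, j), axis=-1)


def angles(ens: BeadEnsemble, i: int, j: int, k: int) -> np.ndarray:
    """Angle at bead j in degrees, in [0, 180]."""
    u = _displacement(ens, j, i)
    v = _displacement(ens, j, k)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu == 0) | (nv == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("fi,fi->f", u, v) / (nu * nv)
    out = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    out[bad] = np.nan
    return out


def dihedrals(ens: BeadEnsemble, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Signed dihedral in (-180, 180]: cis = 0, right-handed positive."""
    b1 = _displacement(ens, i, j)
    b2 = _displacement(ens, j, k)
    b3 = _displacement(ens, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) == 0) | \
          (np.linalg.norm(n2, axis=-1) == 0) | (nb2 == 0)
    x = np.einsum("fi,fi->f", n1, n2)
    y = np.einsum("fi,fi->f", np.cross(n1, n2), b2) / np.where(nb2 == 0, 1,
                                                               nb2)
    out = np.degrees(np.arctan2(y, x))
    out = np.where(out <= -180.0, out + 360.0, out)
    out[bad] = np.nan
    return out


@dataclass
class BondedSample:
    """Per-frame scalar values of one bonded term (nm or degrees)."""

    term: BondedTerm
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def extract_terms(ens: BeadEnsemble,
                  terms: list[BondedTerm]) -> list[BondedSample]:
    """Measure every term in every frame of a bead ensemble.

    Frames with degenerate geometry (zero-length vectors) are excluded
    from the affected term with a warning.
    """
    out = []
    for t in terms:
        idx = t.bead_indices
        if max(idx) >= ens.n_beads:
            raise DomainError(f"term {t.kind} {idx} exceeds bead count")
        if t.kind in ("bond", "constraint"):
            vals = distances(ens, *idx)
        elif t.kind == "angle":
            vals = angles(ens, *idx)
        else:
            vals = dihedrals(ens, *idx)
        bad = np.isnan(vals)
        if bad.any():
            warnings.warn(
                f"{t.kind} {idx}: {int(bad.sum())} degenerate frame(s) "
                f"excluded", stacklevel=2)
            vals = vals[~bad]
        out.append(BondedSample(term=t, values=vals))
    return out


# -- trajectory adapter ------------------------------------------------------

def atom_ensemble_from_files(topology_path, trajectory_path=None,
                             stride: int = 1) -> AtomEnsemble:
    """Read coordinates via MDAnalysis into an :class:`AtomEnsemble`.

    Accepts any pdb/gro topology and xtc/trr/dcd trajectory MDAnalysis
    understands.  Coordinates are converted to nm; the box, when
    present, is taken as orthorhombic lengths.
    """
    import MDAnalysis as mda

    paths = (topology_path,) if trajectory_path is None else \
        (topology_path, trajectory_path)
    u = mda.Universe(*paths)
    atom_ids = tuple((int(a.resid), a.name) for a in u.atoms)
    frames, boxes = [], []
    for ts in u.trajectory[::stride]:
        frames.append(u.atoms.positions / 10.0)        # Angstrom -> nm
        if ts.dimensions is not None and ts.dimensions[:3].all():
            boxes.append(ts.dimensions[:3] / 10.0)
    coords = np.asarray(frames)
    box = np.asarray(boxes) if len(boxes) == len(frames) and boxes else None
    return AtomEnsemble(atom_ids=atom_ids, coordinates=coords, box=box)
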