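"""In-memory conformer ensembles and their plain-text serialization.

A :class:`BeadEnsemble` is the package-wide container for coarse-grained
coordinates: a dense ``(n_frames, n_beads, 3)`` array in nm plus an
optional orthorhombic periodic box.  Synthetic generators, forward
mapping, and all analysis modules exchange this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError


@dataclass
class BeadEnsemble:
    """Time series (or chain collection) of bead coordinates.

    Parameters
    ----------
    coordinates
        Array of shape ``(n_frames, n_beads, 3)`` in nm.
    box
        Optional per-frame orthorhombic box lengths, shape ``(n_frames, 3)``
        or ``(3,)`` (broadcast to all frames), in nm.
    provenance
        One of ``mapped``, ``simulated``, ``synthetic``.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    provenance: str = "synthetic"
    labels: tuple[str, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise ValidationError(
                f"coordinates must have shape (frames, beads, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.ndim == 1:
                box = np.broadcast_to(box, (self.n_frames, 3)).copy()
            if box.shape != (self.n_frames, 3):
                raise ValidationError("box must have shape (frames, 3) or (3,)")
            if np.any(box <= 0):
                raise DomainError("box lengths must be positive")
            self.box = box

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` has ``(..., 3)`` shape; ``box`` is ``(3,)`` orthorhombic
    lengths or None (open boundaries).
    """
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


# -- plain-text round trip ---------------------------------------------------

def write_ensemble_csv(path, ens: BeadEnsemble) -> None:
    """Write an ensemble to a self-describing CSV (frame, bead, x, y, z)."""
    with open(path, "w") as fh:
        fh.write(f"# csacg ensemble frames={ens.n_frames} beads={ens.n_beads} "
                 f"provenance={ens.provenance}\n")
        if ens.box is not None:
            bx = ens.box[0]
            fh.write(f"# box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
        fh.write("frame,bead,x,y,z\n")
        for f in range(ens.n_frames):
            for b in range(ens.n_beads):
                x, y, z = ens.coordinates[f, b]
                fh.write(f"{f},{b},{x:.6f},{y:.6f},{z:.6f}\n")


def read_ensemble_csv(path) -> BeadEnsemble:
    box = None
    provenance = "synthetic"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# box"):
                    box = np.array([float(v) for v in line.split()[2:5]])
                elif "provenance=" in line:
                    provenance = line.rsplit("provenance=", 1)[1].split()[0]
                continue
            if line.startswith("frame,"):
                continue
            f, b, x, y, z = line.split(",")
            rows.append((int(f), int(b), float(x), float(y), float(z)))
    if not rows:
        raise ValidationError(f"no coordinate rows in {path}")
    n_frames = max(r[0] for r in rows) + 1
    n_beads = max(r[1] for r in rows) + 1
    coords = np.full((n_frames, n_beads, 3), np.nan)
    for f, b, x, y, z in rows:
        coords[f, b] = (x, y, z)
    if np.isnan(coords).any():
        raise ValidationError(f"incomplete frame/bead grid in {path}")
    return BeadEnsemble(coords, box=box, provenance=provenance)
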