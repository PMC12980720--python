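"""Surface exposure, contacts, radial distributions, rupture forces.

SASA uses a deterministic Shrake-Rupley-style sphere-point quadrature
with a fixed generated point set (default 960 points per particle).
The multi-chain exposure ratio S_tot / sum_a S_a equals one for
non-contacting chains and decreases toward zero on aggregation.
Contacts use a strict minimum-distance criterion (< 0.45 nm default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import PROBE_RADIUS
from .ensembles import BeadEnsemble, minimum_image
from .errors import DomainError, ValidationError

DEFAULT_SPHERE_POINTS = 960


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _dedupe(coords: np.ndarray, radii: np.ndarray, tol: float = 1e-9):
    """Drop exactly coincident particles of identical radius, so shared
    surface is not double-counted."""
    keep = np.ones(len(coords), dtype=bool)
    for i in range(len(coords)):
        if not keep[i]:
            continue
        same = (np.linalg.norm(coords - coords[i], axis=1) < tol) & \
               (np.abs(radii - radii[i]) < tol)
        same[: i + 1] = False
        keep[same] = False
    return coords[keep], radii[keep], keep


def sasa(coords, radii, probe: float = PROBE_RADIUS,
         n_points: int = DEFAULT_SPHERE_POINTS):
    """Solvent-accessible surface area, nm^2.

    Returns ``(total, per_particle)``; the per-particle array is on the
    original particle order (coincident duplicates score zero).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise DomainError("coords must be (n, 3)")
    if radii.shape != (len(coords),):
        raise DomainError("one radius per particle required")
    if np.any(radii <= 0) or probe <= 0:
        raise DomainError("radii and probe must be positive")

    per_full = np.zeros(len(coords))
    kept_coords, kept_radii, keep = _dedupe(coords, radii)
    unit = _fibonacci_sphere(n_points)
    ext = kept_radii + probe
    areas = np.zeros(len(kept_coords))
    for i in range(len(kept_coords)):
        d = np.linalg.norm(kept_coords - kept_coords[i], axis=1)
        neigh = np.nonzero((d < ext + ext[i]) &
                           (np.arange(len(kept_coords)) != i))[0]
        pts = kept_coords[i] + ext[i] * unit
        if neigh.size:
            dist = np.linalg.norm(pts[:, None, :] -
                                  kept_coords[neigh][None, :, :], axis=2)
            accessible = np.all(dist >= ext[neigh][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    per_full[keep] = areas
    return float(areas.sum()), per_full


@dataclass
class ExposureResult:
    """Per-frame multi-chain surface exposure."""

    s_tot: np.ndarray               # nm^2 per frame
    s_each: np.ndarray              # (frames, chains) isolated-chain SASA
    ratio: np.ndarray               # s_tot / sum(s_each) per frame


def exposure_ratio(ens: BeadEnsemble, chain_ids, radii,
                   probe: float = PROBE_RADIUS,
                   n_points: int = DEFAULT_SPHERE_POINTS) -> ExposureResult:
    """S_tot over all chains vs the sum of isolated single-chain SASAs.

    Each per-chain area S_a is computed with all other chains deleted
    (true isolated-chain SASA).
    """
    chain_ids = np.asarray(chain_ids)
    radii = np.asarray(radii, dtype=float)
    chains = np.unique(chain_ids)
    if chains.size < 2:
        raise DomainError("exposure ratio needs at least two chains")
    s_tot = np.empty(ens.n_frames)
    s_each = np.empty((ens.n_frames, chains.size))
    for f in range(ens.n_frames):
        xyz = ens.coordinates[f]
        s_tot[f], _ = sasa(xyz, radii, probe, n_points)
        for c, cid in enumerate(chains):
            m = chain_ids == cid
            s_each[f, c], _ = sasa(xyz[m], radii[m], probe, n_points)
    return ExposureResult(s_tot=s_tot, s_each=s_each,
                          ratio=s_tot / s_each.sum(axis=1))


@dataclass(frozen=True)
class ContactSpec:
    cutoff: float = 0.45            # nm, strict less-than

    def __post_init__(self):
        if self.cutoff <= 0:
            raise DomainError("cutoff must be positive")


def contacts(group_a, group_b, spec: ContactSpec = ContactSpec(),
             box=None) -> int:
    """Number of cross-group bead pairs closer than the cutoff
    (minimum-image distance, strict ``<``)."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise DomainError("contact groups must be non-empty")
    delta = minimum_image(a[:, None, :] - b[None, :, :], box)
    d = np.linalg.norm(delta, axis=-1)
    return int(np.count_nonzero(d < spec.cutoff))


def contacts_series(ens: BeadEnsemble, idx_a, idx_b,
                    spec: ContactSpec = ContactSpec()) -> np.ndarray:
    out = np.empty(ens.n_frames, dtype=int)
    for f in range(ens.n_frames):
        box = ens.box[f] if ens.box is not None else None
        out[f] = contacts(ens.coordinates[f, idx_a],
                          ens.coordinates[f, idx_b], spec, box)
    return out


def rdf(ens: BeadEnsemble, reference_idx, selection_idx,
        r_max: float, dr: float):
    """Radial distribution function g(r), ideal-gas normalized.

    Requires a periodic box (for the density normalization); distances
    use the minimum image.  Returns ``(r_centers, g)``.
    """
    if ens.box is None:
        raise DomainError("rdf requires a periodic box")
    ref = np.asarray(reference_idx, dtype=int)
    sel = np.asarray(selection_idx, dtype=int)
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(edges.size - 1)
    n_pairs_norm = 0.0
    same = np.intersect1d(ref, sel).size > 0
    block = max(1, int(2e6 // max(1, sel.size)))   # bound pair-matrix memory
    for f in range(ens.n_frames):
        box = ens.box[f]
        volume = float(np.prod(box))
        b = ens.coordinates[f, sel]
        for start in range(0, ref.size, block):
            chunk = ref[start:start + block]
            a = ens.coordinates[f, chunk]
            delta = minimum_image(a[:, None, :] - b[None, :, :], box)
            d = np.linalg.norm(delta, axis=-1)
            if same:
                d = d[chunk[:, None] != sel[None, :]]
            else:
                d = d.ravel()
            counts += np.histogram(d, edges)[0]
        n_sel_eff = sel.size - 1 if same else sel.size
        n_pairs_norm += ref.size * n_sel_eff / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (shell * n_pairs_norm)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, g


@dataclass(frozen=True)
class RuptureSpec:
    distance_threshold: float = 5.0     # nm
    window: float = 10.0                # total width, time units of the trace

    def __post_init__(self):
        if self.distance_threshold <= 0 or self.window <= 0:
            raise DomainError("threshold and window must be positive")


@dataclass
class RuptureResult:
    ruptured: bool
    t_open: float | None = None
    f_rupture: float | None = None


def rupture(time, force, distance,
            spec: RuptureSpec = RuptureSpec()) -> RuptureResult:
    """Rupture force from a pulling trace.

    ``t_open`` is the first sample where the distance reaches the
    threshold; ``f_rupture`` the maximal force within a centered window
    of total width ``spec.window`` around that time.  A trace that
    never crosses the threshold returns a flagged no-rupture result.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    d = np.asarray(distance, dtype=float)
    if not (t.shape == f.shape == d.shape):
        raise ValidationError("time, force and distance series must share "
                              "one time base")
    hit = np.nonzero(d >= spec.distance_threshold)[0]
    if hit.size == 0:
        return RuptureResult(ruptured=False)
    t_open = float(t[hit[0]])
    mask = np.abs(t - t_open) <= spec.window / 2.0
    return RuptureResult(ruptured=True, t_open=t_open,
                         f_rupture=float(f[mask].max()))


def read_trace(path):
    """Two-column (time, value) delimited text; '#' lines are headers."""
    data = np.loadtxt(path, comments="#", delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValidationError(f"expected two columns in {path}")
    return data[:, 0], data[:, 1]
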