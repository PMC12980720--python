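"""Synthetic conformer ensembles with known ground truth.

These generators stand in for MD trajectories when exercising the
estimators: Gaussian chains (i.i.d. normal steps), freely-jointed
chains (fixed-length random steps), discrete worm-like chains (bend
angles from the exponential-of-cosine distribution, with the stiffness
solved exactly from the target persistence length), rigid rods, and
samplers for bonded-term distributions.  Every chain draws from its own
seed substream, so enlarging ``n_chains`` never reshuffles earlier
chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensembles import BeadEnsemble
from .errors import DomainError
from .mapping import BondedSample
from .topology import BondedTerm

CHAIN_KINDS = ("gaussian", "freely_jointed", "wlc", "rod")


@dataclass(frozen=True)
class ChainGeneratorSpec:
    kind: str
    n_monomers: int
    bond_length: float = 0.52        # nm
    lp_target: float | None = None   # nm, wlc only
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CHAIN_KINDS:
            raise DomainError(f"kind must be one of {CHAIN_KINDS}")
        if self.n_monomers < 2 or self.n_chains < 1:
            raise DomainError("need n_monomers >= 2 and n_chains >= 1")
        if self.bond_length <= 0:
            raise DomainError("bond_length must be positive")
        if self.kind == "wlc":
            if self.lp_target is None or self.lp_target < self.bond_length:
                raise DomainError("wlc requires lp_target >= bond_length")


def wlc_stiffness(bond_length: float, lp_target: float,
                  tol: float = 1e-10) -> float:
    """Bending stiffness kappa with <cos theta> = exp(-b/lp).

    Solves the exact relation <cos theta> = coth(kappa) - 1/kappa by
    bisection rather than the large-kappa approximation.
    """
    target = math.exp(-bond_length / lp_target)

    def mean_cos(k):
        if k < 1e-8:
            return k / 3.0
        return 1.0 / math.tanh(k) - 1.0 / k

    lo, hi = 1e-12, 4.0
    while mean_cos(hi) < target:
        hi *= 2.0
    while hi - lo > tol * max(1.0, hi):
        mid = (lo + hi) / 2.0
        if mean_cos(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _sample_cos_theta(kappa: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sampling of P(cos) ~ exp(kappa*cos) on [-1, 1]."""
    if kappa < 1e-8:
        return 2.0 * u - 1.0
    # cos = 1 + ln(u + (1-u) exp(-2 kappa)) / kappa, numerically stable
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _chain_rngs(spec) -> list[np.random.Generator]:
    return [np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
            for i in range(spec.n_chains)]


def _random_unit(rng, size) -> np.ndarray:
    v = rng.normal(size=size + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_chains(spec: ChainGeneratorSpec) -> BeadEnsemble:
    """Generate an ensemble of single chains (one frame per chain)."""
    n, b = spec.n_monomers, spec.bond_length
    coords = np.zeros((spec.n_chains, n, 3))

    if spec.kind == "rod":
        z = np.arange(n) * b
        coords[:, :, 2] = z
        return BeadEnsemble(coords, provenance="synthetic")

    rngs = _chain_rngs(spec)
    if spec.kind == "gaussian":
        for c, rng in enumerate(rngs):
            steps = rng.normal(scale=b / math.sqrt(3.0), size=(n - 1, 3))
            coords[c, 1:] = np.cumsum(steps, axis=0)
    elif spec.kind == "freely_jointed":
        for c, rng in enumerate(rngs):
            steps = b * _random_unit(rng, (n - 1,))
            coords[c, 1:] = np.cumsum(steps, axis=0)
    else:                                    # wlc
        kappa = wlc_stiffness(b, spec.lp_target)
        # raw draws per chain (kept per-substream), propagation vectorized
        cos_t = np.empty((spec.n_chains, n - 2))
        phi = np.empty((spec.n_chains, n - 2))
        u0 = np.empty((spec.n_chains, 3))
        for c, rng in enumerate(rngs):
            u0[c] = _random_unit(rng, ())
            cos_t[c] = _sample_cos_theta(kappa, rng.random(n - 2))
            phi[c] = rng.random(n - 2) * 2.0 * np.pi
        u = u0
        coords[:, 1] = coords[:, 0] + b * u
        for s in range(n - 2):
            u = _bend(u, cos_t[:, s], phi[:, s])
            coords[:, s + 2] = coords[:, s + 1] + b * u
    return BeadEnsemble(coords, provenance="synthetic")


def _bend(u: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors u by polar angle acos(cos_t), azimuth phi."""
    # orthonormal frame (u, e1, e2); reference axis switched near poles
    ref = np.zeros_like(u)
    main_z = np.abs(u[:, 2]) < 0.9
    ref[main_z, 2] = 1.0
    ref[~main_z, 0] = 1.0
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(u, e1)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
    out = (cos_t[:, None] * u +
           sin_t[:, None] * (np.cos(phi)[:, None] * e1 +
                             np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


# -- bonded-term samplers ----------------------------------------------------

@dataclass(frozen=True)
class Mode:
    loc: float                       # nm or degrees
    sd: float
    weight: float = 1.0

    def __post_init__(self):
        if self.sd <= 0 or self.weight <= 0:
            raise DomainError("mode spreads and weights must be positive")


@dataclass(frozen=True)
class BondedGeneratorSpec:
    """Per-term target distributions for synthetic bonded samples.

    ``terms`` pairs each :class:`BondedTerm` with one or more Gaussian
    (bonds, angles) or wrapped-Gaussian-mixture (dihedrals) modes.
    """

    terms: tuple[tuple[BondedTerm, tuple[Mode, ...]], ...]
    n_samples: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 0:
            raise DomainError("n_samples cannot be negative")


def generate_bonded_samples(spec: BondedGeneratorSpec) -> list[BondedSample]:
    if spec.n_samples == 0:
        return []
    out = []
    for t_index, (term, modes) in enumerate(spec.terms):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, t_index]))
        weights = np.array([m.weight for m in modes], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(modes), size=spec.n_samples, p=weights)
        vals = np.empty(spec.n_samples)
        for k, m in enumerate(modes):
            sel = which == k
            vals[sel] = rng.normal(m.loc, m.sd, size=int(sel.sum()))
        if term.kind == "dihedral":
            vals = (vals + 180.0) % 360.0 - 180.0    # wrap to (-180, 180]
            vals[vals == -180.0] = 180.0
        elif term.kind == "angle":
            vals = np.clip(vals, 0.0, 180.0)
        elif term.kind in ("bond", "constraint"):
            vals = np.abs(vals)
        out.append(BondedSample(term=term, values=vals))
    return out


# -- multi-chain placement ---------------------------------------------------

def place_multichain(chains: list[BeadEnsemble], min_separation: float,
                     margin: float = 1.0) -> BeadEnsemble:
    """Rigid-translate single-frame chains onto a cubic grid.

    Guarantees every pairwise bead-bead distance between different
    chains is at least ``min_separation`` and returns the combined
    ensemble with an enclosing periodic box.
    """
    if min_separation <= 0:
        raise DomainError("min_separation must be positive")
    if any(c.n_frames != 1 for c in chains):
        raise DomainError("place_multichain expects single-frame chains")
    centered = []
    half_extents = []
    for c in chains:
        xyz = c.coordinates[0]
        mid = (xyz.max(axis=0) + xyz.min(axis=0)) / 2.0
        centered.append(xyz - mid)
        half_extents.append(np.linalg.norm(xyz - mid, axis=1).max())
    pitch = 2.0 * max(half_extents) + min_separation
    side = math.ceil(len(chains) ** (1.0 / 3.0))
    placed = []
    for k, xyz in enumerate(centered):
        cell = np.array([k % side, (k // side) % side, k // side ** 2],
                        dtype=float)
        placed.append(xyz + pitch * cell)
    combined = np.concatenate(placed, axis=0)[None, :, :]
    lo = combined[0].min(axis=0) - margin
    combined = combined - lo[None, None, :]
    box = combined[0].max(axis=0) + margin
    return BeadEnsemble(combined, box=box, provenance="synthetic")
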