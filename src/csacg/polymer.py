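"""Single-chain polymer observables and estimators.

All inter-monomer geometry is measured between the ring virtual sites
(one per residue), which depend only on ring positions and not on the
orientation of substituents.  Provided estimators: end-to-end distance
(ETE) and radius of gyration (Rg) with their squared ratio, the
characteristic ratio <ETE^2>/(N*b_v^2), the Flory scaling fit
<d_ij> = b*|i-j|^nu, three persistence-length estimators (half-life of
the bond-vector autocorrelation, exponential-fit decay length, and the
worm-like-chain relation <ETE^2> ~ 2*lp*L), and the fixed-geometry
hydrodynamic conversion Rg = 1.5*Rh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import BOND_LENGTH_VIRTUAL
from .ensembles import BeadEnsemble
from .errors import DomainError, FitError
from .topology import ChainTopology


def _site_positions(ens: BeadEnsemble,
                    chain: ChainTopology | None) -> np.ndarray:
    """Per-monomer reference sites: ring virtual sites when a chain
    topology is given, otherwise every bead of the ensemble."""
    if chain is None:
        return ens.coordinates
    return ens.coordinates[:, list(chain.virtual_indices), :]


@dataclass
class PolymerObservables:
    ete: np.ndarray                 # per frame, nm
    rg: np.ndarray                  # per frame, nm
    ratio_sq: float                 # <ETE^2>/<Rg^2>
    characteristic_ratio: float     # <ETE^2>/(N*b_v^2)

    @property
    def mean_ete(self) -> float:
        return float(self.ete.mean())

    @property
    def mean_rg(self) -> float:
        return float(self.rg.mean())


def observables(ens: BeadEnsemble, chain: ChainTopology | None = None,
                b_v: float | None = None,
                mass_weighted: bool = False) -> PolymerObservables:
    """End-to-end distance and radius of gyration, averaged over frames.

    ETE runs between the first and last monomer reference sites; Rg is
    computed over all chain beads, unweighted by default
    (``mass_weighted=True`` uses bead masses and skips massless virtual
    sites).
    """
    sites = _site_positions(ens, chain)
    n = sites.shape[1]
    if n < 2:
        raise DomainError("end-to-end distance needs at least two sites")
    ete = np.linalg.norm(sites[:, -1, :] - sites[:, 0, :], axis=-1)

    all_beads = ens.coordinates
    if mass_weighted:
        if chain is None:
            raise DomainError("mass weighting requires a chain topology")
        w = np.array([b.mass for b in chain.beads])
    else:
        w = np.ones(all_beads.shape[1])
    w = w / w.sum()
    com = np.einsum("b,fbi->fi", w, all_beads)
    sq = np.einsum("b,fb->f", w,
                   ((all_beads - com[:, None, :]) ** 2).sum(axis=-1))
    rg = np.sqrt(sq)

    bv = b_v if b_v is not None else (chain.b_v if chain is not None
                                      else BOND_LENGTH_VIRTUAL)
    mean_ete2 = float((ete ** 2).mean())
    ratio_sq = mean_ete2 / float((rg ** 2).mean())
    return PolymerObservables(
        ete=ete, rg=rg, ratio_sq=ratio_sq,
        characteristic_ratio=mean_ete2 / (n * bv ** 2))


def characteristic_ratio(mean_ete: float, n_monomers: int,
                         b_v: float = BOND_LENGTH_VIRTUAL) -> float:
    """``<ETE^2>/(N*b_v^2)`` from a scalar mean ETE (printed-number
    convenience; the ensemble route is :func:`observables`)."""
    if mean_ete <= 0 or n_monomers < 1 or b_v <= 0:
        raise DomainError("inputs must be positive")
    return mean_ete ** 2 / (n_monomers * b_v ** 2)


@dataclass
class FloryFit:
    b: float                        # proportionality constant, nm
    nu: float                       # scaling exponent
    separations: np.ndarray         # s = |i-j|
    mean_dij: np.ndarray            # <d_ij>(s), nm


def mean_separation_profile(ens: BeadEnsemble,
                            chain: ChainTopology | None = None):
    """``<d_ij>`` averaged over frames and all pairs at each s >= 1."""
    sites = _site_positions(ens, chain)
    n = sites.shape[1]
    seps = np.arange(1, n)
    means = np.empty(n - 1)
    for s in seps:
        d = np.linalg.norm(sites[:, s:, :] - sites[:, :-s, :], axis=-1)
        means[s - 1] = d.mean()
    return seps, means


def flory_fit(ens: BeadEnsemble, chain: ChainTopology | None = None,
              log_log: bool = False) -> FloryFit:
    """Fit ``<d_ij> = b*s^nu`` over all separations s >= 1.

    The default is an unweighted nonlinear least squares on the mean
    distances; ``log_log=True`` uses the linear fit of log<d_ij> vs
    log s instead.
    """
    seps, means = mean_separation_profile(ens, chain)
    if seps.size < 3:
        raise FitError("need at least 3 distinct separations for the fit")
    if log_log:
        slope, intercept = np.polyfit(np.log(seps), np.log(means), 1)
        b, nu = float(np.exp(intercept)), float(slope)
    else:
        p0 = (float(means[0]), 0.6)
        popt, _ = curve_fit(lambda s, b, nu: b * np.power(s, nu),
                            seps.astype(float), means, p0=p0, maxfev=10000)
        b, nu = float(popt[0]), float(popt[1])
    if not (np.isfinite(b) and np.isfinite(nu)) or b <= 0:
        raise FitError("power-law fit failed")
    return FloryFit(b=b, nu=nu, separations=seps, mean_dij=means)


@dataclass
class PersistenceResult:
    lp_halflife: float | None       # nm; None when C never crosses 0.5
    lp_expfit: float                # nm
    lp_wlc: float | None            # nm; None when no contour available
    contour_length: float | None    # nm
    x: np.ndarray                   # arc-length separations, nm
    correlation: np.ndarray         # C(x)


def bond_autocorrelation(sites: np.ndarray):
    """Average cosine correlation of successive site-to-site bond
    vectors versus arc-length separation.

    Returns ``(x, C)`` where ``x[k] = k * <bond length>`` in nm and
    ``C[k]`` averages ``u_i . u_{i+k}`` over origins and frames.
    """
    bonds = np.diff(sites, axis=1)
    norms = np.linalg.norm(bonds, axis=-1, keepdims=True)
    u = bonds / norms
    n_bonds = u.shape[1]
    c = np.empty(n_bonds)
    for k in range(n_bonds):
        dots = np.einsum("fbi,fbi->fb", u[:, : n_bonds - k, :],
                         u[:, k:, :])
        c[k] = dots.mean()
    x = np.arange(n_bonds) * float(norms.mean())
    return x, c


def persistence_length(ens: BeadEnsemble, chain: ChainTopology | None = None,
                       contour_length: float | None = None) -> PersistenceResult:
    """Persistence length by three estimators.

    * ``lp_halflife``: arc length of the first downward crossing of
      C(x) = 0.5 (linear interpolation); flagged None when C never
      crosses.
    * ``lp_expfit``: decay length of the least-squares fit
      C = exp(-x/lp).
    * ``lp_wlc``: ``<ETE^2>/(2L)``, using the supplied contour length
      or, by default, the frame-0 ETE (appropriate for trajectories
      started from the extended conformation).
    """
    sites = _site_positions(ens, chain)
    if sites.shape[1] < 6:
        raise DomainError("autocorrelation needs at least 6 monomer sites")
    x, c = bond_autocorrelation(sites)

    lp_half = None
    below = np.nonzero(c < 0.5)[0]
    if below.size:
        j = int(below[0])
        if j == 0:
            lp_half = None          # correlation starts below 0.5: undefined
        else:
            x0, x1, c0, c1 = x[j - 1], x[j], c[j - 1], c[j]
            lp_half = float(x0 + (c0 - 0.5) * (x1 - x0) / (c0 - c1))

    try:
        popt, _ = curve_fit(lambda xx, lam: np.exp(-xx / lam), x, c,
                            p0=(max(x[-1] / 2.0, 1e-6),), maxfev=10000)
        lp_exp = float(popt[0])
    except RuntimeError:
        raise FitError("exponential fit of C(x) did not converge")

    ete = np.linalg.norm(sites[:, -1, :] - sites[:, 0, :], axis=-1)
    if contour_length is None:
        contour_length = float(ete[0])
    lp_wlc = None
    if contour_length and contour_length > 0:
        lp_wlc = float((ete ** 2).mean() / (2.0 * contour_length))
    return PersistenceResult(lp_halflife=lp_half, lp_expfit=lp_exp,
                             lp_wlc=lp_wlc, contour_length=contour_length,
                             x=x, correlation=c)


def rh_from_rg(rg: float) -> float:
    """Hydrodynamic radius from Rg for a linear monodisperse chain
    (Rg = 1.5*Rh)."""
    if rg <= 0:
        raise DomainError("rg must be positive")
    return rg / 1.5
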