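"""Freedman-Diaconis binning, Jensen-Shannon scoring, Boltzmann
inversion, and the ring-constraint elongation rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csacg.constants import KB
from csacg.errors import DomainError, PairingError
from csacg.fitting import (HistogramSpec, ParamConfig, apply_ring_scaling,
                           compare_model, fd_bin_width, fit_harmonic,
                           fit_ring_constraint, js_divergence)
from csacg.mapping import BondedSample
from csacg.topology import BondedTerm

BOND = BondedTerm("bond", (0, 1), 0.47, 1000.0)
ANGLE = BondedTerm("angle", (0, 1, 2), 110.0, 100.0)
DIHEDRAL = BondedTerm("dihedral", (0, 1, 2, 3), 60.0, 5.0, multiplicity=1)


# -- Freedman-Diaconis -------------------------------------------------------

def test_fd_width_hand_computed():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    q75, q25 = np.percentile(x, [75, 25])       # linear interpolation
    assert fd_bin_width(x) == pytest.approx(2 * (q75 - q25) * 4 ** (-1 / 3))


def test_fd_width_scales_homogeneously(rng):
    x = rng.normal(size=500)
    assert fd_bin_width(7.3 * x) == pytest.approx(7.3 * fd_bin_width(x))


def test_fd_width_zero_iqr_falls_back_to_scott():
    # IQR of this sample is zero but the spread is not
    x = np.array([5.0] * 90 + [0.0] * 5 + [10.0] * 5)
    want = 3.49 * x.std() * x.size ** (-1 / 3)
    assert fd_bin_width(x) == pytest.approx(want)


def test_fd_width_needs_four_samples():
    with pytest.raises(DomainError):
        fd_bin_width([1.0, 2.0, 3.0])


# -- Jensen-Shannon ----------------------------------------------------------

def test_jsd_identical_samples_is_exactly_zero(rng):
    x = rng.normal(0.47, 0.02, 5000)
    assert js_divergence(x, x).value == 0.0


def test_jsd_disjoint_supports_is_one(rng):
    a = rng.uniform(0.0, 1.0, 4000)
    b = rng.uniform(5.0, 6.0, 4000)
    assert js_divergence(a, b).value == pytest.approx(1.0, abs=1e-12)
    # divergence form shares both endpoints
    assert js_divergence(a, b, distance_form=False).value == \
        pytest.approx(1.0, abs=1e-12)


def _kl(p, q):
    m = p > 0
    return float(np.sum(p[m] * np.log2(p[m] / q[m])))


def test_jsd_matches_brute_force_formula():
    # two explicit 3-bin distributions, scored by direct KL summation
    p = np.array([0.2, 0.5, 0.3])
    q = np.array([0.6, 0.3, 0.1])
    m = (p + q) / 2
    expected = np.sqrt(0.5 * _kl(p, m) + 0.5 * _kl(q, m))
    # realize the histograms as samples on bins [0,1,2] (counts of 10)
    a = np.repeat([0.0, 1.0, 2.0], (10 * p).astype(int))
    b = np.repeat([0.0, 1.0, 2.0], (10 * q).astype(int))
    spec = HistogramSpec(np.array([-0.5, 0.5, 1.5, 2.5]))
    assert js_divergence(a, b, spec).value == pytest.approx(expected,
                                                            rel=1e-12)


@given(st.lists(st.floats(-50, 50), min_size=8, max_size=60),
       st.lists(st.floats(-50, 50), min_size=8, max_size=60))
def test_jsd_symmetric_and_bounded(xs, ys):
    a, b = np.array(xs), np.array(ys)
    s1 = js_divergence(a, b).value
    s2 = js_divergence(b, a).value
    assert s1 == s2
    assert 0.0 <= s1 <= 1.0


def test_jsd_empty_sample_rejected():
    with pytest.raises(DomainError):
        js_divergence([], [1.0, 2.0, 3.0, 4.0])


# -- Boltzmann inversion -----------------------------------------------------

def test_fit_harmonic_bond_closed_form():
    # exact moments, no sampling: mean 0.47, sd 0.02 at 303.15 K
    x = 0.47 + 0.02 * np.array([-1.0, 1.0])
    term = fit_harmonic(BondedSample(BOND, np.repeat(x, 100)))
    assert term.equilibrium == pytest.approx(0.47)
    assert term.force_constant == pytest.approx(KB * 303.15 / 0.0004)


def test_fit_harmonic_recovers_generating_parameters(rng):
    k_true, b0, temp = 6000.0, 0.47, 303.15
    sd = np.sqrt(KB * temp / k_true)
    sample = BondedSample(BOND, rng.normal(b0, sd, 100_000))
    fit = fit_harmonic(sample, ParamConfig(temperature=temp))
    assert fit.equilibrium == pytest.approx(b0, rel=0.005)
    assert fit.force_constant == pytest.approx(k_true, rel=0.05)


def test_fit_harmonic_angle_uses_radian_variance(rng):
    sd_deg = 5.0
    sample = BondedSample(ANGLE, rng.normal(110.0, sd_deg, 100_000))
    fit = fit_harmonic(sample)
    want_k = KB * 303.15 / np.radians(sd_deg) ** 2
    assert fit.equilibrium == pytest.approx(110.0, abs=0.1)
    assert fit.force_constant == pytest.approx(want_k, rel=0.05)


def test_fit_harmonic_zero_variance_becomes_constraint():
    sample = BondedSample(BOND, np.full(200, 0.33))
    term = fit_harmonic(sample)
    assert term.kind == "constraint"
    assert term.equilibrium == pytest.approx(0.33)
    assert term.force_constant is None


def test_fit_harmonic_small_sample_warns(rng):
    with pytest.warns(UserWarning, match="samples"):
        fit_harmonic(BondedSample(BOND, rng.normal(0.4, 0.01, 50)))


def test_bimodal_dihedral_fits_dominant_mode(rng):
    major = rng.normal(60.0, 8.0, 9000)
    minor = rng.normal(180.0, 8.0, 1000)
    vals = np.concatenate([major, minor])
    vals = (vals + 180.0) % 360.0 - 180.0
    with pytest.warns(UserWarning, match="dominant mode"):
        fit = fit_harmonic(BondedSample(DIHEDRAL, vals))
    assert fit.equilibrium == pytest.approx(60.0, abs=2.0)


def test_wraparound_dihedral_mean_is_circular(rng):
    vals = (rng.normal(178.0, 4.0, 50_000) + 180.0) % 360.0 - 180.0
    fit = fit_harmonic(BondedSample(DIHEDRAL, vals))
    assert abs(abs(fit.equilibrium) - 178.0) < 1.0


# -- ring rule ---------------------------------------------------------------

def test_ring_constraint_exceeds_reference_mean_by_ten_percent(rng):
    ring_term = BondedTerm("constraint", (0, 1), 0.30, ring=True)
    sample = BondedSample(ring_term, rng.normal(0.30, 0.005, 20_000))
    fitted = fit_ring_constraint(sample)
    mean = sample.values.mean()
    assert fitted.equilibrium / mean == pytest.approx(1.10, rel=1e-12)
    assert fitted.kind == "constraint" and fitted.ring


@pytest.mark.parametrize("scale", [1.0, 1.10])
def test_apply_ring_scaling_selectivity(scale):
    terms = [BondedTerm("constraint", (0, 1), 0.300, ring=True),
             BondedTerm("constraint", (1, 2), 0.400, ring=False),
             BondedTerm("bond", (2, 3), 0.500, 100.0)]
    out = apply_ring_scaling(terms, ParamConfig(ring_scaling=scale))
    assert out[0].equilibrium == pytest.approx(0.300 * scale)
    assert out[1].equilibrium == 0.400
    assert out[2].equilibrium == 0.500


# -- model comparison --------------------------------------------------------

def _samples(rng, shift=0.0):
    return [BondedSample(BOND, rng.normal(0.47 + shift, 0.02, 4000)),
            BondedSample(ANGLE, rng.normal(110.0 + 100 * shift, 5.0, 4000))]


def test_compare_model_identical_lists_score_zero(rng):
    ref = _samples(rng)
    scores, summary = compare_model(ref, ref)
    assert all(s.value == 0.0 for s in scores)
    assert summary["median"] == 0.0 and summary["max"] == 0.0


def test_compare_model_monotone_in_shift(rng):
    ref = _samples(np.random.default_rng(1))
    medians = []
    for shift in (0.0, 0.01, 0.02, 0.04):
        model = _samples(np.random.default_rng(2), shift)
        _, summary = compare_model(ref, model)
        medians.append(summary["median"])
    assert all(a < b for a, b in zip(medians, medians[1:]))


def test_compare_model_rejects_misaligned_terms(rng):
    ref = _samples(rng)
    with pytest.raises(PairingError):
        compare_model(ref, ref[::-1])
    with pytest.raises(PairingError):
        compare_model(ref, ref[:1])
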