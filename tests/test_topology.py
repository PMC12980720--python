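"""Chain builder, templates, ion schemes, and serialization."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csacg.errors import ConfigurationError, DomainError, ValidationError
from csacg.topology import (IonScheme, build_chain, classify_scheme,
                            load_templates, neutralize, repeat_unit_summary)
from csacg.topology_io import (extended_coordinates, read_gro, read_itp,
                               topologies_equal, write_gro, write_itp)


@pytest.mark.parametrize("n, n_gla, n_gal", [
    (1, 1, 0),
    (2, 1, 1),
    (21, 11, 10),        # the reference 21mer
    (123, 62, 61),       # long-chain case
])
def test_alternating_residue_counts(templates, n, n_gla, n_gal):
    chain = build_chain(n, templates)
    assert chain.residue_names.count("GLA") == n_gla
    assert chain.residue_names.count("GAL") == n_gal
    assert chain.residue_names[0] == "GLA"
    # odd 1-based positions are GLA
    for i, name in enumerate(chain.residue_names, start=1):
        assert name == ("GLA" if i % 2 else "GAL")


@pytest.mark.parametrize("n", [1, 2, 21, 40])
def test_total_charge_is_minus_n(templates, n):
    assert build_chain(n, templates).total_charge == -n


def test_terminal_variants_at_chain_ends(chain21):
    assert chain21.residue_variants[0] == "terminal"
    assert chain21.residue_variants[-1] == "terminal"
    assert set(chain21.residue_variants[1:-1]) == {"internal"}


def test_bonded_graph_connectivity(chain21):
    g = chain21.bonded_graph()
    assert nx.is_connected(g)
    # removing glycosidic terms must leave exactly one component per residue
    g_intra = chain21.bonded_graph(include_glycosidic=False)
    assert nx.number_connected_components(g_intra) == chain21.n_monomers


def test_build_chain_rejects_bad_input(templates):
    with pytest.raises(DomainError):
        build_chain(0, templates)
    incomplete = {k: v for k, v in templates.items()
                  if k != ("GAL", "internal")}
    with pytest.raises(ConfigurationError):
        build_chain(5, incomplete)


def test_repeat_unit_atom_and_particle_counts(templates):
    atoms, particles = repeat_unit_summary(templates)
    assert particles == 11       # 9 mapped beads + 2 ring virtual sites
    assert atoms == 53


def test_repeat_unit_summary_rejects_duplicate_atoms(templates):
    from dataclasses import replace
    gla = templates[("GLA", "internal")]
    bead0 = replace(gla.beads[0], mapped_atoms=("C1", "H1", "C3"))  # C3 dup
    bad = dict(templates)
    bad[("GLA", "internal")] = replace(gla, beads=(bead0,) + gla.beads[1:])
    with pytest.raises(ValidationError):
        repeat_unit_summary(bad)


def test_templates_one_virtual_and_one_charge_each(templates):
    for (name, variant), tpl in templates.items():
        assert sum(b.is_virtual for b in tpl.beads) == 1
        charged = [b for b in tpl.beads if b.charge != 0]
        assert len(charged) == 1 and charged[0].charge == -1.0
        if name == "GAL":
            assert charged[0].type_label == "Q4n"
            assert charged[0].size_class == "regular"
        else:
            assert charged[0].type_label == "SQ5n"
    gav = [b for tpl in templates.values() for b in tpl.beads if b.is_virtual]
    assert {b.type_label for b in gav} == {"TC4"}
    assert all(b.mass == 0.0 for b in gav)


def test_ring_terms_are_constraints(templates):
    for tpl in templates.values():
        ring = [t for t in tpl.intra_terms if t.ring]
        assert ring and all(t.kind == "constraint" for t in ring)
        assert all(t.force_constant is None for t in ring)


# -- neutralization ----------------------------------------------------------

def test_neutralize_exact_division():
    scheme = IonScheme("regular", 0.75, "pme")
    out = neutralize(-21.0, scheme, salt_molarity=0.0)
    assert out.n_cations == 28              # 21 / 0.75 exactly
    assert out.residual == 0.0
    assert out.neutralizer is None
    assert out.net_charge == 0.0


def test_neutralize_no_charge_no_ions():
    out = neutralize(0.0, IonScheme("tiny", 1.0, "reaction_field"),
                     salt_molarity=0.0)
    assert out.n_cations == out.n_anions == 0
    assert out.neutralizer is None


def test_neutralize_fractional_residual():
    out = neutralize(-21.25, IonScheme("regular", 0.75, "pme"),
                     salt_molarity=0.0)
    assert out.n_cations == 28
    assert out.residual == pytest.approx(-0.25)
    assert out.neutralizer is not None
    assert out.neutralizer.charge == pytest.approx(0.25)
    assert out.neutralizer.type_label == "TP1"
    assert out.net_charge == pytest.approx(0.0, abs=1e-12)


def test_neutralize_salt_counts_from_molarity():
    out = neutralize(0.0, IonScheme("regular", 0.75, "pme"),
                     salt_molarity=0.15, box_volume=1000.0)
    expected = round(0.15 * 1000.0 * 0.602214076)
    assert out.n_cations == out.n_anions == expected


@given(q=st.integers(min_value=-200, max_value=200),
       frac=st.sampled_from([0.0, 0.25, 0.5, -0.25]),
       mag=st.sampled_from([1.0, 0.75]),
       molarity=st.sampled_from([0.0, 0.15]))
def test_neutralize_always_exactly_neutral(q, frac, mag, molarity):
    scheme = IonScheme("regular", mag, "pme")
    out = neutralize(q + frac, scheme, molarity, box_volume=500.0)
    assert abs(out.net_charge) < 1e-9
    assert abs(out.residual) < mag


# -- ion scheme classification -----------------------------------------------

@pytest.mark.parametrize("elec, size, q, expected", [
    ("reaction_field", "tiny", 1.0, "default_aggregating"),
    ("reaction_field", "regular", 0.75, "non_aggregating"),
    ("pme", "regular", 1.0, "non_aggregating"),
    ("pme", "regular", 0.75, "non_aggregating"),
    ("pme", "tiny", 0.75, "partially_mitigated"),
    ("pme", "tiny", 1.0, "partially_mitigated"),
    ("reaction_field", "regular", 1.0, "partially_mitigated"),
    ("reaction_field", "tiny", 0.75, "partially_mitigated"),
])
def test_classify_scheme_table(elec, size, q, expected):
    assert classify_scheme(IonScheme(size, q, elec)) == expected


def test_ion_scheme_validation():
    with pytest.raises(DomainError):
        IonScheme("small", 1.0, "pme")
    with pytest.raises(DomainError):
        IonScheme("tiny", 0.5, "pme")


# -- serialization -----------------------------------------------------------

@pytest.mark.parametrize("n", [1, 2, 7, 21])
def test_itp_round_trip_identity(tmp_path, templates, n):
    chain = build_chain(n, templates)
    path = tmp_path / "chain.itp"
    write_itp(path, chain, IonScheme("regular", 0.75, "pme"))
    assert topologies_equal(chain, read_itp(path))


def test_gro_round_trip(tmp_path, chain21, chain21_coords):
    path = tmp_path / "chain.gro"
    write_gro(path, chain21, chain21_coords)
    resids, resnames, names, coords, box = read_gro(path)
    assert len(resids) == chain21.n_beads
    assert resnames[0] == "GLA"
    np.testing.assert_allclose(coords, chain21_coords, atol=5e-4)
    assert all(b > 0 for b in box)


def test_extended_coordinates_virtual_sites_are_ring_centroids(
        chain21, chain21_coords):
    for site, parents in chain21.virtual_site_rules:
        np.testing.assert_allclose(
            chain21_coords[site],
            chain21_coords[list(parents)].mean(axis=0), atol=1e-12)


def test_loaded_templates_reload_from_explicit_paths(tmp_path, templates):
    # template data is editable text: a copied file set loads identically
    from importlib import resources
    root = resources.files("csacg") / "templates"
    paths = []
    for name in ("gla_internal.yaml", "gla_terminal.yaml",
                 "gal_internal.yaml", "gal_terminal.yaml"):
        p = tmp_path / name
        p.write_text((root / name).read_text())
        paths.append(p)
    again = load_templates(paths)
    assert set(again) == set(templates)
    assert repeat_unit_summary(again) == repeat_unit_summary(templates)
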