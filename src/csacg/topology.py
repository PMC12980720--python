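"""Coarse-grained topology builder for chondroitin sulfate A chains.

The chain model alternates glucuronic acid (GLA, carrying the -1
carboxylate) and N-acetyl-galactosamine-4-sulfate (GAL, carrying the -1
sulfate) residues, connected beta-1,3 (GLA->GAL) and beta-1,4
(GAL->GLA).  Each six-membered glycan ring is represented by three
constraint-linked beads plus a massless TC4 virtual site at the ring
center; substituents (sulfate, acetamido, hydroxymethyl) hang off the
ring beads with harmonic bonds.  Residue templates are shipped as
editable YAML files in :mod:`csacg.templates`.

Salt handling implements the electronic-continuum-corrected ion schemes:
monovalent ions as tiny (TQ5) or regular (Q5) beads with full (+-1.0 e)
or rescaled (+-0.75 e) charges, combined with reaction-field or PME
long-range electrostatics.  Only salt (and the fractional neutralizer
bead) charges are ever rescaled; chain charges stay integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import yaml

from .constants import (BOND_LENGTH_VIRTUAL, CLASS_MASSES, CLASS_RADII,
                        PROBE_RADIUS)
from .errors import ConfigurationError, DomainError, ValidationError

SIZE_CLASSES = ("regular", "small", "tiny")


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained particle of a residue template."""

    name: str
    type_label: str
    size_class: str
    charge: float
    mass: float
    is_virtual: bool = False
    mapped_atoms: tuple[str, ...] = ()

    def __post_init__(self):
        if self.size_class not in SIZE_CLASSES:
            raise ValidationError(f"unknown size class {self.size_class!r}")
        if self.is_virtual:
            if self.mapped_atoms:
                raise ValidationError(
                    f"virtual bead {self.name} cannot map atoms")
            if self.mass != 0.0:
                raise ValidationError(
                    f"virtual bead {self.name} must be massless")
        elif not self.mapped_atoms:
            raise ValidationError(f"bead {self.name} maps no atoms")

    @property
    def radius(self) -> float:
        """Van der Waals radius from the size class, nm."""
        return CLASS_RADII[self.size_class]


@dataclass(frozen=True)
class BondedTerm:
    """A constraint, bond, angle, or dihedral between beads.

    ``equilibrium`` is in nm for 2-body terms, degrees otherwise.
    Constraints carry no force constant; ring-internal pairwise terms
    are always constraints.
    """

    kind: str
    bead_indices: tuple[int, ...]
    equilibrium: float
    force_constant: float | None = None
    ring: bool = False
    multiplicity: int | None = None

    _ARITY = {"constraint": 2, "bond": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self):
        if self.kind not in self._ARITY:
            raise ValidationError(f"unknown term kind {self.kind!r}")
        if len(self.bead_indices) != self._ARITY[self.kind]:
            raise ValidationError(
                f"{self.kind} needs {self._ARITY[self.kind]} beads, "
                f"got {self.bead_indices}")
        if self.kind == "constraint" and self.force_constant is not None:
            raise ValidationError("constraints carry no force constant")
        if self.kind != "constraint" and self.force_constant is None:
            raise ValidationError(f"{self.kind} needs a force constant")


@dataclass(frozen=True)
class ResidueTemplate:
    """Bead layout and intra-residue terms of one residue variant."""

    residue_name: str
    variant: str                       # "internal" ("w/o") or "terminal" ("w")
    beads: tuple[BeadSpec, ...]        # real beads followed by the virtual site
    intra_terms: tuple[BondedTerm, ...]
    ring_bead_indices: tuple[int, ...]
    ring_atoms: tuple[str, ...]
    linkage_ports: Mapping[str, int]
    local_xyz: tuple[tuple[float, float, float], ...]

    @property
    def n_particles(self) -> int:
        return len(self.beads)

    @property
    def charge(self) -> float:
        return sum(b.charge for b in self.beads)

    def port(self, name: str) -> int:
        try:
            return self.linkage_ports[name]
        except KeyError:
            raise ConfigurationError(
                f"{self.residue_name}/{self.variant} has no port {name!r}")


def _validate_template(tpl: ResidueTemplate) -> None:
    virtuals = [b for b in tpl.beads if b.is_virtual]
    if len(virtuals) != 1:
        raise ValidationError(
            f"{tpl.residue_name}/{tpl.variant}: expected exactly one virtual "
            f"ring site, found {len(virtuals)}")
    charged = [b for b in tpl.beads if b.charge != 0.0]
    if len(charged) != 1 or charged[0].charge != -1.0:
        raise ValidationError(
            f"{tpl.residue_name}/{tpl.variant}: expected exactly one bead of "
            f"charge -1")
    want = "Q4n" if tpl.residue_name == "GAL" else "SQ5n"
    if charged[0].type_label != want:
        raise ValidationError(
            f"{tpl.residue_name}: charged bead must be {want}")
    for t in tpl.intra_terms:
        if t.ring and t.kind != "constraint":
            raise ValidationError("ring-internal pairwise terms must be "
                                  "constraints, not bonds")


def _template_from_dict(data: dict) -> ResidueTemplate:
    beads = []
    xyz = []
    for b in data["beads"]:
        beads.append(BeadSpec(
            name=b["name"], type_label=b["type"], size_class=b["size"],
            charge=float(b["charge"]), mass=CLASS_MASSES[b["size"]],
            mapped_atoms=tuple(b["atoms"])))
        xyz.append(tuple(float(v) for v in b["xyz"]))
    vs = data["virtual_site"]
    beads.append(BeadSpec(name=vs["name"], type_label=vs["type"],
                          size_class=vs["size"], charge=0.0, mass=0.0,
                          is_virtual=True))
    xyz.append((0.0, 0.0, 0.0))       # recomputed from the ring beads
    index = {b.name: i for i, b in enumerate(beads)}
    terms = []
    for c in data.get("constraints", []):
        terms.append(BondedTerm("constraint",
                                tuple(index[n] for n in c["beads"]),
                                float(c["length"]),
                                ring=bool(c.get("ring", False))))
    for b in data.get("bonds", []):
        terms.append(BondedTerm("bond", tuple(index[n] for n in b["beads"]),
                                float(b["length"]), float(b["k"])))
    for a in data.get("angles", []):
        terms.append(BondedTerm("angle", tuple(index[n] for n in a["beads"]),
                                float(a["theta"]), float(a["k"])))
    for d in data.get("dihedrals", []):
        terms.append(BondedTerm("dihedral",
                                tuple(index[n] for n in d["beads"]),
                                float(d["phi"]), float(d["k"]),
                                multiplicity=int(d.get("mult", 1))))
    tpl = ResidueTemplate(
        residue_name=data["residue"], variant=data["variant"],
        beads=tuple(beads), intra_terms=tuple(terms),
        ring_bead_indices=tuple(index[n] for n in data["ring_beads"]),
        ring_atoms=tuple(data["ring_atoms"]),
        linkage_ports={k: index[v] for k, v in data["ports"].items()},
        local_xyz=tuple(xyz))
    _validate_template(tpl)
    return tpl


def load_templates(paths: Iterable | None = None) -> dict:
    """Load residue templates, keyed by ``(residue_name, variant)``.

    By default the four YAML files shipped with the package are read;
    pass explicit paths to use edited template data.
    """
    if paths is None:
        root = resources.files("csacg") / "templates"
        paths = [root / n for n in ("gla_internal.yaml", "gla_terminal.yaml",
                                    "gal_internal.yaml", "gal_terminal.yaml")]
    templates = {}
    for p in paths:
        data = yaml.safe_load(p.read_text() if hasattr(p, "read_text")
                              else open(p).read())
        tpl = _template_from_dict(data)
        templates[(tpl.residue_name, tpl.variant)] = tpl
    return templates


def load_linkages(path=None) -> dict:
    if path is None:
        path = resources.files("csacg") / "templates" / "linkages.yaml"
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    return yaml.safe_load(text)


@dataclass
class ChainTopology:
    """A fully instantiated CSA n-mer topology."""

    n_monomers: int
    residue_names: tuple[str, ...]
    residue_variants: tuple[str, ...]
    beads: tuple[BeadSpec, ...]                 # flattened, chain order
    bead_resids: tuple[int, ...]                # 1-based residue index per bead
    terms: tuple[BondedTerm, ...]
    virtual_site_rules: tuple[tuple[int, tuple[int, ...]], ...]
    residue_bead_offsets: tuple[int, ...]
    b_v: float = BOND_LENGTH_VIRTUAL
    name: str = "CSA"

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def total_charge(self) -> float:
        return sum(b.charge for b in self.beads)

    @property
    def virtual_indices(self) -> tuple[int, ...]:
        """Global indices of the ring virtual sites, one per residue."""
        return tuple(site for site, _ in self.virtual_site_rules)

    def radii(self, radius_set: "RadiusSet | None" = None):
        rs = radius_set or RadiusSet()
        return [rs.class_radii[b.size_class] for b in self.beads]

    def bonded_graph(self, include_glycosidic: bool = True) -> nx.Graph:
        """Connectivity graph from 2-body terms and virtual-site rules."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_beads))
        resid = self.bead_resids
        for t in self.terms:
            if len(t.bead_indices) != 2:
                continue
            i, j = t.bead_indices
            if not include_glycosidic and resid[i] != resid[j]:
                continue
            g.add_edge(i, j)
        for site, parents in self.virtual_site_rules:
            for p in parents:
                g.add_edge(site, p)
        return g


def build_chain(n_monomers: int, templates: dict | None = None,
                linkages: dict | None = None) -> ChainTopology:
    """Build an alternating GLA/GAL chain of ``n_monomers`` residues.

    Residue 1 is GLA; odd (1-based) positions are GLA, even positions
    GAL, so an odd-length chain starts and ends with GLA (21 residues
    give 11 GLA + 10 GAL).  Terminal residues use the "w" template
    variant, internal residues "w/o".  The total charge is exactly
    ``-n_monomers`` (one -1 group per residue).
    """
    if n_monomers < 1:
        raise DomainError("n_monomers must be >= 1")
    templates = templates if templates is not None else load_templates()
    linkages = linkages if linkages is not None else load_linkages()
    for key in (("GLA", "internal"), ("GLA", "terminal"),
                ("GAL", "internal"), ("GAL", "terminal")):
        if key not in templates:
            raise ConfigurationError(f"missing template variant {key}")

    residues, names, variants = [], [], []
    for i in range(1, n_monomers + 1):
        resname = "GLA" if i % 2 == 1 else "GAL"
        variant = "terminal" if i in (1, n_monomers) else "internal"
        residues.append(templates[(resname, variant)])
        names.append(resname)
        variants.append(variant)

    beads, bead_resids, terms, vrules, offsets = [], [], [], [], []
    offset = 0
    for i, tpl in enumerate(residues, start=1):
        offsets.append(offset)
        for b in tpl.beads:
            beads.append(b)
            bead_resids.append(i)
        for t in tpl.intra_terms:
            terms.append(replace(
                t, bead_indices=tuple(k + offset for k in t.bead_indices)))
        site = offset + len(tpl.beads) - 1       # virtual site is last
        vrules.append((site, tuple(k + offset for k in tpl.ring_bead_indices)))
        offset += len(tpl.beads)

    # glycosidic terms across each junction
    for i in range(n_monomers - 1):
        donor, acceptor = residues[i], residues[i + 1]
        link = linkages["beta13" if names[i] == "GLA" else "beta14"]
        off_d, off_a = offsets[i], offsets[i + 1]

        def resolve(ref: str) -> int:
            side, bead = ref.split(":")
            tpl, off = ((donor, off_d) if side == "d" else (acceptor, off_a))
            idx = {b.name: k for k, b in enumerate(tpl.beads)}
            if bead not in idx:
                raise ConfigurationError(
                    f"linkage references unknown bead {bead!r}")
            return idx[bead] + off

        b = link["bond"]
        terms.append(BondedTerm("bond", tuple(resolve(r) for r in b["beads"]),
                                float(b["length"]), float(b["k"])))
        for a in link.get("angles", []):
            terms.append(BondedTerm("angle",
                                    tuple(resolve(r) for r in a["beads"]),
                                    float(a["theta"]), float(a["k"])))
        for d in link.get("dihedrals", []):
            terms.append(BondedTerm("dihedral",
                                    tuple(resolve(r) for r in d["beads"]),
                                    float(d["phi"]), float(d["k"]),
                                    multiplicity=int(d.get("mult", 1))))

    chain = ChainTopology(
        n_monomers=n_monomers, residue_names=tuple(names),
        residue_variants=tuple(variants), beads=tuple(beads),
        bead_resids=tuple(bead_resids), terms=tuple(terms),
        virtual_site_rules=tuple(vrules),
        residue_bead_offsets=tuple(offsets))

    if not nx.is_connected(chain.bonded_graph()):
        raise ValidationError("bonded graph of the built chain is not "
                              "connected")
    return chain


def repeat_unit_summary(templates: dict | None = None) -> tuple[int, int]:
    """Atom and particle counts of the internal GLA+GAL repeating unit.

    Returns ``(atoms_mapped, particles)``: the number of distinct atoms
    covered by the mapping tables of the two internal templates, and
    the total bead count including the two ring virtual sites.
    """
    templates = templates if templates is not None else load_templates()
    try:
        pair = [templates[("GLA", "internal")], templates[("GAL", "internal")]]
    except KeyError as e:
        raise ConfigurationError(f"missing internal template: {e}")
    atoms = 0
    for tpl in pair:
        seen: set[str] = set()
        for b in tpl.beads:
            for a in b.mapped_atoms:
                if a in seen:
                    raise ValidationError(
                        f"{tpl.residue_name}: atom {a!r} assigned to more "
                        f"than one bead")
                seen.add(a)
        atoms += len(seen)
    particles = sum(tpl.n_particles for tpl in pair)
    return atoms, particles


# -- ion and charge schemes --------------------------------------------------

ION_TYPE_LABELS = {"tiny": "TQ5", "regular": "Q5"}

#: The three scheme combinations that abolish chain aggregation.
NON_AGGREGATING = frozenset({
    ("reaction_field", "regular", 0.75),
    ("pme", "regular", 1.0),
    ("pme", "regular", 0.75),
})


@dataclass(frozen=True)
class IonScheme:
    """Monovalent-salt representation and electrostatics treatment.

    ``ion_charge_magnitude`` of 0.75 e applies the electronic continuum
    correction (mean-field electronic polarizability) to salt ions only;
    chain charges are never rescaled.
    """

    ion_size_class: str = "regular"            # "tiny" (TQ5) or "regular" (Q5)
    ion_charge_magnitude: float = 0.75
    electrostatics_hint: str = "pme"           # "reaction_field" or "pme"
    neutralizer_type: str = "TP1"

    def __post_init__(self):
        if self.ion_size_class not in ION_TYPE_LABELS:
            raise DomainError(f"ion size class must be one of "
                              f"{sorted(ION_TYPE_LABELS)}")
        if self.ion_charge_magnitude not in (1.0, 0.75):
            raise DomainError("ion charge magnitude must be 1.0 or 0.75 e")
        if self.electrostatics_hint not in ("reaction_field", "pme"):
            raise DomainError("electrostatics must be reaction_field or pme")

    @property
    def ion_type_label(self) -> str:
        return ION_TYPE_LABELS[self.ion_size_class]

    def ion_bead(self, sign: int) -> BeadSpec:
        name = "NA" if sign > 0 else "CL"
        return BeadSpec(name=name, type_label=self.ion_type_label,
                        size_class=self.ion_size_class,
                        charge=sign * self.ion_charge_magnitude,
                        mass=CLASS_MASSES[self.ion_size_class],
                        mapped_atoms=(name,))


DEFAULT_SCHEME = IonScheme("tiny", 1.0, "reaction_field")


def classify_scheme(scheme: IonScheme) -> str:
    """Classify a scheme by how well it suppresses chain aggregation.

    The default combination (reaction field, tiny TQ5 ions, full +-1.0 e
    charge) aggregates; the three schemes in :data:`NON_AGGREGATING`
    keep chains dispersed; every other combination mitigates only
    partially.
    """
    key = (scheme.electrostatics_hint, scheme.ion_size_class,
           scheme.ion_charge_magnitude)
    if key == ("reaction_field", "tiny", 1.0):
        return "default_aggregating"
    if key in NON_AGGREGATING:
        return "non_aggregating"
    return "partially_mitigated"


@dataclass(frozen=True)
class RadiusSet:
    """Probe and per-size-class radii for surface calculations, nm."""

    probe_radius: float = PROBE_RADIUS
    class_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_RADII))

    def __post_init__(self):
        if self.probe_radius <= 0 or any(r <= 0
                                         for r in self.class_radii.values()):
            raise DomainError("all radii must be strictly positive")


@dataclass(frozen=True)
class IonContent:
    """Result of neutralizing a system: ion counts and optional fixer bead."""

    n_cations: int
    n_anions: int
    cation: BeadSpec | None
    anion: BeadSpec | None
    neutralizer: BeadSpec | None
    residual: float

    @property
    def net_charge(self) -> float:
        q = self.residual
        if self.neutralizer is not None:
            q += self.neutralizer.charge
        return q


def neutralize(system_charge: float, scheme: IonScheme,
               salt_molarity: float = 0.0,
               box_volume: float = 1000.0) -> IonContent:
    """Choose salt and counter-ion counts that cancel the system charge.

    Background salt pairs come from ``salt_molarity`` and ``box_volume``
    (nm^3); counter-ions of magnitude ``scheme.ion_charge_magnitude``
    are added with the count rounded to nearest (ties toward fewer
    ions).  Any residual -- possible only with fractional charges -- is
    cancelled by a single neutralizer bead of charge ``-residual`` so
    the final net charge is exactly zero.
    """
    if box_volume <= 0:
        raise DomainError("box_volume must be positive")
    if salt_molarity < 0:
        raise DomainError("salt molarity cannot be negative")
    from .constants import PARTICLES_PER_NM3_PER_MOLAR
    n_salt = round(salt_molarity * box_volume * PARTICLES_PER_NM3_PER_MOLAR)

    q = scheme.ion_charge_magnitude
    n_counter = math.ceil(abs(system_charge) / q - 0.5)   # ties -> fewer
    n_cat, n_an = n_salt, n_salt
    if system_charge < 0:
        n_cat += n_counter
    elif system_charge > 0:
        n_an += n_counter

    residual = system_charge + (n_cat - n_an) * q
    neutralizer = None
    if abs(residual) > 1e-9:
        neutralizer = BeadSpec(name="NEU", type_label=scheme.neutralizer_type,
                               size_class="tiny", charge=-residual,
                               mass=CLASS_MASSES["tiny"],
                               mapped_atoms=("NEU",))
    else:
        residual = 0.0
    cation = scheme.ion_bead(+1) if n_cat else None
    anion = scheme.ion_bead(-1) if n_an else None
    return IonContent(n_cations=n_cat, n_anions=n_an, cation=cation,
                      anion=anion, neutralizer=neutralizer, residual=residual)
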