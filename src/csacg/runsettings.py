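"""Advisory run-settings emission for the supported electrostatics
schemes.  The emitted key-value text documents the conditions a chain
system should be run under; it is advice for an external MD engine, not
a guarantee of engine compatibility."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .topology import IonScheme, classify_scheme


@dataclass(frozen=True)
class RunSettings:
    electrostatics: str = "pme"          # "reaction_field" or "pme"
    rf_dielectric: float = 15.0
    rf_cutoff: float = 1.1               # nm
    timestep: float = 15.0               # fs
    neighbor_list_cutoff: float = 1.35   # nm
    temperature: float = 303.15          # K
    pressure: float = 1.0                # bar

    def __post_init__(self):
        if self.electrostatics not in ("reaction_field", "pme"):
            raise DomainError("electrostatics must be reaction_field or pme")
        for v in (self.rf_dielectric, self.rf_cutoff, self.timestep,
                  self.neighbor_list_cutoff, self.temperature, self.pressure):
            if v <= 0:
                raise DomainError("all run settings must be positive")


def settings_for_scheme(scheme: IonScheme) -> RunSettings:
    return RunSettings(electrostatics=scheme.electrostatics_hint)


def write_run_settings(scheme: IonScheme, path=None) -> str:
    """Render (and optionally write) settings text for an ion scheme.

    A warning banner is prepended when the scheme is not one of the
    non-aggregating combinations.
    """
    rs = settings_for_scheme(scheme)
    label = classify_scheme(scheme)
    lines = []
    if label != "non_aggregating":
        lines += [
            "; WARNING: this ion/electrostatics combination is classified "
            f"'{label}'.",
            "; Multi-chain systems are expected to aggregate artificially; "
            "prefer one of:",
            ";   reaction_field + Q5 ions + q=+-0.75 e",
            ";   pme            + Q5 ions + q=+-1.0 e",
            ";   pme            + Q5 ions + q=+-0.75 e",
        ]
    lines += [
        f"electrostatics       = {rs.electrostatics}",
    ]
    if rs.electrostatics == "reaction_field":
        lines += [
            f"rf-dielectric        = {rs.rf_dielectric:g}",
            f"rf-cutoff-nm         = {rs.rf_cutoff:g}",
        ]
    lines += [
        f"ion-bead-type        = {scheme.ion_type_label}",
        f"ion-charge-e         = {scheme.ion_charge_magnitude:g}",
        f"timestep-fs          = {rs.timestep:g}",
        f"neighbor-cutoff-nm   = {rs.neighbor_list_cutoff:g}",
        f"temperature-K        = {rs.temperature:g}",
        f"pressure-bar         = {rs.pressure:g}",
        f"aggregation-class    = {label}",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
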