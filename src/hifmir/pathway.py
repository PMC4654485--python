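"""The concrete HIF-let-7-AGO1-VEGF pathway model: canonical network builder,
unit conversions, and the virtual-perturbation grammar.

Perturbations mirror wet-lab treatments applied at the start of a hypoxia
experiment: mRNA overexpression bumps the initial condition of the target
mRNA; silencing introduces an siRNA that sequesters the mRNA into an
untranslatable duplex (default Kd 1 nM); miR mimics bump the corresponding
precursor pool; miR antagonists bind the matched RISC into a non-functional
complex; CoCl2 sequesters the hydroxylation-competent PHD2/FIH complexes.
All perturbant species exist in the canonical model at zero concentration, so
a dose-zero perturbation is an exact no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import registry
from .errors import ConfigurationError, DomainError
from .network import ModelDefinition, validate_model

__all__ = [
    "AVOGADRO",
    "O2_NORMOXIA_UM",
    "O2_NORMOXIA_PERCENT",
    "SUBNETWORKS",
    "Perturbation",
    "build_canonical_model",
    "o2_percent_to_concentration",
    "copies_to_concentration",
    "perturbation_effects",
    "apply_perturbations",
]

AVOGADRO = 6.02214076e23
#: 21% ambient O2 corresponds to 209 uM dissolved O2 in culture medium.
O2_NORMOXIA_UM = 209.0
O2_NORMOXIA_PERCENT = 21.0

#: Functional sub-networks of the pathway (species grouping used for reports).
SUBNETWORKS: dict[str, tuple[str, ...]] = {
    "oxygen_sensing": (
        "O2", "HIF1A_mRNA", "HIF1A_cyt", "PHD2", "FIH", "Fe", "DG",
        "PHD2_Fe_DG", "FIH_Fe_DG", "PHD2_Fe_DG_O2", "FIH_Fe_DG_O2",
        "HIF1A_OH", "VHL", "CoCl2", "CoCl2_PHD2_Fe_DG", "CoCl2_FIH_Fe_DG",
    ),
    "hif_transcription": (
        "HIF1A_nuc", "HIF1B", "HIF1_complex", "TTP_mRNA", "TTP",
    ),
    "let7_arm": (
        "pri_let7", "pre_let7", "let7", "AGO1_mRNA", "AGO1_mRNA_pbody",
        "AGO1", "let7_AGO1", "let7_AGO1_nuc", "Dicer_mRNA",
        "Dicer_mRNA_pbody", "Dicer",
    ),
    "mir15a_vegf_arm": (
        "pre_miR15a", "miR15a", "miR15a_RISC", "VEGF_mRNA", "VEGF_mRNA_RISC",
        "VEGF_mRNA_pbody", "VEGF",
    ),
    "perturbants": (
        "siRNA_TTP", "siRNA_TTP_mRNA", "siRNA_AGO1", "siRNA_AGO1_mRNA",
        "anti_let7", "anti_let7_RISC", "anti_miR15a", "anti_miR15a_RISC",
    ),
}

#: silencing target mRNA -> (siRNA species, Kd parameter id)
_SIRNA_TARGETS = {
    "TTP_mRNA": ("siRNA_TTP", "kd_sirna_ttp"),
    "AGO1_mRNA": ("siRNA_AGO1", "kd_sirna_ago1"),
}
#: mimic / antagonist target miR -> species acted upon
_MIMIC_TARGETS = {"let7": "pre_let7", "miR15a": "pre_miR15a"}
_ANTAGONIST_TARGETS = {"let7": "anti_let7", "miR15a": "anti_miR15a"}

PERTURBATION_KINDS = frozenset({
    "sirna_silencing", "mrna_overexpression", "mir_mimic",
    "mir_antagonist", "cocl2", "parameter_override",
})


@dataclass(frozen=True)
class Perturbation:
    """A declarative virtual treatment applied at t=0 of a protocol.

    ``dose`` is in uM except for ``parameter_override`` where it is a
    multiplier on the target parameter.  ``kd`` applies to siRNA silencing
    only (uM, default the registry Kd of 1e-3).
    """

    kind: str
    target: str
    dose: float
    kd: float | None = None
    applied_at: float = 0.0

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ConfigurationError(f"unknown perturbation kind {self.kind!r}")
        if self.dose < 0:
            raise ConfigurationError("perturbation dose must be >= 0")
        if self.applied_at != 0.0:
            raise ConfigurationError(
                "treatments are applied at experiment start (t=0) only")


def build_canonical_model(params: dict[str, float] | str = "registry") -> ModelDefinition:
    """The canonical 47-species / 57-reaction / 91-parameter model.

    ``params="registry"`` uses the built-in calibrated parameter table;
    otherwise pass a complete or partial mapping of parameter overrides.
    """
    overrides = None if isinstance(params, str) else dict(params)
    model = registry.build_model(overrides)
    report = validate_model(model)
    if report["violations"]:
        raise ConfigurationError(
            "canonical model failed validation: " + "; ".join(report["violations"]))
    return model


def o2_percent_to_concentration(pct: float) -> float:
    """Dissolved O2 (uM) for an ambient O2 percentage.

    Linear map anchored at 21% = 209 uM (normoxic cell culture).
    """
    if not 0.0 <= pct <= O2_NORMOXIA_PERCENT:
        raise DomainError(f"ambient O2 must be within [0, 21]%, got {pct}")
    return O2_NORMOXIA_UM * pct / O2_NORMOXIA_PERCENT


def copies_to_concentration(copies: float, volume_pl: float = 1.0) -> float:
    """Convert molecule copies per cell to uM, assuming a 1 pL cell volume."""
    if copies < 0:
        raise DomainError("copy number must be >= 0")
    if volume_pl <= 0:
        raise DomainError("cell volume must be > 0")
    litres = volume_pl * 1e-12
    molar = copies / (AVOGADRO * litres)
    return molar * 1e6


def perturbation_effects(model: ModelDefinition,
                         perturbations: list[Perturbation]):
    """Resolve treatments into (initial-condition deltas, parameter overrides,
    parameter multipliers) without touching the model.

    The protocol layer adds the deltas on top of the pre-equilibrated normoxic
    state, mirroring a treatment administered at experiment start.
    """
    species_ids = set(model.species_ids())
    ic_delta: dict[str, float] = {}
    par_mult: dict[str, float] = {}
    par_set: dict[str, float] = {}

    def bump(sid: str, dose: float):
        ic_delta[sid] = ic_delta.get(sid, 0.0) + dose

    for p in perturbations:
        if p.kind == "sirna_silencing":
            if p.target not in _SIRNA_TARGETS:
                raise ConfigurationError(
                    f"no siRNA species defined for target {p.target!r}; "
                    f"available: {sorted(_SIRNA_TARGETS)}")
            sid, kd_param = _SIRNA_TARGETS[p.target]
            bump(sid, p.dose)
            if p.kd is not None:
                par_set[kd_param] = p.kd
        elif p.kind == "mrna_overexpression":
            if p.target not in species_ids:
                raise ConfigurationError(f"unknown species {p.target!r}")
            bump(p.target, p.dose)
        elif p.kind == "mir_mimic":
            if p.target not in _MIMIC_TARGETS:
                raise ConfigurationError(
                    f"no mimic route for miR {p.target!r}")
            bump(_MIMIC_TARGETS[p.target], p.dose)
        elif p.kind == "mir_antagonist":
            if p.target not in _ANTAGONIST_TARGETS:
                raise ConfigurationError(
                    f"no antagonist species for miR {p.target!r}")
            bump(_ANTAGONIST_TARGETS[p.target], p.dose)
        elif p.kind == "cocl2":
            bump("CoCl2", p.dose)
        elif p.kind == "parameter_override":
            if p.target not in model.parameters:
                raise ConfigurationError(f"unknown parameter {p.target!r}")
            par_mult[p.target] = par_mult.get(p.target, 1.0) * p.dose
    return ic_delta, par_set, par_mult


def apply_perturbations(model: ModelDefinition,
                        perturbations: list[Perturbation]) -> ModelDefinition:
    """Return a new model with the treatments applied; the input is unchanged.

    Doses translate to initial-condition bumps of the matching perturbant or
    target species; ``parameter_override`` multiplies a kinetic parameter.
    """
    ic_delta, par_set, par_mult = perturbation_effects(model, perturbations)
    out = model
    if ic_delta:
        out = out.with_initial_concentrations({
            sid: model.get_species(sid).initial_concentration + d
            for sid, d in ic_delta.items()
        })
    if par_set:
        out = out.with_parameters(par_set)
    if par_mult:
        out = out.with_parameters(
            {k: out.parameters[k] * m for k, m in par_mult.items()})
    return out
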