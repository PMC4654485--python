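"""Compartmentalized reaction networks with mass-action, Michaelis-Menten and
Hill rate laws, and assembly of the ODE right-hand side.

Conventions (package-wide): concentrations in uM, time in minutes.
First-order rate constants are min^-1, second-order uM^-1 min^-1, zero-order
(synthesis) uM min^-1, Vmax uM min^-1, kcat min^-1, K constants uM, Hill
coefficients dimensionless (>= 1).

A reversible binding or transport step is represented as a single
:class:`Reaction` carrying both a forward and a reverse rate law; its net flux
is forward minus reverse.  Degradation reactions have empty product lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ModelDefinitionError, StateError

__all__ = [
    "Compartment",
    "SpeciesDef",
    "RateLaw",
    "Reaction",
    "Parameter",
    "ParameterSet",
    "ModelDefinition",
    "StateVector",
    "RATE_LAW_KINDS",
    "rate",
    "assemble_rhs",
    "assemble_jacobian",
    "validate_model",
]

SPECIES_ROLES = frozenset(
    {"mRNA", "miR_precursor", "miR_mature", "protein", "complex",
     "small_molecule", "perturbant"}
)

#: rate-law kind -> ordered tuple of parameter roles
RATE_LAW_KINDS: dict[str, tuple[str, ...]] = {
    "constant": ("k",),
    "mass_action_1": ("k",),
    "mass_action_2": ("k",),
    "michaelis_menten": ("vmax", "km"),
    "michaelis_menten_catalyzed": ("kcat", "km"),
    "hill_activation": ("vmax", "k", "n"),
    "hill_activation_basal": ("vmax", "k", "n", "basal"),
    "hill_inhibition": ("vmax", "k", "n"),
    "ma1_modulated": ("k", "a"),
    "ma1_saturating_activation": ("k", "a", "ka"),
    "kd_dissociation": ("kf", "kd"),
}

_NEGATIVE_TOL = -1e-9  # uM; values below this are treated as corrupt state


@dataclass(frozen=True)
class Compartment:
    """A well-mixed cellular compartment."""

    id: str
    label: str = ""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species bound to one compartment.

    ``boundary=True`` marks a clamped species (its time derivative is held at
    zero during integration; used for O2, which is an experimentally imposed
    boundary condition rather than a consumed substrate).
    """

    id: str
    compartment: str
    role: str
    initial_concentration: float
    boundary: bool = False
    label: str = ""

    def __post_init__(self):
        if self.role not in SPECIES_ROLES:
            raise ModelDefinitionError(f"unknown species role {self.role!r}")
        if self.initial_concentration < 0:
            raise ModelDefinitionError(
                f"species {self.id!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class RateLaw:
    """A kinetic rate law.

    ``parameters`` maps each role required by ``kind`` (see
    :data:`RATE_LAW_KINDS`) to a parameter id; numeric values live in the
    model's :class:`ParameterSet` so a single parameter can be shared between
    reactions and swapped during calibration without touching the topology.
    """

    kind: str
    parameters: Mapping[str, str]

    def __post_init__(self):
        if self.kind not in RATE_LAW_KINDS:
            raise ModelDefinitionError(f"unknown rate law kind {self.kind!r}")
        missing = [r for r in RATE_LAW_KINDS[self.kind] if r not in self.parameters]
        if missing:
            raise ModelDefinitionError(
                f"rate law {self.kind!r}: missing parameter roles {missing}"
            )

    def resolve(self, params: "ParameterSet") -> dict[str, float]:
        """Role -> numeric value mapping for this law."""
        return {role: params[pid] for role, pid in self.parameters.items()}


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) reaction.

    ``modifiers`` are catalytic species that appear in the rate law but are
    not consumed (e.g. TTP destabilizing an mRNA, Dicer processing a pre-miR).
    The species the forward rate law acts on are the reactants in order,
    followed by the modifiers; the reverse law (if any) acts on the products.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    modifiers: tuple[str, ...] = ()
    reverse_rate_law: RateLaw | None = None
    group: str = "other"
    description: str = ""

    @property
    def reversible(self) -> bool:
        return self.reverse_rate_law is not None

    def forward_rate_species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.reactants) + tuple(self.modifiers)

    def reverse_rate_species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.products) + tuple(self.modifiers)


@dataclass(frozen=True)
class Parameter:
    """A kinetic parameter value with units and provenance."""

    value: float
    units: str
    provenance: str = "user"  # one of {reference_table, fitted, default_median, user}


class ParameterSet(Mapping[str, float]):
    """Mapping parameter id -> value, with units/provenance metadata.

    Behaves as a read-only mapping of values; use :meth:`info` for metadata and
    :meth:`updated` to derive a new set.
    """

    def __init__(self, entries: Mapping[str, Parameter]):
        self._entries = dict(entries)

    def __getitem__(self, key: str) -> float:
        return self._entries[key].value

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def info(self, key: str) -> Parameter:
        return self._entries[key]

    def updated(self, values: Mapping[str, float],
                provenance: str = "user") -> "ParameterSet":
        """New ParameterSet with ``values`` overriding existing entries."""
        entries = dict(self._entries)
        for pid, v in values.items():
            if pid not in entries:
                raise ModelDefinitionError(f"unknown parameter {pid!r}")
            # complex values are admitted for complex-step sensitivity runs
            val = complex(v) if isinstance(v, complex) else float(v)
            entries[pid] = replace(entries[pid], value=val,
                                   provenance=provenance)
        return ParameterSet(entries)

    def as_dict(self) -> dict[str, Parameter]:
        return dict(self._entries)


@dataclass(frozen=True)
class StateVector:
    """Concentrations (uM) of all species at one timestamp (minutes)."""

    values: Mapping[str, float]
    timestamp: float = 0.0

    def __getitem__(self, species: str) -> float:
        return self.values[species]


@dataclass(frozen=True)
class ModelDefinition:
    """The immutable reaction network."""

    compartments: tuple[Compartment, ...]
    species: tuple[SpeciesDef, ...]
    reactions: tuple[Reaction, ...]
    parameters: ParameterSet

    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise ModelDefinitionError(f"unknown species {sid!r}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def with_parameters(self, values: Mapping[str, float],
                        provenance: str = "user") -> "ModelDefinition":
        return replace(self, parameters=self.parameters.updated(values, provenance))

    def with_initial_concentrations(
            self, values: Mapping[str, float]) -> "ModelDefinition":
        idx = {s.id for s in self.species}
        unknown = set(values) - idx
        if unknown:
            raise ModelDefinitionError(f"unknown species {sorted(unknown)}")
        new_species = tuple(
            replace(s, initial_concentration=float(values.get(s.id,
                                                   s.initial_concentration)))
            for s in self.species
        )
        return replace(self, species=new_species)

    def with_boundary(self, species_id: str, boundary: bool) -> "ModelDefinition":
        new_species = tuple(
            replace(s, boundary=boundary) if s.id == species_id else s
            for s in self.species
        )
        return replace(self, species=new_species)

    def content_hash(self) -> str:
        """Stable hash of topology, parameter values and initial conditions."""
        import hashlib

        h = hashlib.sha256()
        for s in self.species:
            h.update(f"{s.id}|{s.compartment}|{s.initial_concentration!r}|"
                     f"{s.boundary}".encode())
        for r in self.reactions:
            h.update(f"{r.id}|{r.reactants}|{r.products}|{r.modifiers}|"
                     f"{r.rate_law.kind}|{sorted(r.rate_law.parameters.items())}"
                     .encode())
            if r.reverse_rate_law is not None:
                h.update(f"{r.reverse_rate_law.kind}|"
                         f"{sorted(r.reverse_rate_law.parameters.items())}".encode())
        for pid in sorted(self.parameters):
            h.update(f"{pid}={self.parameters[pid]!r}".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# flux evaluation


def _law_flux(kind: str, p: Sequence[float], conc: Sequence[float]) -> float:
    """Flux of one rate law given resolved parameter values and the
    concentrations of its rate species (reactants then modifiers)."""
    if kind == "constant":
        return p[0]
    if kind == "mass_action_1":
        return p[0] * conc[0]
    if kind == "mass_action_2":
        return p[0] * conc[0] * conc[1]
    if kind == "michaelis_menten":
        s = conc[0]
        return p[0] * s / (p[1] + s)
    if kind == "michaelis_menten_catalyzed":
        s, e = conc[0], conc[-1]
        return p[0] * e * s / (p[1] + s)
    if kind in ("hill_activation", "hill_activation_basal"):
        x = conc[0]
        vmax, k, n = p[0], p[1], p[2]
        xn = x ** n
        f = vmax * xn / (k ** n + xn)
        if kind == "hill_activation_basal":
            f = f + p[3]
        return f
    if kind == "hill_inhibition":
        x = conc[0]
        vmax, k, n = p[0], p[1], p[2]
        kn = k ** n
        return vmax * kn / (kn + x ** n)
    if kind == "ma1_modulated":
        return p[0] * conc[0] * (1.0 + p[1] * conc[1])
    if kind == "ma1_saturating_activation":
        m = conc[1]
        return p[0] * conc[0] * (1.0 + p[1] * m / (p[2] + m))
    if kind == "kd_dissociation":
        return p[0] * p[1] * conc[0]
    raise ModelDefinitionError(f"unknown rate law kind {kind!r}")


def rate(reaction: Reaction, state: StateVector, params: ParameterSet) -> float:
    """Net flux (uM min^-1) of ``reaction`` at ``state``.

    For a reversible reaction this is forward minus reverse flux; for the
    irreversible laws the result is non-negative for non-negative state.
    """
    def conc(sid: str) -> float:
        try:
            c = state.values[sid]
        except KeyError:
            raise ModelDefinitionError(
                f"reaction {reaction.id!r}: species {sid!r} absent from state"
            ) from None
        if c < _NEGATIVE_TOL:
            raise StateError(
                f"species {sid!r}: concentration {c} below tolerance"
            )
        return c

    fwd_conc = [conc(s) for s in reaction.forward_rate_species()]
    p = [params[pid] for pid in
         (reaction.rate_law.parameters[r]
          for r in RATE_LAW_KINDS[reaction.rate_law.kind])]
    flux = _law_flux(reaction.rate_law.kind, p, fwd_conc)
    if reaction.reverse_rate_law is not None:
        rev_conc = [conc(s) for s in reaction.reverse_rate_species()]
        pr = [params[pid] for pid in
              (reaction.reverse_rate_law.parameters[r]
               for r in RATE_LAW_KINDS[reaction.reverse_rate_law.kind])]
        flux -= _law_flux(reaction.reverse_rate_law.kind, pr, rev_conc)
    return flux


# ---------------------------------------------------------------------------
# compiled RHS / Jacobian


class _CompiledLaw:
    __slots__ = ("kind", "p", "idx")

    def __init__(self, kind: str, p: np.ndarray, idx: np.ndarray):
        self.kind = kind
        self.p = p        # resolved parameter values, law order
        self.idx = idx    # state indices of rate species


def _compile(model: ModelDefinition):
    sindex = model.species_index()
    n_sp = len(model.species)
    n_rx = len(model.reactions)
    params = model.parameters

    def law(rl: RateLaw, species: Iterable[str]) -> _CompiledLaw:
        roles = RATE_LAW_KINDS[rl.kind]
        try:
            # dtype inferred so complex-valued parameters propagate
            p = np.array([params[rl.parameters[r]] for r in roles])
        except KeyError as e:
            raise ModelDefinitionError(f"missing parameter {e}") from None
        try:
            idx = np.array([sindex[s] for s in species], dtype=np.intp)
        except KeyError as e:
            raise ModelDefinitionError(
                f"reaction references undeclared species {e}") from None
        return _CompiledLaw(rl.kind, p, idx)

    forward, reverse = [], []
    stoich = np.zeros((n_sp, n_rx))
    for j, r in enumerate(model.reactions):
        forward.append(law(r.rate_law, r.forward_rate_species()))
        reverse.append(law(r.reverse_rate_law, r.reverse_rate_species())
                       if r.reverse_rate_law is not None else None)
        for sid, c in r.reactants:
            stoich[sindex[sid], j] -= c
        for sid, c in r.products:
            stoich[sindex[sid], j] += c
    free = np.array([not s.boundary for s in model.species])
    return forward, reverse, stoich, free


def _eval_flux(cl: _CompiledLaw, y: np.ndarray) -> float:
    return _law_flux(cl.kind, cl.p, y[cl.idx])


def _law_grad(cl: _CompiledLaw, y: np.ndarray) -> list[tuple[int, float]]:
    """(state index, d flux / d species) pairs for one law."""
    k = cl.kind
    p = cl.p
    i = cl.idx
    if k == "constant":
        return []
    if k == "mass_action_1":
        return [(i[0], p[0])]
    if k == "mass_action_2":
        return [(i[0], p[0] * y[i[1]]), (i[1], p[0] * y[i[0]])]
    if k == "michaelis_menten":
        s = y[i[0]]
        return [(i[0], p[0] * p[1] / (p[1] + s) ** 2)]
    if k == "michaelis_menten_catalyzed":
        s, e = y[i[0]], y[i[-1]]
        den = p[1] + s
        return [(i[0], p[0] * e * p[1] / den ** 2), (i[-1], p[0] * s / den)]
    if k in ("hill_activation", "hill_activation_basal"):
        x = y[i[0]]
        vmax, kk, n = p[0], p[1], p[2]
        kn = kk ** n
        xn1 = x ** (n - 1.0)
        den = (kn + x ** n) ** 2
        return [(i[0], vmax * n * kn * xn1 / den)]
    if k == "hill_inhibition":
        x = y[i[0]]
        vmax, kk, n = p[0], p[1], p[2]
        kn = kk ** n
        xn1 = x ** (n - 1.0)
        return [(i[0], -vmax * kn * n * xn1 / (kn + x ** n) ** 2)]
    if k == "ma1_modulated":
        return [(i[0], p[0] * (1.0 + p[1] * y[i[1]])),
                (i[1], p[0] * y[i[0]] * p[1])]
    if k == "ma1_saturating_activation":
        m = y[i[1]]
        den = p[2] + m
        return [(i[0], p[0] * (1.0 + p[1] * m / den)),
                (i[1], p[0] * y[i[0]] * p[1] * p[2] / den ** 2)]
    if k == "kd_dissociation":
        return [(i[0], p[0] * p[1])]
    raise ModelDefinitionError(f"unknown rate law kind {k!r}")


def assemble_rhs(model: ModelDefinition) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the ODE right-hand side d[state]/dt = N . flux(state).

    Modifiers contribute to rates but not to stoichiometry; boundary (clamped)
    species get a zero derivative.  The returned function preserves the dtype
    of the state, so complex-step trajectories integrate transparently.
    """
    forward, reverse, stoich, free = _compile(model)
    n_rx = stoich.shape[1]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        flux = np.empty(n_rx, dtype=y.dtype)
        for j in range(n_rx):
            f = _eval_flux(forward[j], y)
            if reverse[j] is not None:
                f -= _eval_flux(reverse[j], y)
            flux[j] = f
        dy = stoich @ flux
        dy[~free] = 0.0
        return dy

    return rhs


def assemble_jacobian(model: ModelDefinition) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic Jacobian of the RHS (dense n_species x n_species)."""
    forward, reverse, stoich, free = _compile(model)
    n_sp, n_rx = stoich.shape

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        J = np.zeros((n_sp, n_sp), dtype=y.dtype)
        for j in range(n_rx):
            col = stoich[:, j]
            for si, d in _law_grad(forward[j], y):
                J[:, si] += col * d
            if reverse[j] is not None:
                for si, d in _law_grad(reverse[j], y):
                    J[:, si] -= col * d
        J[~free, :] = 0.0
        return J

    return jac


# ---------------------------------------------------------------------------
# validation


def validate_model(model: ModelDefinition) -> dict:
    """Check all model invariants; reports violations instead of raising.

    Returns a dict with ``species``/``reactions``/``parameters`` counts and a
    (possibly empty) list of human-readable ``violations``.
    """
    violations: list[str] = []
    comp_ids = [c.id for c in model.compartments]
    if len(set(comp_ids)) != len(comp_ids):
        violations.append("duplicate compartment ids")
    sp_ids = [s.id for s in model.species]
    if len(set(sp_ids)) != len(sp_ids):
        violations.append("duplicate species ids")
    known = set(sp_ids)
    for s in model.species:
        if s.compartment not in comp_ids:
            violations.append(f"species {s.id}: unknown compartment {s.compartment}")
        if s.initial_concentration < 0:
            violations.append(f"species {s.id}: negative initial concentration")
    rx_ids = [r.id for r in model.reactions]
    if len(set(rx_ids)) != len(rx_ids):
        violations.append("duplicate reaction ids")
    for r in model.reactions:
        for sid, c in (*r.reactants, *r.products):
            if sid not in known:
                violations.append(f"reaction {r.id}: dangling species reference {sid}")
            if not (isinstance(c, int) and c > 0):
                violations.append(f"reaction {r.id}: non-positive-integer "
                                  f"stoichiometric coefficient for {sid}")
        for sid in r.modifiers:
            if sid not in known:
                violations.append(f"reaction {r.id}: dangling modifier {sid}")
        for rl in (r.rate_law, r.reverse_rate_law):
            if rl is None:
                continue
            for role in RATE_LAW_KINDS[rl.kind]:
                pid = rl.parameters.get(role)
                if pid not in model.parameters:
                    violations.append(
                        f"reaction {r.id}: unknown parameter {pid!r} for role {role}")
    for pid in model.parameters:
        v = model.parameters[pid]
        if not v > 0:
            violations.append(f"parameter {pid}: non-positive value {v}")
    for pid in model.parameters:
        if pid.startswith("n_") and model.parameters[pid] < 1:
            violations.append(f"parameter {pid}: Hill coefficient < 1")
    return {
        "species": len(model.species),
        "reactions": len(model.reactions),
        "parameters": len(model.parameters),
        "violations": violations,
    }
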