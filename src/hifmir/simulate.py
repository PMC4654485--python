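"""Protocol layer: normoxic pre-equilibration, hypoxia switching, stiff
time-course integration and the derived readouts.

Every virtual experiment follows the same template: the model is first driven
to its steady state at 21% O2 (O2 clamped at 209 uM), that state becomes the
initial condition, treatments are added as concentration bumps at t=0, the O2
clamp is set to the protocol's oxygen tension, and the stiff system is
integrated over the protocol span.  Readouts are computed from the dense
solver output (>= 1-minute resolution) so flux integrals are accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConvergenceError,
    DomainError,
    NormalizationError,
    SolverError,
)
from .network import (
    ModelDefinition,
    StateVector,
    assemble_jacobian,
    assemble_rhs,
)
from .pathway import Perturbation, o2_percent_to_concentration, perturbation_effects

__all__ = [
    "Protocol",
    "TimeCourse",
    "ReadoutDefinition",
    "READOUTS",
    "find_normoxic_steady_state",
    "run_protocol",
    "relative_expression",
    "total_vegf_produced",
    "free_vegf_mrna_fraction",
    "onset_delay",
]

#: default stiff-solver tolerances (ode15s analogue)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12

_SS_RESIDUAL = 1e-8    # min^-1, relative residual threshold for steady state
_SS_FLOOR = 1e-9       # uM, concentration floor in the residual denominator


@dataclass(frozen=True)
class Protocol:
    """One virtual experiment: oxygen tension, span, treatments, solver."""

    o2_percent: float = 21.0
    duration: float = 2880.0          # minutes
    perturbations: tuple[Perturbation, ...] = ()
    output_every: float = 1.0         # minutes between stored samples
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self):
        if self.duration <= 0:
            raise DomainError("protocol duration must be > 0")
        if self.output_every <= 0:
            raise DomainError("output_every must be > 0")

    def output_grid(self) -> np.ndarray:
        grid = np.arange(0.0, self.duration, self.output_every)
        if grid[-1] != self.duration:
            grid = np.append(grid, self.duration)
        return grid


@dataclass(frozen=True)
class TimeCourse:
    """Species concentrations (uM) on a time grid (minutes)."""

    time: np.ndarray                   # (n_t,)
    concentrations: np.ndarray         # (n_t, n_species)
    species_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.concentrations.shape != (len(self.time), len(self.species_ids)):
            raise ValueError("time grid / concentration matrix shape mismatch")

    def column(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species_ids.index(species)]

    def state_at(self, t: float) -> StateVector:
        i = int(np.argmin(np.abs(self.time - t)))
        return StateVector(
            dict(zip(self.species_ids, self.concentrations[i])),
            timestamp=float(self.time[i]),
        )

    def to_frame(self):
        """Tidy pandas DataFrame: time_min first, then one column per species."""
        import pandas as pd

        data = {"time_min": self.time}
        for j, sid in enumerate(self.species_ids):
            data[sid] = self.concentrations[:, j]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ReadoutDefinition:
    """A named sum over member species, optionally normalized to t=0."""

    name: str
    members: tuple[str, ...]
    normalization: str = "relative_to_t0"   # or "absolute"

    def __post_init__(self):
        if not self.members:
            raise ValueError("readout needs at least one member species")

    def total(self, tc: TimeCourse) -> np.ndarray:
        cols = [tc.column(m) for m in self.members]
        return np.sum(cols, axis=0)


#: Canonical readouts.  Total HIF-1a and total AGO1 sum free plus all bound
#: forms across both compartments, the normalization the validation data use.
READOUTS: dict[str, ReadoutDefinition] = {
    "total_hif1a": ReadoutDefinition(
        "total_hif1a",
        ("HIF1A_cyt", "HIF1A_OH", "HIF1A_nuc", "HIF1_complex")),
    "total_ago1": ReadoutDefinition(
        "total_ago1",
        ("AGO1", "let7_AGO1", "let7_AGO1_nuc", "miR15a_RISC",
         "VEGF_mRNA_RISC", "anti_let7_RISC", "anti_miR15a_RISC")),
    "total_let7": ReadoutDefinition(
        "total_let7",
        ("let7", "let7_AGO1", "let7_AGO1_nuc", "anti_let7_RISC")),
    "total_mir15a": ReadoutDefinition(
        "total_mir15a",
        ("miR15a", "miR15a_RISC", "VEGF_mRNA_RISC", "anti_miR15a_RISC")),
    "vegf_protein": ReadoutDefinition("vegf_protein", ("VEGF",)),
    "free_vegf_mrna": ReadoutDefinition("free_vegf_mrna", ("VEGF_mRNA",)),
    "dicer_protein": ReadoutDefinition("dicer_protein", ("Dicer",)),
    "hif1_complex": ReadoutDefinition("hif1_complex", ("HIF1_complex",)),
}


def _clamp_o2(model: ModelDefinition, o2_um: float) -> ModelDefinition:
    return model.with_initial_concentrations({"O2": o2_um})


_steady_state_cache: dict[str, np.ndarray] = {}


def find_normoxic_steady_state(model: ModelDefinition,
                               rtol: float = DEFAULT_RTOL,
                               atol: float = DEFAULT_ATOL,
                               max_time: float = 2e7) -> StateVector:
    """Steady state at 21% O2 (O2 clamped at 209 uM), found by long
    integration until max_i |dy_i/dt| / max(y_i, floor) < 1e-8 min^-1.

    Results are memoized on the model content hash; a protocol's first run
    pays the equilibration cost once.
    """
    m = _clamp_o2(model, o2_percent_to_concentration(21.0))
    key = m.content_hash() + f"|{rtol}|{atol}"
    if key in _steady_state_cache:
        y = _steady_state_cache[key]
        return StateVector(dict(zip(m.species_ids(), y)), timestamp=0.0)

    rhs = assemble_rhs(m)
    jac = assemble_jacobian(m)
    y = m.initial_state()
    t_total, span = 0.0, 1e5
    residual = np.inf
    while t_total < max_time:
        sol = solve_ivp(rhs, (0.0, span), y, method="BDF", jac=jac,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise SolverError(
                f"pre-equilibration failed at t={t_total}: {sol.message}")
        y = sol.y[:, -1]
        t_total += span
        dy = rhs(0.0, y)
        residual = float(np.max(np.abs(dy) / np.maximum(np.abs(y), _SS_FLOOR)))
        if residual < _SS_RESIDUAL:
            y = np.maximum(y, 0.0)
            _steady_state_cache[key] = y
            return StateVector(dict(zip(m.species_ids(), y)), timestamp=0.0)
        span = min(span * 2.0, 4e6)
    raise ConvergenceError(
        f"no steady state within {max_time} min (residual {residual:.3e})",
        residual=residual,
    )


def run_protocol(model: ModelDefinition, protocol: Protocol,
                 initial_state: StateVector | None = None) -> TimeCourse:
    """Integrate one virtual experiment.

    The initial state defaults to the normoxic steady state of the untreated
    model; perturbation doses are then added at t=0 and O2 is clamped at the
    protocol's tension.  Deterministic given (model, protocol, tolerances).
    """
    ic_delta, par_set, par_mult = perturbation_effects(
        model, list(protocol.perturbations))

    if initial_state is None:
        base = find_normoxic_steady_state(model, protocol.rtol, protocol.atol)
    else:
        base = initial_state

    m = model
    if par_set:
        m = m.with_parameters(par_set)
    if par_mult:
        m = m.with_parameters(
            {k: m.parameters[k] * v for k, v in par_mult.items()})

    sids = m.species_ids()
    y0 = np.array([base.values[s] for s in sids])
    index = {s: i for i, s in enumerate(sids)}
    for sid, d in ic_delta.items():
        y0[index[sid]] += d
    y0[index["O2"]] = o2_percent_to_concentration(protocol.o2_percent)

    m = _clamp_o2(m, y0[index["O2"]])
    rhs = assemble_rhs(m)
    jac = assemble_jacobian(m)
    grid = protocol.output_grid()
    sol = solve_ivp(rhs, (0.0, protocol.duration), y0, method="BDF", jac=jac,
                    t_eval=grid, rtol=protocol.rtol, atol=protocol.atol)
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    conc = sol.y.T
    if conc.min() < -1e-9:
        raise SolverError(
            f"integrator produced concentration {conc.min():.3e} uM < -1e-9")
    return TimeCourse(
        time=sol.t,
        concentrations=np.clip(conc, 0.0, None),
        species_ids=sids,
        provenance={
            "model_hash": model.content_hash(),
            "o2_percent": protocol.o2_percent,
            "duration_min": protocol.duration,
            "perturbations": [vars(p) for p in protocol.perturbations],
            "rtol": protocol.rtol,
            "atol": protocol.atol,
        },
    )


def relative_expression(tc: TimeCourse, readout: ReadoutDefinition) -> np.ndarray:
    """Summed member trace normalized to its t=0 value (exactly 1 at t=0)."""
    total = readout.total(tc)
    if readout.normalization == "absolute":
        return total
    t0 = total[0]
    if t0 <= 0:
        raise NormalizationError(
            f"readout {readout.name!r} is zero at t=0; cannot normalize")
    trace = total / t0
    trace[0] = 1.0
    return trace


def total_vegf_produced(tc: TimeCourse, model: ModelDefinition,
                        span: float | None = None) -> float:
    """Cumulative VEGF produced (uM) over ``span`` minutes: the time integral
    of the translation flux kt_vegf * [free VEGF mRNA].

    A production quantity — independent of the VEGF degradation rate, unlike
    the end-point protein level.
    """
    span = float(tc.time[-1]) if span is None else float(span)
    if span > tc.time[-1] + 1e-9:
        raise DomainError(
            f"span {span} min exceeds time course range {tc.time[-1]} min")
    mask = tc.time <= span + 1e-9
    kt = model.parameters["kt_vegf"]
    flux = kt * tc.column("VEGF_mRNA")[mask]
    return float(np.trapezoid(flux, tc.time[mask]))


def free_vegf_mrna_fraction(tc: TimeCourse) -> np.ndarray:
    """Fraction of the VEGF mRNA pool that is free (translatable), in [0,1].

    Entries where the total pool is zero are reported as NaN.
    """
    free = tc.column("VEGF_mRNA")
    total = free + tc.column("VEGF_mRNA_RISC") + tc.column("VEGF_mRNA_pbody")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, free / np.maximum(total, 1e-300), np.nan)
    return frac


def onset_delay(tc: TimeCourse, species: str,
                reference_time: float = 120.0,
                threshold: float = 0.05) -> float:
    """Transcriptional onset delay (minutes): first time the species' net
    increase reaches ``threshold`` of its increase at ``reference_time``.

    Returns NaN when there is no net increase by the reference time.
    """
    y = tc.column(species)
    t = tc.time
    iref = int(np.argmin(np.abs(t - reference_time)))
    rise = y[iref] - y[0]
    if rise <= 0:
        return float("nan")
    target = y[0] + threshold * rise
    above = np.nonzero(y[: iref + 1] >= target)[0]
    if len(above) == 0:
        return float("nan")
    i = int(above[0])
    if i == 0:
        return 0.0
    # linear interpolation between bracketing samples
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))
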