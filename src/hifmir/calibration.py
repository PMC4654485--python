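"""Least-squares calibration against normalized time-course datasets,
default parameter priors, and a synthetic densitometry fixture generator.

The calibration target mirrors quantified Western-blot experiments: a readout
(e.g. total HIF-1a) normalized to its value at hypoxia onset, observed at a
handful of time points over 48 h with standard deviations.  Parameters are
fitted in log space with bounds spanning +/- 2 orders of magnitude around
class medians, using bounded trust-region least squares (the bounded analogue
of Levenberg-Marquardt) with optional multistart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import CalibrationError, ConfigurationError, HifmirError
from .network import ModelDefinition, ParameterSet
from .simulate import (
    Protocol,
    ReadoutDefinition,
    find_normoxic_steady_state,
    relative_expression,
    run_protocol,
)

__all__ = [
    "CalibrationDataset",
    "ParameterPrior",
    "FitResult",
    "CLASS_MEDIANS",
    "default_priors",
    "sse_objective",
    "fit_parameters",
    "generate_western_fixture",
    "write_dataset",
    "read_dataset",
]

#: printed class medians (1 pL cell volume normalization)
CLASS_MEDIANS = {
    "mrna_decay": 1.2e-3,      # min^-1
    "mir_decay": 1e-4,         # min^-1
    "protein_decay": 2.5e-4,   # min^-1
    "translation": 3.0,        # min^-1 per mRNA
    "mrna_level": 2.8e-5,      # uM
    "protein_level": 0.08,     # uM
}

_PENALTY = 1e6


@dataclass(frozen=True)
class CalibrationDataset:
    """Normalized relative-expression observations for one condition."""

    readout: ReadoutDefinition
    observations: tuple[tuple[float, float, float], ...]  # (t_min, value, sd)
    condition: Protocol

    def __post_init__(self):
        if len(self.observations) < 3:
            raise ConfigurationError("calibration dataset needs >= 3 time points")
        t0, v0, _ = self.observations[0]
        if t0 != 0.0 or abs(v0 - 1.0) > 1e-12:
            raise ConfigurationError(
                "first observation must be the normalization anchor (t=0, value=1)")
        for _, v, _ in self.observations:
            if v <= 0:
                raise ConfigurationError("relative expression must be > 0")

    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.observations])

    def values(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.observations])

    def sds(self) -> np.ndarray:
        return np.array([s for _, _, s in self.observations])


@dataclass(frozen=True)
class ParameterPrior:
    """Class-median prior with +/- 2 orders-of-magnitude bounds."""

    parameter_id: str
    median: float
    parameter_class: str = "other"

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.median / 100.0, self.median * 100.0)


def _classify(pid: str, value: float) -> tuple[str, float]:
    """Heuristic parameter classification from the registry naming scheme."""
    mir_decays = {"kd_let7_free", "kd_let7_ago1", "kd_mir15a_free",
                  "kd_mir15a_risc", "kd_pre_let7", "kd_pre_mir15a"}
    if pid in mir_decays:
        return "mir_decay", CLASS_MEDIANS["mir_decay"]
    if pid.startswith("kt_"):
        return "translation", CLASS_MEDIANS["translation"]
    if pid.startswith("kd_") and ("mrna" in pid or pid.endswith("_pb")):
        return "mrna_decay", CLASS_MEDIANS["mrna_decay"]
    if pid in {"kd_hif_cyt", "kd_ttp", "kd_ago1", "kd_dicer", "kd_vegf"}:
        return "protein_decay", CLASS_MEDIANS["protein_decay"]
    if pid.startswith("ks_") and "mrna" in pid:
        # synthesis constant implied by the level and decay medians
        return "mrna_level", CLASS_MEDIANS["mrna_level"] * CLASS_MEDIANS["mrna_decay"]
    return "other", value


def default_priors(model: ModelDefinition) -> list[ParameterPrior]:
    """A prior for every model parameter.

    Decay/translation/synthesis classes get the printed medians; everything
    else ("other") takes its registry value as the median, so bounds always
    exist.
    """
    priors = []
    for pid in model.parameters:
        cls, median = _classify(pid, model.parameters[pid])
        if median <= 0:
            raise ConfigurationError(f"parameter {pid!r} has no usable prior")
        priors.append(ParameterPrior(pid, median, cls))
    return priors


@dataclass
class FitResult:
    """Outcome of one calibration."""

    parameters: ParameterSet
    objective: float
    initial_objective: float
    residuals: dict[int, np.ndarray]
    n_starts: int
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "objective": self.objective,
            "initial_objective": self.initial_objective,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "parameters": {
                pid: {"value": self.parameters[pid],
                      "units": self.parameters.info(pid).units,
                      "provenance": self.parameters.info(pid).provenance}
                for pid in self.parameters
            },
        }
        return json.dumps(payload, indent=2)


def _simulate_dataset(model: ModelDefinition, ds: CalibrationDataset) -> np.ndarray:
    """Model-predicted relative expression at the dataset's observation times."""
    tc = run_protocol(model, ds.condition)
    trace = relative_expression(tc, ds.readout)
    return np.interp(ds.times(), tc.time, trace)


def sse_objective(values: dict[str, float], model: ModelDefinition,
                  datasets: list[CalibrationDataset],
                  weighted: bool = False) -> float:
    """Sum of squared errors between normalized simulation profiles and the
    datasets (optionally 1/sd^2 weighted).  Simulation failures return a
    large finite penalty so optimizers can continue."""
    try:
        res = _residual_vector(values, model, datasets, weighted)
    except HifmirError:
        return _PENALTY
    return float(np.sum(res ** 2))


def _residual_vector(values, model, datasets, weighted) -> np.ndarray:
    m = model.with_parameters(values, provenance="fitted") if values else model
    parts = []
    for ds in datasets:
        sim = _simulate_dataset(m, ds)
        r = sim - ds.values()
        if weighted:
            r = r / np.maximum(ds.sds(), 1e-6)
        parts.append(r)
    return np.concatenate(parts)


def fit_parameters(model: ModelDefinition,
                   datasets: list[CalibrationDataset],
                   free_parameter_ids: list[str],
                   priors: list[ParameterPrior] | None = None,
                   n_starts: int = 1,
                   seed: int | None = 0,
                   weighted: bool = False,
                   xtol: float = 1e-4,
                   ftol: float = 1e-6) -> FitResult:
    """Bounded least-squares calibration of ``free_parameter_ids``.

    Start 0 is the model's current values; additional starts are drawn
    log-uniformly inside the prior bounds with the given seed.  The best of
    all converged starts (including the unfitted model itself) is returned,
    so the fitted objective never exceeds the initial one.
    """
    unknown = [p for p in free_parameter_ids if p not in model.parameters]
    if unknown:
        raise ConfigurationError(f"unknown free parameters {unknown}")
    if not free_parameter_ids:
        obj = sse_objective({}, model, datasets, weighted)
        return FitResult(model.parameters, obj, obj, {}, 0, seed,
                         {"note": "no free parameters"})

    prior_map = {p.parameter_id: p for p in (priors or default_priors(model))}
    missing = [p for p in free_parameter_ids if p not in prior_map]
    if missing:
        raise ConfigurationError(f"no priors for {missing}")

    lo = np.log10([prior_map[p].bounds[0] for p in free_parameter_ids])
    hi = np.log10([prior_map[p].bounds[1] for p in free_parameter_ids])
    x_current = np.log10([model.parameters[p] for p in free_parameter_ids])
    x_current = np.clip(x_current, lo, hi)

    def resid(x):
        values = {p: 10.0 ** xi for p, xi in zip(free_parameter_ids, x)}
        try:
            return _residual_vector(values, model, datasets, weighted)
        except HifmirError:
            return np.full(sum(len(d.observations) for d in datasets),
                           np.sqrt(_PENALTY))

    rng = np.random.default_rng(seed)
    starts = [x_current]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    best_x, best_obj, n_ok = None, np.inf, 0
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                diff_step=0.05, xtol=xtol, ftol=ftol)
        except Exception:
            continue
        n_ok += 1
        obj = float(np.sum(sol.fun ** 2))
        if obj < best_obj:
            best_obj, best_x = obj, sol.x
    if best_x is None:
        raise CalibrationError("all calibration starts failed")

    initial_obj = float(np.sum(resid(x_current) ** 2))
    if initial_obj < best_obj:  # optimizer never worsens the model
        best_obj, best_x = initial_obj, x_current
    values = {p: 10.0 ** xi for p, xi in zip(free_parameter_ids, best_x)}
    fitted = model.with_parameters(values, provenance="fitted")
    residuals = {}
    for i, ds in enumerate(datasets):
        residuals[i] = _simulate_dataset(fitted, ds) - ds.values()
    return FitResult(fitted.parameters, best_obj, initial_obj, residuals,
                     len(starts), seed,
                     {"free_parameters": list(free_parameter_ids),
                      "converged_starts": n_ok, "weighted": weighted})


def generate_western_fixture(model: ModelDefinition, protocol: Protocol,
                             readout: ReadoutDefinition, n_points: int = 6,
                             noise_cv: float = 0.15,
                             seed: int = 0) -> CalibrationDataset:
    """Synthetic quantified-Western-blot dataset.

    Simulates the protocol, samples ``n_points`` times spanning [0, duration],
    applies multiplicative lognormal noise with the requested coefficient of
    variation to every point after the t=0 normalization anchor (which is 1 by
    construction, as in densitometry normalization), and attaches
    sd = noise_cv * value.
    """
    if n_points < 3:
        raise ConfigurationError("need at least 3 fixture time points")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    tc = run_protocol(model, protocol)
    trace = relative_expression(tc, readout)
    times = np.linspace(0.0, protocol.duration, n_points)
    clean = np.interp(times, tc.time, trace)
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                size=n_points - 1)
        noisy[1:] = clean[1:] * factors
    noisy[0] = 1.0
    obs = tuple((float(t), float(v), float(noise_cv * v))
                for t, v in zip(times, noisy))
    return CalibrationDataset(readout=readout, observations=obs,
                              condition=protocol)


def write_dataset(ds: CalibrationDataset, path: str) -> None:
    """Delimited text: header + (time_min, value, sd) rows, with the condition
    in a sidecar ``<path>.condition.json``."""
    with open(path, "w") as fh:
        fh.write("time_min\tvalue\tsd\n")
        for t, v, s in ds.observations:
            fh.write(f"{t!r}\t{v!r}\t{s!r}\n")
    sidecar = {
        "readout": {"name": ds.readout.name, "members": list(ds.readout.members),
                    "normalization": ds.readout.normalization},
        "condition": {"o2_percent": ds.condition.o2_percent,
                      "duration_min": ds.condition.duration,
                      "rtol": ds.condition.rtol, "atol": ds.condition.atol},
    }
    with open(path + ".condition.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_dataset(path: str) -> CalibrationDataset:
    with open(path + ".condition.json") as fh:
        side = json.load(fh)
    readout = ReadoutDefinition(side["readout"]["name"],
                                tuple(side["readout"]["members"]),
                                side["readout"]["normalization"])
    cond = Protocol(o2_percent=side["condition"]["o2_percent"],
                    duration=side["condition"]["duration_min"],
                    rtol=side["condition"]["rtol"],
                    atol=side["condition"]["atol"])
    obs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            t, v, s = line.split()
            obs.append((float(t), float(v), float(s)))
    return CalibrationDataset(readout=readout, observations=tuple(obs),
                              condition=cond)
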