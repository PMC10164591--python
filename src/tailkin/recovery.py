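"""Simulation-based parameter recovery.

Kinetic parameters are fitted by minimizing squared residuals between
observed summary curves (modal tail length, fraction deadenylated) and the
same summaries computed from fresh simulations at candidate parameters.
Every candidate is simulated with the same inner seed (common random
numbers), which makes the objective a deterministic, reasonably smooth
function of the parameters and — for data generated with that seed —
exactly zero at the truth.

The optimizer is a derivative-free local search (Nelder-Mead in log
space) started from the best point of a coarse log-spaced grid, because
the simulation objective is noisy across parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .gel import timecourse_table
from .kinetics import simulate
from .types import (
    Curve,
    InvalidInputError,
    KineticParams,
    NonIdentifiableError,
)

__all__ = ["FitResult", "fit_kinetic_params", "observed_summaries"]

_REQUIRED = ("modal_tail_nt", "frac_deadenylated")


@dataclass
class FitResult:
    estimates: dict
    loss: float
    profile_flags: dict
    bounds: dict
    n_evaluations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            lo, hi = self.bounds[name]
            rows.append({"parameter": name, "estimate": est,
                         "bound_low": lo, "bound_high": hi, "loss": self.loss})
        return pd.DataFrame(rows)


def observed_summaries(ensemble) -> dict:
    """Extract the standard summary curves from an ensemble."""
    table = timecourse_table(ensemble)
    t = table["time_s"].to_numpy(dtype=float)
    return {
        "modal_tail_nt": Curve(t, table["modal_tail_nt"].to_numpy(dtype=float)),
        "frac_deadenylated": Curve(t, table["frac_deadenylated"].to_numpy(dtype=float)),
    }


def fit_kinetic_params(observed: dict, free_params, bounds: dict, seed: int, *,
                       base_params: KineticParams, substrate, enzyme,
                       effectors=(), n_molecules: int, pre_bound: bool = False,
                       interaction: bool = True, grid_points: int = 3,
                       maxfev: int = 80) -> FitResult:
    """Fit selected kinetic parameters to observed time-course summaries.

    ``observed`` maps summary names to Curves sharing one time grid; at
    least the modal-length and fraction-deadenylated curves are required.
    ``bounds`` maps each free parameter to (low, high); all free parameters
    must be fields of :class:`KineticParams`.
    """
    free_params = list(free_params)
    for name in free_params:
        if name not in KineticParams.field_names():
            raise InvalidInputError(f"unknown parameter {name!r}")
        if name not in bounds:
            raise InvalidInputError(f"missing bounds for {name!r}")
    missing = [k for k in _REQUIRED if k not in observed]
    if missing:
        raise InvalidInputError(f"observed must include summaries {missing}")

    grid = np.asarray(observed["frac_deadenylated"].times, dtype=float)
    if not np.array_equal(grid, np.asarray(observed["modal_tail_nt"].times)):
        raise InvalidInputError("observed summaries must share a time grid")
    obs_modal = np.asarray(observed["modal_tail_nt"].values, dtype=float)
    obs_frac = np.asarray(observed["frac_deadenylated"].values, dtype=float)
    if np.ptp(obs_modal) == 0 and np.ptp(obs_frac) == 0:
        raise NonIdentifiableError(
            free_params[0], "observations are flat; no parameter is identifiable")

    L0 = max(substrate.tail_length0, 1)
    inner_seed = int(seed) % (2 ** 31)
    n_eval = 0

    def loss_at(values) -> float:
        nonlocal n_eval
        n_eval += 1
        params = replace(base_params, **dict(zip(free_params, values)))
        ens = simulate(substrate, enzyme, effectors, params, grid,
                       n_molecules=n_molecules, seed=inner_seed,
                       pre_bound=pre_bound, interaction=interaction)
        table = timecourse_table(ens)
        modal = table["modal_tail_nt"].to_numpy(dtype=float)
        frac = table["frac_deadenylated"].to_numpy(dtype=float)
        return float(np.sum(((modal - obs_modal) / L0) ** 2)
                     + np.sum((frac - obs_frac) ** 2))

    # pre-fit identifiability probe: a parameter whose whole range leaves the
    # loss bit-identical (common random numbers!) cannot be estimated
    mids = [np.sqrt(bounds[p][0] * bounds[p][1]) for p in free_params]
    base_loss = loss_at(mids)
    for i, name in enumerate(free_params):
        probes = []
        for v in (bounds[name][0], bounds[name][1]):
            vec = list(mids)
            vec[i] = v
            probes.append(loss_at(vec))
        if all(abs(p - base_loss) <= 1e-12 * (1.0 + base_loss) for p in probes):
            raise NonIdentifiableError(name)

    # coarse log-grid start
    axes = [np.geomspace(bounds[p][0], bounds[p][1], grid_points) for p in free_params]
    best_vec, best_loss = list(mids), base_loss
    mesh = np.meshgrid(*axes, indexing="ij")
    for idx in np.ndindex(*[a.size for a in axes]):
        vec = [float(m[idx]) for m in mesh]
        val = loss_at(vec)
        if val < best_loss:
            best_vec, best_loss = vec, val

    log_bounds = [(np.log10(bounds[p][0]), np.log10(bounds[p][1])) for p in free_params]

    def loss_log(x):
        return loss_at(10.0 ** np.asarray(x))

    res = minimize(loss_log, np.log10(best_vec), method="Nelder-Mead",
                   bounds=log_bounds,
                   options={"xatol": 5e-3, "fatol": 1e-12, "maxfev": maxfev})
    est_vec = 10.0 ** np.asarray(res.x)
    est_loss = float(res.fun)
    if est_loss > best_loss:
        est_vec, est_loss = np.asarray(best_vec), best_loss

    estimates = dict(zip(free_params, (float(v) for v in est_vec)))
    flags = {}
    for i, name in enumerate(free_params):
        probes = []
        for f in (0.8, 1.25):
            vec = est_vec.copy()
            vec[i] = min(max(vec[i] * f, bounds[name][0]), bounds[name][1])
            probes.append(loss_at(vec))
        flat = all(abs(p - est_loss) <= 1e-3 * (1.0 + est_loss) for p in probes)
        flags[name] = "non-identifiable" if flat else "ok"

    return FitResult(estimates=estimates, loss=est_loss, profile_flags=flags,
                     bounds={p: tuple(bounds[p]) for p in free_params},
                     n_evaluations=n_eval)
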