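"""Time integration, activity observables, and normalization arithmetic.

Simulation covers the first 20 minutes after growth-factor stimulation.
Kinase "activity" is the concentration of the fully activated form of a
kinase (Raf*, MEKpp, ERKpp), by default counting both free and
complex-bound copies — a phospho-specific measurement does not
distinguish the two. Activities are reported raw, normalized to the
5-minute reference point (the convention of ratio-type proteomic data),
or rescaled to absolute concentrations via a known activated
concentration at the reference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._integrate import integrate_lsoda
from .network import (
    CYTOSOL,
    NUCLEUS,
    RateVector,
    ReactionNetwork,
    conservation_totals,
)

KINASES = ("Raf", "MEK", "ERK")
COMPARTMENTS = (CYTOSOL, NUCLEUS, "total")

#: measurement grid of the source dataset (minutes)
MEASURED_TIMES = (0.0, 1.0, 5.0, 10.0, 20.0)
T_REF = 5.0
NORMALIZATION_FLOOR = 1e-8

# protein concentration table (arbitrary units), System 2
SYSTEM2_TOTALS = {
    "Raf": 0.013,
    "P_Raf": 0.002,
    "MEK": 1.4,
    "P_MEK": 0.14,
    "ERK": 0.96,
    "P_ERK": 0.48,
}
SYSTEM2_RAS_AMPLITUDE = 0.4
#: maximal fraction of each kinase activated at the 5-min reference
SYSTEM2_MAX_ACTIVE_FRACTION = {"Raf": 1.0, "MEK": 0.05, "ERK": 0.50}


class DegenerateNormalizationError(ValueError):
    """Reference-time activity too small to define a normalized trace."""


class IntegrationFailure(RuntimeError):
    def __init__(self, message: str, rates=None):
        super().__init__(message)
        self.rates = rates


@dataclass
class RasInput:
    """Clamped external Ras-GTP activity r(t).

    Parametric mode uses the pulse r(t) = A * (t/t_p) * exp(1 - t/t_p):
    zero at stimulation, peak A at t_p minutes, slow decay — the shape of
    receptor-proximal Ras activation seen by live-cell FRET reporters.
    Tabulated mode interpolates a measured curve linearly.
    """

    mode: str = "parametric"
    peak_amplitude: float = 0.4
    peak_time: float = 2.0
    table: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "tabulated"):
            raise ValueError(f"unknown Ras input mode {self.mode!r}")
        if self.mode == "parametric":
            if self.peak_amplitude < 0 or self.peak_time <= 0:
                raise ValueError("parametric Ras input needs A >= 0, t_p > 0")
        else:
            if not self.table:
                raise ValueError("tabulated Ras input needs a table")
            t = np.array([p[0] for p in self.table])
            v = np.array([p[1] for p in self.table])
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated times must be strictly increasing")
            if np.any(v < 0):
                raise ValueError("Ras activity must be non-negative")

    def __call__(self, t):
        if self.mode == "parametric":
            t = np.asarray(t, dtype=float)
            with np.errstate(over="ignore"):
                out = self.peak_amplitude * (t / self.peak_time) * np.exp(1.0 - t / self.peak_time)
            return out if out.ndim else float(out)
        times = np.array([p[0] for p in self.table])
        vals = np.array([p[1] for p in self.table])
        out = np.interp(t, times, vals)
        return out if np.ndim(t) else float(out)

    def rescaled(self, amplitude: float) -> "RasInput":
        """Same time profile with the peak amplitude reset."""
        if self.mode == "parametric":
            return RasInput("parametric", amplitude, self.peak_time)
        vals = np.array([p[1] for p in self.table])
        peak = vals.max()
        scale = amplitude / peak if peak > 0 else 0.0
        return RasInput("tabulated", table=[(t, v * scale) for t, v in self.table])


@dataclass
class InitialCondition:
    """Protein totals defining the model variant.

    System 1: every kinase and phosphatase total set to one (purely
    normalized data). System 2: absolute concentrations from quantitative
    measurements, plus the absolute activated kinase concentrations at
    the 5-min anchor used to rescale normalized traces.

    Phosphatases do not shuttle; each compartment's phosphatase pool is
    initialized at the tabulated concentration.
    """

    system: str
    totals: dict[str, float]
    ras_amplitude: float
    activated_at_ref: dict[str, float] = field(default_factory=dict)

    def to_state(self, network: ReactionNetwork) -> np.ndarray:
        """Initial 33-vector: inactive kinases and phosphatases in the
        cytosol (phosphatases also in the nucleus), everything else zero."""
        x0 = np.zeros(network.n_species)
        ix = network.species_index
        x0[ix("Raf")] = self.totals["Raf"]
        x0[ix("MEK")] = self.totals["MEK"]
        x0[ix("ERK")] = self.totals["ERK"]
        x0[ix("P_Raf")] = self.totals["P_Raf"]
        x0[ix("P_MEK")] = self.totals["P_MEK"]
        x0[ix("P_ERK")] = self.totals["P_ERK"]
        x0[ix("N-P_MEK")] = self.totals.get("N-P_MEK", self.totals["P_MEK"])
        x0[ix("N-P_ERK")] = self.totals.get("N-P_ERK", self.totals["P_ERK"])
        return x0


def build_initial_condition(system: str, table: dict | None = None) -> InitialCondition:
    """Initial condition for a named model variant.

    ``system1``: all totals one, Ras amplitude one. ``system2``: the
    absolute concentration table, Ras amplitude 0.4, and activated
    kinase concentrations at 5 min computed as total x maximal active
    fraction (MEK: 1.4 x 5% = 0.07; ERK: 0.96 x 50% = 0.48).
    """
    if system == "system1":
        totals = {k: 1.0 for k in ("Raf", "P_Raf", "MEK", "P_MEK", "ERK", "P_ERK")}
        return InitialCondition("system1", totals, ras_amplitude=1.0)
    if system == "system2":
        totals = dict(SYSTEM2_TOTALS if table is None else table)
        frac = SYSTEM2_MAX_ACTIVE_FRACTION
        activated = {k: totals[k] * frac[k] for k in ("Raf", "MEK", "ERK")}
        return InitialCondition("system2", totals, SYSTEM2_RAS_AMPLITUDE, activated)
    raise ValueError(f"unknown system {system!r}")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    ras: np.ndarray
    network: ReactionNetwork

    def state_at(self, t: float) -> np.ndarray:
        i = _grid_index(self.times, t)
        return self.states[i]


@dataclass
class ActivityTrace:
    kinase: str
    compartment: str
    kind: str  # raw | normalized | absolute
    times: np.ndarray
    values: np.ndarray

    def value_at(self, t: float) -> float:
        return float(self.values[_grid_index(self.times, t)])


def _grid_index(times: np.ndarray, t: float) -> int:
    hits = np.nonzero(np.isclose(times, t, rtol=0, atol=1e-9))[0]
    if len(hits) != 1:
        raise KeyError(f"time {t} not on the output grid")
    return int(hits[0])


def default_grid(t_end: float = 20.0, dt: float = 1.0) -> np.ndarray:
    """Output grid over [0, t_end]; always contains the 5-min anchor."""
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    if not np.any(np.isclose(grid, T_REF)):
        raise ValueError("output grid must contain the 5-min reference time")
    return grid


def simulate(
    network: ReactionNetwork,
    rates: RateVector | np.ndarray,
    init: InitialCondition,
    ras: RasInput,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the stiff mass-action system under the Ras input.

    Uses LSODA (automatic stiff/non-stiff switching). Raises
    IntegrationFailure if the solver does not reach the end of the grid
    or a concentration dips below -1e-9.
    """
    k = rates.values if isinstance(rates, RateVector) else np.asarray(rates, float)
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    t_grid = default_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    x0 = init.to_state(network)

    states, ok, message = integrate_lsoda(network, k, x0, t_grid, ras, rtol, atol)
    if not ok:
        raise IntegrationFailure(f"ODE integration failed: {message}", rates=k)
    # negatives within the solver's absolute-error band are integration
    # noise and are clamped; larger undershoots mean the solve is wrong
    floor = -1e3 * atol
    if states.min() < floor:
        raise IntegrationFailure(
            f"negative concentration beyond tolerance ({states.min():.3e})", rates=k
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(t_grid, states, np.asarray(ras(t_grid), dtype=float), network)


# ---------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------

_ACTIVE_SPECIES = {
    ("Raf", CYTOSOL): ("Raf*", "Raf*:P_Raf", "Raf*:MEK", "Raf*:MEKp"),
    ("MEK", CYTOSOL): ("MEKpp", "P_MEK:MEKpp", "MEKpp:ERK", "MEKpp:ERKp"),
    ("MEK", NUCLEUS): ("N-MEKpp", "N-P_MEK:N-MEKpp", "N-MEKpp:N-ERK", "N-MEKpp:N-ERKp"),
    ("ERK", CYTOSOL): ("ERKpp", "P_ERK:ERKpp"),
    ("ERK", NUCLEUS): ("N-ERKpp", "N-P_ERK:N-ERKpp"),
}
_FREE_ACTIVE_SPECIES = {
    ("Raf", CYTOSOL): ("Raf*",),
    ("MEK", CYTOSOL): ("MEKpp",),
    ("MEK", NUCLEUS): ("N-MEKpp",),
    ("ERK", CYTOSOL): ("ERKpp",),
    ("ERK", NUCLEUS): ("N-ERKpp",),
}


def active_species_indices(
    network: ReactionNetwork, kinase: str, compartment: str, free_only: bool = False
) -> list[int]:
    if kinase not in KINASES:
        raise ValueError(f"unknown kinase {kinase!r}")
    if kinase == "Raf" and compartment == NUCLEUS:
        raise ValueError("Raf is cytosolic only")
    table = _FREE_ACTIVE_SPECIES if free_only else _ACTIVE_SPECIES
    if compartment == "total":
        keys = [(kinase, c) for c in (CYTOSOL, NUCLEUS) if (kinase, c) in table]
    elif compartment in (CYTOSOL, NUCLEUS):
        keys = [(kinase, compartment)]
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return [network.species_index(n) for key in keys for n in table[key]]


def observable_activity(
    traj: Trajectory, kinase: str, compartment: str, free_only: bool = False
) -> ActivityTrace:
    """Activated-kinase concentration over time (raw scale).

    The activated form is the sum of all species carrying that kinase in
    its fully activated state (free plus, by default, complex-bound);
    ``total`` sums cytosol and nucleus.
    """
    idx = active_species_indices(traj.network, kinase, compartment, free_only)
    values = traj.states[:, idx].sum(axis=1)
    return ActivityTrace(kinase, compartment, "raw", traj.times.copy(), values)


def activity_at_state(
    network: ReactionNetwork, state: np.ndarray, kinase: str, compartment: str,
    free_only: bool = False,
) -> float:
    idx = active_species_indices(network, kinase, compartment, free_only)
    return float(np.asarray(state)[idx].sum())


def normalize_at_reference(trace: ActivityTrace, t_ref: float = T_REF) -> ActivityTrace:
    """Divide a trace by its value at the reference time (ratio data
    convention); the result is exactly 1 at t_ref."""
    ref = trace.value_at(t_ref)
    if ref <= NORMALIZATION_FLOOR:
        raise DegenerateNormalizationError(
            f"{trace.kinase}/{trace.compartment}: activity {ref:.3e} at "
            f"t={t_ref} min is below the normalization floor"
        )
    return ActivityTrace(
        trace.kinase, trace.compartment, "normalized", trace.times.copy(), trace.values / ref
    )


def rescale_to_absolute(normalized: ActivityTrace, activated_at_ref: float) -> ActivityTrace:
    """Multiply a normalized trace by the absolute activated concentration
    at the reference time; relative activities are unchanged."""
    if activated_at_ref < 0:
        raise ValueError("activated concentration must be non-negative")
    return ActivityTrace(
        normalized.kinase,
        normalized.compartment,
        "absolute",
        normalized.times.copy(),
        normalized.values * activated_at_ref,
    )


def trajectory_conservation_error(traj: Trajectory) -> float:
    """Largest relative drift of any conserved protein total along the
    trajectory (diagnostic for integrator accuracy)."""
    t0 = conservation_totals(traj.network, traj.states[0])
    worst = 0.0
    for i in range(1, len(traj.times)):
        tot = conservation_totals(traj.network, traj.states[i])
        for base, ref in t0.items():
            if ref > 0:
                worst = max(worst, abs(tot[base] - ref) / ref)
    return worst
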