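"""Rate-constant inference by a genetic algorithm.

The fitting target is a set of five-point kinase-activity time courses
(0, 1, 5, 10, 20 min): Raf in the cytosol, MEK and ERK in cytosol and
nucleus. The measured points are linearly interpolated onto a 1-minute
grid over [0, 20] (16 extra points per trace) and the model is scored by
the weighted sum of squared residuals

    E = sum_i sum_j ((x_ij - y_ij) / w_i)^2

where x_ij / y_ij are simulated / measured activities of trace i at grid
time j, and w_i is the trace weight: 1 for normalized traces, the
maximal measured activity for absolute traces (dividing by w_i balances
traces of very different amplitudes).

The optimizer is a classical binary genetic algorithm: Gray-coded
chromosomes mapped linearly onto [0, W_max] per rate constant, linear
ranking fitness, stochastic-universal-sampling selection, single-point
crossover, bit-flip mutation, and fitness-based reinsertion with a
generation gap. Runs are repeated from independent seeds and the
lowest-error candidates are kept for robustness-based selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    DegenerateNormalizationError,
    IntegrationFailure,
    MEASURED_TIMES,
    T_REF,
    InitialCondition,
    RasInput,
    default_grid,
    normalize_at_reference,
    observable_activity,
    simulate,
)
from .network import RateVector, ReactionNetwork

PENALTY_BASE = 1e12

DATASET_COLUMNS = ("kinase", "compartment", "time_min", "value", "kind")


@dataclass
class TimeCourseDataset:
    """Long-format kinase activity records.

    One row per (kinase, compartment, time); ``kind`` is ``normalized``
    (unit activity at the 5-min reference) or ``absolute``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)
        dup = self.frame.duplicated(subset=["kinase", "compartment", "time_min"])
        if dup.any():
            raise ValueError(
                f"duplicate (kinase, compartment, time) rows: {self.frame[dup].index.tolist()}"
            )
        for (kin, comp, kind), g in self.frame.groupby(
            ["kinase", "compartment", "kind"], sort=False
        ):
            if kind == "normalized":
                at_ref = g.loc[np.isclose(g["time_min"], T_REF), "value"]
                if len(at_ref) and not np.allclose(at_ref, 1.0, atol=1e-9):
                    raise ValueError(
                        f"normalized trace {kin}/{comp} must equal 1 at t={T_REF} min"
                    )

    def trace_keys(self) -> list[tuple[str, str, str]]:
        return list(
            self.frame.groupby(["kinase", "compartment", "kind"], sort=False).groups
        )

    def trace(self, kinase: str, compartment: str) -> tuple[np.ndarray, np.ndarray, str]:
        g = self.frame[
            (self.frame["kinase"] == kinase) & (self.frame["compartment"] == compartment)
        ].sort_values("time_min")
        if g.empty:
            raise KeyError(f"no trace {kinase}/{compartment}")
        return g["time_min"].to_numpy(), g["value"].to_numpy(), g["kind"].iloc[0]


def interpolate_timecourse(
    dataset: TimeCourseDataset, fit_grid: np.ndarray | None = None
) -> TimeCourseDataset:
    """Linearly interpolate every five-point trace onto the dense fit grid
    (default 1-min spacing over [0, 20], i.e. 16 new points per trace)."""
    fit_grid = default_grid() if fit_grid is None else np.asarray(fit_grid, float)
    rows = []
    for kin, comp, kind in dataset.trace_keys():
        t, v, _ = dataset.trace(kin, comp)
        missing = [m for m in MEASURED_TIMES if not np.any(np.isclose(t, m))]
        if missing:
            raise ValueError(f"trace {kin}/{comp} lacks measured times {missing}")
        dense = np.interp(fit_grid, t, v)
        rows.append(
            pd.DataFrame(
                {
                    "kinase": kin,
                    "compartment": comp,
                    "time_min": fit_grid,
                    "value": dense,
                    "kind": kind,
                }
            )
        )
    return TimeCourseDataset(pd.concat(rows, ignore_index=True))


@dataclass
class ObjectiveSpec:
    """Weights and grid for the weighted least-squares error."""

    fit_grid: np.ndarray = field(default_factory=default_grid)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def weight(self, kinase: str, compartment: str) -> float:
        w = self.weights.get((kinase, compartment), 1.0)
        if w <= 0:
            raise ValueError(f"non-positive weight for {kinase}/{compartment}")
        return w

    @classmethod
    def for_dataset(cls, dense: TimeCourseDataset) -> "ObjectiveSpec":
        """Default weighting rule: normalized traces weight one, absolute
        traces weighted by their maximal measured activity."""
        weights = {}
        for kin, comp, kind in dense.trace_keys():
            _, v, _ = dense.trace(kin, comp)
            weights[(kin, comp)] = 1.0 if kind == "normalized" else float(np.max(v))
        grid = np.unique(dense.frame["time_min"].to_numpy())
        return cls(fit_grid=grid, weights=weights)


def weighted_error(
    sim: dict[tuple[str, str], np.ndarray],
    data: TimeCourseDataset,
    spec: ObjectiveSpec,
) -> float:
    """E = sum over traces and grid times of ((x - y) / w)^2."""
    total = 0.0
    for kin, comp, _kind in data.trace_keys():
        t, y, _ = data.trace(kin, comp)
        if (kin, comp) not in sim:
            raise KeyError(f"simulation missing trace {kin}/{comp}")
        x = np.asarray(sim[(kin, comp)], float)
        if x.shape != y.shape:
            raise ValueError(f"trace {kin}/{comp}: shape mismatch {x.shape} vs {y.shape}")
        w = spec.weight(kin, comp)
        total += float(np.sum(((x - y) / w) ** 2))
    return total


def make_objective(
    network: ReactionNetwork,
    init: InitialCondition,
    ras: RasInput,
    dense_data: TimeCourseDataset,
    spec: ObjectiveSpec | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Objective E(rates) for the GA: one simulation scores all traces.

    Total function: integration failures and degenerate normalizations
    return a penalty (1e12 + number of affected traces) so every rate
    vector is rankable and failures always rank worse than any fit.
    """
    spec = ObjectiveSpec.for_dataset(dense_data) if spec is None else spec
    keys = dense_data.trace_keys()

    def objective(rates: np.ndarray) -> float:
        try:
            traj = simulate(network, rates, init, ras, spec.fit_grid, rtol=rtol, atol=atol)
        except IntegrationFailure:
            return PENALTY_BASE + len(keys)
        sim = {}
        failed = 0
        for kin, comp, kind in keys:
            trace = observable_activity(traj, kin, comp)
            if kind == "normalized":
                try:
                    trace = normalize_at_reference(trace)
                except DegenerateNormalizationError:
                    failed += 1
                    continue
            sim[(kin, comp)] = trace.values
        if failed:
            return PENALTY_BASE + failed
        return weighted_error(sim, dense_data, spec)

    return objective


# ---------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------


@dataclass
class GAConfig:
    generations: int = 500
    population: int = 100
    w_max: float = 1000.0
    bits_per_parameter: int = 16
    crossover_rate: float = 0.7
    mutation_rate: float | None = None  # default 1 / chromosome length
    generation_gap: float = 0.9
    selection_pressure: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population < 1:
            raise ValueError("generations and population must be >= 1")
        if self.w_max <= 0:
            raise ValueError("W_max must be positive")

    def desk_scale(self, **overrides) -> "GAConfig":
        """Reduced profile (100 generations x 40 individuals) for tests
        and quick exploration."""
        kw = dict(self.__dict__, generations=100, population=40)
        kw.update(overrides)
        return GAConfig(**kw)


@dataclass
class CandidateEstimate:
    rates: RateVector
    error: float
    seed: int
    rank: int = -1
    selected: bool = False
    history: np.ndarray | None = None  # best-ever error per generation

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be non-negative")


def _decode(pop: np.ndarray, n_params: int, bits: int, w_max: float) -> np.ndarray:
    """Gray-coded bits -> real parameter matrix on [0, w_max]."""
    g = pop.reshape(pop.shape[0], n_params, bits)
    b = np.logical_xor.accumulate(g, axis=2)  # Gray -> binary
    weights = 2 ** np.arange(bits - 1, -1, -1, dtype=float)
    ints = b @ weights
    return ints / (2.0**bits - 1.0) * w_max


def _linear_ranking(errors: np.ndarray, sp: float) -> np.ndarray:
    """Fitness by linear ranking (minimization): the best individual gets
    sp, the worst 2 - sp."""
    n = len(errors)
    if n == 1:
        return np.ones(1)
    order = np.argsort(np.argsort(-errors, kind="stable"), kind="stable")
    return 2.0 - sp + 2.0 * (sp - 1.0) * order / (n - 1.0)


def _sus(fitness: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n_select equally spaced pointers on
    the cumulative fitness wheel."""
    cum = np.cumsum(fitness)
    total = cum[-1]
    step = total / n_select
    start = rng.uniform(0, step)
    pointers = start + step * np.arange(n_select)
    idx = np.searchsorted(cum, pointers, side="right")
    return rng.permutation(np.clip(idx, 0, len(fitness) - 1))


def run_ga(objective, n_params: int, config: GAConfig,
           rate_names: tuple[str, ...] | None = None) -> CandidateEstimate:
    """Minimize the objective; returns the best individual ever seen.

    Deterministic for a fixed config (including the seed).
    """
    bits = config.bits_per_parameter
    length = n_params * bits
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / length
    rng = np.random.default_rng(config.seed)
    names = rate_names or tuple(f"p{i}" for i in range(n_params))

    pop = rng.random((config.population, length)) < 0.5
    values = _decode(pop, n_params, bits, config.w_max)
    errors = np.array([objective(v) for v in values])

    best_i = int(np.argmin(errors))
    best_err, best_vec = float(errors[best_i]), values[best_i].copy()
    history = [best_err]

    n_off = max(1, int(round(config.generation_gap * config.population)))
    for _gen in range(config.generations):
        fitness = _linear_ranking(errors, config.selection_pressure)
        parents = pop[_sus(fitness, n_off, rng)]
        # single-point crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, n_off - 1, 2):
            if rng.random() < config.crossover_rate:
                cut = rng.integers(1, length)
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(),
                    parents[i, cut:].copy(),
                )
        children ^= rng.random(children.shape) < mut
        child_values = _decode(children, n_params, bits, config.w_max)
        child_errors = np.array([objective(v) for v in child_values])
        # fitness-based reinsertion: offspring replace the worst members
        worst = np.argsort(errors, kind="stable")[::-1][:n_off]
        pop[worst], values[worst], errors[worst] = children, child_values, child_errors
        gen_best = int(np.argmin(errors))
        if errors[gen_best] < best_err:
            best_err, best_vec = float(errors[gen_best]), values[gen_best].copy()
        history.append(best_err)

    if not np.isfinite(best_err) or best_err >= PENALTY_BASE:
        raise RuntimeError("GA found no finite-error individual")
    return CandidateEstimate(
        RateVector(best_vec, names), best_err, config.seed, history=np.array(history)
    )


def multi_start(
    objective,
    n_params: int,
    config: GAConfig,
    n_seeds: int = 20,
    top_k: int = 10,
    rate_names: tuple[str, ...] | None = None,
    seeds: list[int] | None = None,
) -> list[CandidateEstimate]:
    """Repeat the GA from independent seeds; rank candidates by error.

    Returns all candidates sorted ascending by error (ties broken by seed
    order); the first ``top_k`` are flagged selected.
    """
    if not (n_seeds >= top_k >= 1):
        raise ValueError("need n_seeds >= top_k >= 1")
    seeds = [config.seed + i for i in range(n_seeds)] if seeds is None else list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if len(seeds) != n_seeds:
        raise ValueError("need one seed per run")

    candidates = []
    for s in seeds:
        cfg = GAConfig(**{**config.__dict__, "seed": s})
        candidates.append(run_ga(objective, n_params, cfg, rate_names))
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].error, i))
    ranked = []
    for rank, i in enumerate(order):
        c = candidates[i]
        c.rank = rank
        c.selected = rank < top_k
        ranked.append(c)
    return ranked
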