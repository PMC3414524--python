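"""Synthetic phosphoproteomic-style time courses.

Emulates the structure of the SILAC ratio dataset the inference stage
assumes: five measurement times (0, 1, 5, 10, 20 min), Raf activity in
the cytosol only, MEK and ERK activities in both cytosol and nucleus,
each trace normalized to its own 5-minute value, no Ras trace at all
(Ras activity was never part of the proteomic readout), and multiplicative
measurement noise.

Noise is log-normal: intensities are positive and errors scale with the
signal, so a noisy value is y * exp(N(0, s)) with s chosen to give a
target coefficient of variation. Normalization is applied AFTER noising
(ratios are formed from noisy intensities), so the stored 5-min value is
exactly one and the other points inherit the reference point's error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    MEASURED_TIMES,
    T_REF,
    NORMALIZATION_FLOOR,
    RasInput,
    build_initial_condition,
    default_grid,
    IntegrationFailure,
    observable_activity,
    simulate,
)
from .inference import TimeCourseDataset
from .network import RateVector, ReactionNetwork, make_rate_vector

#: traces present in the emulated dataset (Ras is deliberately absent)
EMITTED_TRACES = (
    ("Raf", "cytosol"),
    ("MEK", "cytosol"),
    ("MEK", "nucleus"),
    ("ERK", "cytosol"),
    ("ERK", "nucleus"),
)

#: default log-uniform sampling range for ground-truth rate constants;
#: within the GA search range [0, W_max=1000] and fast enough that a
#: 0.013-unit Raf pool can push ERK activation past 10% by 5 min
DEFAULT_BOUNDS = (10.0, 1000.0)

#: viable dynamics: activated ERK at 5 min between 10% and 100% of total
VIABILITY_WINDOW = (0.1, 1.0)


@dataclass
class SyntheticSpec:
    ground_truth: RateVector
    system: str = "system1"
    cv: float = 0.1
    emit_normalized: bool = True
    measured_times: tuple[float, ...] = MEASURED_TIMES
    seed: int = 0
    ras: RasInput | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be non-negative")


def sample_ground_truth(
    network: ReactionNetwork,
    rng: np.random.Generator,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    max_tries: int = 100,
) -> RateVector:
    """Sample a viable ground-truth rate vector, log-uniform per constant.

    Viability is checked on the absolute-concentration model (System 2):
    the activated ERK concentration at the 5-min reference must fall
    within 10-100% of the total ERK pool, so the sampled kinetics produce
    non-degenerate, measurable dynamics.
    """
    lo, hi = bounds
    if not (0 < lo <= hi):
        raise ValueError("bounds must satisfy 0 < low <= high")
    init = build_initial_condition("system2")
    ras = RasInput(peak_amplitude=init.ras_amplitude)
    grid = default_grid()
    for _ in range(max_tries):
        values = np.exp(rng.uniform(np.log(lo), np.log(hi), network.n_rates))
        rates = make_rate_vector(network, values)
        if _viable(network, rates, init, ras, grid):
            return rates
    raise RuntimeError(f"no viable ground truth found in {max_tries} tries")


def _viable(network, rates, init, ras, grid) -> bool:
    try:
        traj = simulate(network, rates, init, ras, grid)
    except IntegrationFailure:
        return False
    erk_total = init.totals["ERK"]
    active = observable_activity(traj, "ERK", "total").value_at(T_REF)
    lo, hi = VIABILITY_WINDOW
    return lo * erk_total <= active <= hi * erk_total


def generate_dataset(
    network: ReactionNetwork, spec: SyntheticSpec
) -> TimeCourseDataset:
    """Simulate the ground truth and emit the five noisy measured traces.

    Deterministic for a fixed spec seed. With ``emit_normalized`` each
    noisy trace is renormalized by its own noisy 5-min value.
    """
    init = build_initial_condition(spec.system)
    ras = spec.ras or RasInput(peak_amplitude=init.ras_amplitude)
    times = np.asarray(spec.measured_times, dtype=float)
    traj = simulate(network, spec.ground_truth, init, ras, default_grid())
    rng = np.random.default_rng(spec.seed)
    sigma_ln = float(np.sqrt(np.log1p(spec.cv**2)))

    rows = []
    for kinase, compartment in EMITTED_TRACES:
        trace = observable_activity(traj, kinase, compartment)
        clean = np.array([trace.value_at(t) for t in times])
        noisy = clean * np.exp(rng.normal(0.0, sigma_ln, size=clean.shape)) if sigma_ln else clean
        if spec.emit_normalized:
            ref = noisy[np.isclose(times, T_REF)][0]
            if ref <= NORMALIZATION_FLOOR:
                raise ValueError(
                    f"{kinase}/{compartment}: 5-min activity below the normalization floor"
                )
            noisy = noisy / ref
            kind = "normalized"
        else:
            kind = "absolute"
        rows.append(
            pd.DataFrame(
                {
                    "kinase": kinase,
                    "compartment": compartment,
                    "time_min": times,
                    "value": noisy,
                    "kind": kind,
                }
            )
        )
    return TimeCourseDataset(pd.concat(rows, ignore_index=True))
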