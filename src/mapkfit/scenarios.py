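"""Phosphatase-inhibition dose-response predictions.

Two phosphatase manipulations are modeled on the absolute-concentration
system, emulating titration experiments:

* PP2A — a dual-role enzyme: it dephosphorylates activated MEK
  (inhibition) but also promotes Raf activation upstream. Scaling PP2A
  by s therefore scales the MEK-phosphatase pools (both compartments) by
  s AND couples the Ras-Raf binding constant positively, a1 = a1_basal * s.
* MKP3 — a dual-specificity phosphatase acting mainly on ERK: the ERK
  phosphatase pools scale by s, while only a quarter of the MEK
  phosphatase pool tracks MKP3 (the remaining 75% is MKP3-independent),
  so MEK-P'ase scales by (0.75 + 0.25 * s).

The dose-response grid crosses phosphatase scales (0.3-2x) with Ras-GTP
input amplitudes (0.004-0.4) and records activated Raf, total MEK and
total ERK at the readout times (default 10 min, plus 5 and 20 min for
the early/late pictures).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    InitialCondition,
    IntegrationFailure,
    RasInput,
    default_grid,
    observable_activity,
    simulate,
)
from .network import RateVector, ReactionNetwork

DEFAULT_RAS_LEVELS = (0.004, 0.02, 0.04, 0.4)
DEFAULT_SCALES = tuple(np.round(np.arange(0.3, 2.01, 0.1), 10))
DEFAULT_READOUT_TIMES = (5.0, 10.0, 20.0)

#: fraction of the MEK phosphatase pool that tracks MKP3 abundance
MKP3_MEK_FRACTION = 0.25

READOUT_OBSERVABLES = (("Raf", "cytosol"), ("MEK", "total"), ("ERK", "total"))


def _scaled_totals(init: InitialCondition, factors: dict[str, float]) -> InitialCondition:
    new = copy.deepcopy(init)
    totals = dict(new.totals)
    # make the nuclear phosphatase pools explicit before scaling
    totals.setdefault("N-P_MEK", totals["P_MEK"])
    totals.setdefault("N-P_ERK", totals["P_ERK"])
    for key, f in factors.items():
        totals[key] = totals[key] * f
    new.totals = totals
    return new


def apply_pp2a(
    network: ReactionNetwork,
    rates: RateVector,
    init: InitialCondition,
    s: float,
    a1_basal: float | None = None,
) -> tuple[RateVector, InitialCondition]:
    """PP2A at relative abundance s: MEK-phosphatase pools (cytosol and
    nucleus) scaled by s; Ras-Raf binding a1 = a1_basal * s (linear
    positive coupling). s = 1 reproduces the baseline exactly."""
    if s <= 0:
        raise ValueError("phosphatase scale must be positive")
    basal = rates.as_dict()["a1"] if a1_basal is None else a1_basal
    new_rates = rates.replace(a1=basal * s)
    new_init = _scaled_totals(init, {"P_MEK": s, "N-P_MEK": s})
    return new_rates, new_init


def apply_mkp3(
    network: ReactionNetwork,
    rates: RateVector,
    init: InitialCondition,
    s: float,
) -> tuple[RateVector, InitialCondition]:
    """MKP3 at relative abundance s: ERK-phosphatase pools scaled by s;
    MEK-phosphatase pools scaled by (0.75 + 0.25 s) — only a quarter of
    the MEK phosphatase varies with MKP3. No rate constants change."""
    if s <= 0:
        raise ValueError("phosphatase scale must be positive")
    mek_factor = (1.0 - MKP3_MEK_FRACTION) + MKP3_MEK_FRACTION * s
    new_init = _scaled_totals(
        init, {"P_ERK": s, "N-P_ERK": s, "P_MEK": mek_factor, "N-P_MEK": mek_factor}
    )
    return RateVector(rates.values.copy(), rates.names), new_init


_APPLY = {"PP2A": apply_pp2a, "MKP3": apply_mkp3}


@dataclass
class ScenarioSpec:
    phosphatase: str = "PP2A"
    scales: tuple[float, ...] = DEFAULT_SCALES
    ras_levels: tuple[float, ...] = DEFAULT_RAS_LEVELS
    readout_times: tuple[float, ...] = DEFAULT_READOUT_TIMES
    a1_basal: float | None = None

    def __post_init__(self) -> None:
        if self.phosphatase not in _APPLY:
            raise ValueError(f"unknown phosphatase {self.phosphatase!r}")
        if any(s <= 0 for s in self.scales):
            raise ValueError("phosphatase scales must be positive")
        if any(r < 0 for r in self.ras_levels):
            raise ValueError("Ras levels must be non-negative")


def apply_phosphatase(
    network: ReactionNetwork,
    rates: RateVector,
    init: InitialCondition,
    spec: ScenarioSpec,
    s: float,
) -> tuple[RateVector, InitialCondition]:
    if spec.phosphatase == "PP2A":
        return apply_pp2a(network, rates, init, s, spec.a1_basal)
    return apply_mkp3(network, rates, init, s)


def dose_response(
    network: ReactionNetwork,
    rates: RateVector,
    init: InitialCondition,
    ras: RasInput,
    spec: ScenarioSpec,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Full dose-response table over (scale, Ras level, readout time,
    kinase). Integration failures are recorded per cell (NaN activity),
    never fatal."""
    grid = default_grid()
    rows = []
    for s in spec.scales:
        mod_rates, mod_init = apply_phosphatase(network, rates, init, spec, s)
        for ras_level in spec.ras_levels:
            scaled_ras = ras.rescaled(ras_level)
            try:
                traj = simulate(network, mod_rates, mod_init, scaled_ras, grid,
                                rtol=rtol, atol=atol)
                traces = {
                    (k, c): observable_activity(traj, k, c) for k, c in READOUT_OBSERVABLES
                }
                failed = False
            except IntegrationFailure:
                failed = True
            for t in spec.readout_times:
                for kinase, compartment in READOUT_OBSERVABLES:
                    rows.append(
                        {
                            "phosphatase": spec.phosphatase,
                            "scale": s,
                            "ras_level": ras_level,
                            "readout_time": t,
                            "kinase": kinase,
                            "compartment": compartment,
                            "activity": (
                                np.nan if failed else traces[(kinase, compartment)].value_at(t)
                            ),
                        }
                    )
    return pd.DataFrame(rows)
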