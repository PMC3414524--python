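"""Robustness of candidate models to rate-constant perturbation.

Following the robustness-as-averaged-behavior view of Kitano, each
candidate rate vector is perturbed many times, every perturbed model is
simulated, and kinase activities are collected at a fixed evaluation
time (default 20 min). Two ensemble summaries are kept:

* average behavior A — the sum over observables of the ensemble mean
  activity; a robust model keeps A close to the unperturbed activities;
* nominal behavior V — the sum over observables of the ensemble
  variance; smaller V means the output is less sensitive to kinetic
  uncertainty.

Perturbations are multiplicative and independent per rate constant:

    uniform:  k' = k * (1 + sigma * (2U - 1)),  U ~ U(0,1)
    gaussian: k' = max(k * (1 + sigma * Z), 0), Z ~ N(0,1)

so sigma is a dimensionless strength and sigma = 0 is the identity. With
shared draws, every candidate sees the same random-number sequence,
making the comparison between candidates fair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    CYTOSOL,
    NUCLEUS,
    InitialCondition,
    IntegrationFailure,
    RasInput,
    activity_at_state,
    simulate,
)
from .inference import CandidateEstimate
from .network import RateVector, ReactionNetwork

#: kinase activities collected at the evaluation time: per-location
#: MEK/ERK, cytosolic Raf, and the three compartment totals
DEFAULT_OBSERVABLES = (
    ("Raf", CYTOSOL),
    ("MEK", CYTOSOL),
    ("MEK", NUCLEUS),
    ("MEK", "total"),
    ("ERK", CYTOSOL),
    ("ERK", NUCLEUS),
    ("ERK", "total"),
)


@dataclass
class PerturbationSpec:
    distribution: str = "uniform"  # uniform | gaussian
    strength: float = 0.2
    n_sets: int = 10_000
    seed: int = 0
    shared_draws: bool = True
    eval_time: float = 20.0

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.strength < 0:
            raise ValueError("perturbation strength must be non-negative")
        if self.n_sets < 1:
            raise ValueError("need at least one perturbed set")

    def draws(self, n_rates: int) -> np.ndarray:
        """The (n_sets, n_rates) random matrix; same seed -> same draws,
        which is what shared_draws relies on."""
        rng = np.random.default_rng(self.seed)
        if self.distribution == "uniform":
            return rng.random((self.n_sets, n_rates))
        return rng.standard_normal((self.n_sets, n_rates))


def perturb_rates(
    rates: RateVector, spec: PerturbationSpec, draw: np.ndarray
) -> RateVector:
    """Apply one multiplicative perturbation draw (one variate per
    constant); Gaussian perturbations are truncated at zero."""
    draw = np.asarray(draw, dtype=float)
    if draw.shape != rates.values.shape:
        raise ValueError("need exactly one variate per rate constant")
    if spec.distribution == "uniform":
        perturbed = rates.values * (1.0 + spec.strength * (2.0 * draw - 1.0))
    else:
        perturbed = rates.values * (1.0 + spec.strength * draw)
    return RateVector(np.maximum(perturbed, 0.0), rates.names)


@dataclass
class RobustnessSummary:
    observables: tuple[tuple[str, str], ...]
    unperturbed: np.ndarray  # x_i at eval_time, standard simulation
    means: np.ndarray  # mu_i over the ensemble
    variances: np.ndarray  # v_i, population variance
    n_sets: int
    n_failures: int
    spec: PerturbationSpec

    @property
    def average_behavior(self) -> float:
        """A = sum of ensemble-mean activities."""
        return float(self.means.sum())

    @property
    def nominal_behavior(self) -> float:
        """V = sum of ensemble variances."""
        return float(self.variances.sum())

    @property
    def unperturbed_total(self) -> float:
        return float(self.unperturbed.sum())


def ensemble_stats(
    network: ReactionNetwork,
    rates: RateVector,
    init: InitialCondition,
    ras: RasInput,
    spec: PerturbationSpec,
    observables: tuple[tuple[str, str], ...] = DEFAULT_OBSERVABLES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RobustnessSummary:
    """Simulate the unperturbed model and the perturbation ensemble;
    collect per-observable means and variances at the evaluation time.

    Individual integration failures are dropped and counted; more than
    50% failures aborts with diagnostics.
    """
    grid = np.array([0.0, spec.eval_time])

    def activities(r) -> np.ndarray:
        traj = simulate(network, r, init, ras, grid, rtol=rtol, atol=atol)
        state = traj.states[-1]
        return np.array([activity_at_state(network, state, k, c) for k, c in observables])

    x = activities(rates)
    draws = spec.draws(len(rates))
    samples = []
    failures = 0
    for i in range(spec.n_sets):
        try:
            samples.append(activities(perturb_rates(rates, spec, draws[i])))
        except IntegrationFailure:
            failures += 1
    if failures > 0.5 * spec.n_sets:
        raise RuntimeError(
            f"robustness ensemble unusable: {failures}/{spec.n_sets} perturbed "
            f"simulations failed (sigma={spec.strength}, {spec.distribution})"
        )
    sample = np.array(samples)
    variances = sample.var(axis=0)  # population variance
    # a bitwise-constant column has zero spread by definition; keep the
    # sigma = 0 identity exact instead of inheriting mean-rounding noise
    variances[np.all(sample == sample[0], axis=0)] = 0.0
    return RobustnessSummary(
        observables=tuple(observables),
        unperturbed=x,
        means=sample.mean(axis=0),
        variances=variances,
        n_sets=spec.n_sets,
        n_failures=failures,
        spec=spec,
    )


def rank_by_robustness(
    candidates: list[CandidateEstimate],
    summaries: list[RobustnessSummary],
) -> CandidateEstimate:
    """Final model selection among the low-error candidates.

    Returns the candidate with the smallest nominal behavior V; ties are
    broken by the smaller deviation of the average behavior A from the
    unperturbed activity sum, then by estimation error.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    if len(candidates) != len(summaries):
        raise ValueError("need one robustness summary per candidate")

    def key(pair):
        c, s = pair
        return (
            s.nominal_behavior,
            abs(s.average_behavior - s.unperturbed_total),
            c.error,
        )

    return min(zip(candidates, summaries), key=key)[0]
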