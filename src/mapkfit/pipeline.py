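"""End-to-end modeling pipeline.

Stages: (optional) synthetic data generation -> multi-start GA fitting ->
robustness analysis of the low-error candidates -> final selection by
nominal behavior -> (optional) phosphatase dose-response prediction.
Each stage writes its artifact (data.csv, candidates.json,
robustness.csv, final.json, dose_response.csv) plus a manifest with
seeds, the config hash and wall times, so every number is reproducible
and stages can be rerun in isolation.

A single global seed is split deterministically into per-stage seeds
(stage_seed = (global * 1000 + stage offset) mod 2^31).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import RasInput, build_initial_condition
from .inference import (
    GAConfig,
    ObjectiveSpec,
    interpolate_timecourse,
    make_objective,
    multi_start,
)
from .io import (
    config_hash,
    read_timecourse_csv,
    write_candidates,
    write_timecourse_csv,
)
from .network import build_canonical_network
from .robustness import PerturbationSpec, ensemble_stats, rank_by_robustness
from .scenarios import ScenarioSpec, dose_response
from .synthetic import SyntheticSpec, generate_dataset, sample_ground_truth

_STAGE_OFFSETS = {"synth": 1, "fit": 2, "robustness": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    system: str = "system1"
    data_csv: str | None = None  # measured data; None -> synthesize
    synth_cv: float = 0.1
    ga: GAConfig = field(default_factory=lambda: GAConfig().desk_scale())
    n_seeds: int = 20
    top_k: int = 10
    perturbation: PerturbationSpec = field(default_factory=lambda: PerturbationSpec(n_sets=1000))
    scenario: ScenarioSpec | None = None
    objective_rtol: float = 1e-8

    def validate(self) -> None:
        if self.top_k > self.n_seeds:
            raise ValueError("top_k cannot exceed n_seeds")
        if self.data_csv is None and self.synth_cv < 0:
            raise ValueError("synthetic noise cv must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ga"]["w_max"] = self.ga.w_max
        return d


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full flowchart; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network = build_canonical_network()
    init = build_initial_condition(config.system)
    ras = RasInput(peak_amplitude=init.ras_amplitude)
    manifest: dict = {
        "mapkfit_version": __version__,
        "config_hash": config_hash(config.to_dict()),
        "global_seed": config.seed,
        "n_species": network.n_species,
        "n_rate_constants": network.n_rates,
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()
        return lambda extra: manifest["stages"].__setitem__(
            name, {"wall_time_s": round(time.perf_counter() - t0, 3), **extra}
        )

    # -- data ----------------------------------------------------------
    done = _stage("data")
    truth = None
    if config.data_csv is not None:
        dataset = read_timecourse_csv(config.data_csv)
        done({"source": str(config.data_csv)})
    else:
        rng = np.random.default_rng(stage_seed(config.seed, "synth"))
        truth = sample_ground_truth(network, rng)
        spec = SyntheticSpec(
            ground_truth=truth,
            system=config.system,
            cv=config.synth_cv,
            seed=stage_seed(config.seed, "synth"),
        )
        dataset = generate_dataset(network, spec)
        write_timecourse_csv(dataset, outdir / "data.csv")
        (outdir / "truth.json").write_text(json.dumps(truth.as_dict(), indent=1))
        done({"source": "synthetic", "cv": config.synth_cv})

    # -- fit -------------------------------------------------------------
    done = _stage("fit")
    dense = interpolate_timecourse(dataset)
    obj_spec = ObjectiveSpec.for_dataset(dense)
    objective = make_objective(
        network, init, ras, dense, obj_spec, rtol=config.objective_rtol
    )
    ga = GAConfig(**{**config.ga.__dict__, "seed": stage_seed(config.seed, "fit")})
    candidates = multi_start(
        objective, network.n_rates, ga,
        n_seeds=config.n_seeds, top_k=config.top_k, rate_names=network.rate_names,
    )
    write_candidates(candidates, outdir / "candidates.json",
                     meta={"config_hash": manifest["config_hash"], "seed": ga.seed})
    fit_info = {"best_error": candidates[0].error, "n_candidates": len(candidates)}
    if truth is not None:
        fit_info["true_rates_error"] = objective(truth.values)
    done(fit_info)

    # -- robustness & final selection -----------------------------------
    done = _stage("robustness")
    selected = [c for c in candidates if c.selected]
    pspec = PerturbationSpec(
        **{**config.perturbation.__dict__, "seed": stage_seed(config.seed, "robustness")}
    )
    summaries = [
        ensemble_stats(network, c.rates, init, ras, pspec) for c in selected
    ]
    rows = []
    for c, s in zip(selected, summaries):
        for (kin, comp), mu, v, x in zip(s.observables, s.means, s.variances, s.unperturbed):
            rows.append({
                "candidate_seed": c.seed, "error": c.error, "kinase": kin,
                "compartment": comp, "mean": mu, "variance": v, "unperturbed": x,
                "average_behavior": s.average_behavior,
                "nominal_behavior": s.nominal_behavior, "failures": s.n_failures,
            })
    pd.DataFrame(rows).to_csv(outdir / "robustness.csv", index=False)
    final = rank_by_robustness(selected, summaries)
    write_candidates([final], outdir / "final.json",
                     meta={"config_hash": manifest["config_hash"], "seed": pspec.seed})
    done({"final_seed": final.seed, "final_error": final.error,
          "nominal_behavior": summaries[selected.index(final)].nominal_behavior})

    # -- scenarios -------------------------------------------------------
    if config.scenario is not None:
        done = _stage("scenarios")
        init2 = build_initial_condition("system2")
        ras2 = RasInput(peak_amplitude=init2.ras_amplitude)
        table = dose_response(network, final.rates, init2, ras2, config.scenario)
        table.to_csv(outdir / "dose_response.csv", index=False)
        done({"rows": len(table)})

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
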