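"""File formats: time-course CSV, candidate JSON records, YAML config.

The time-course CSV is long-format with header
``kinase,compartment,time_min,value,kind`` — one row per measurement.
Candidate estimates are stored as JSON (rates keyed by symbol, error,
seed, rank, selection flag, network parameter count) so any stage can be
rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import KINASES, T_REF
from .inference import CandidateEstimate, TimeCourseDataset
from .network import RateVector

VALID_COMPARTMENTS = ("cytosol", "nucleus", "total")
VALID_KINDS = ("normalized", "absolute", "raw")


def read_timecourse_csv(path: str | Path) -> TimeCourseDataset:
    """Read and validate a long-format time-course CSV.

    Malformed rows are reported with their line numbers; a normalized
    trace must include the 5-min anchor.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in ("kinase", "compartment", "time_min", "value", "kind")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    bad = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        if row["kinase"] not in KINASES:
            bad.append(f"line {line}: unknown kinase {row['kinase']!r}")
        if row["compartment"] not in VALID_COMPARTMENTS:
            bad.append(f"line {line}: unknown compartment {row['compartment']!r}")
        if row["kind"] not in VALID_KINDS:
            bad.append(f"line {line}: unknown kind {row['kind']!r}")
        if not np.isfinite(row["value"]):
            bad.append(f"line {line}: non-finite value")
    if bad:
        raise ValueError(f"{path}: " + "; ".join(bad))

    for (kin, comp, kind), g in frame.groupby(["kinase", "compartment", "kind"]):
        if kind == "normalized" and not np.any(np.isclose(g["time_min"], T_REF)):
            raise ValueError(
                f"{path}: normalized trace {kin}/{comp} lacks the t={T_REF} min anchor"
            )
    return TimeCourseDataset(frame)


def write_timecourse_csv(dataset: TimeCourseDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


def candidate_to_record(c: CandidateEstimate) -> dict:
    # names/values as parallel lists: rate order is meaningful and JSON
    # serialization must not re-sort it
    return {
        "rates": {"names": list(c.rates.names), "values": c.rates.values.tolist()},
        "error": c.error,
        "seed": c.seed,
        "rank": c.rank,
        "selected": c.selected,
        "n_rate_constants": len(c.rates),
    }


def record_to_candidate(rec: dict) -> CandidateEstimate:
    names = tuple(rec["rates"]["names"])
    values = np.array(rec["rates"]["values"], dtype=float)
    return CandidateEstimate(
        RateVector(values, names),
        error=rec["error"],
        seed=rec["seed"],
        rank=rec.get("rank", -1),
        selected=rec.get("selected", False),
    )


def write_candidates(candidates: list[CandidateEstimate], path: str | Path,
                     meta: dict | None = None) -> None:
    payload = {
        "meta": meta or {},
        "candidates": [candidate_to_record(c) for c in candidates],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_candidates(path: str | Path) -> list[CandidateEstimate]:
    payload = json.loads(Path(path).read_text())
    return [record_to_candidate(r) for r in payload["candidates"]]


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
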