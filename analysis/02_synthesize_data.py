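"""Generate the synthetic proteomic-style dataset used by the fitting
stages.

Samples a viable ground-truth rate vector (log-uniform, checked for
non-degenerate ERK activation on the absolute-concentration system),
simulates the normalized-concentration model (System 1), and emits the
five measured traces (Raf cytosol; MEK and ERK in cytosol and nucleus)
at 0, 1, 5, 10 and 20 min — noiseless and with 10% multiplicative
noise, each normalized to its own 5-min value.
"""

import json
from pathlib import Path

import numpy as np

from mapkfit import SyntheticSpec, build_canonical_network, generate_dataset, sample_ground_truth
from mapkfit.io import write_timecourse_csv

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 42


def main() -> None:
    network = build_canonical_network()
    truth = sample_ground_truth(network, np.random.default_rng(SEED))
    (OUT / "ground_truth.json").write_text(json.dumps(truth.as_dict(), indent=1))
    for cv, name in [(0.0, "synthetic_noiseless.csv"), (0.1, "synthetic_cv10.csv")]:
        ds = generate_dataset(network, SyntheticSpec(
            ground_truth=truth, system="system1", cv=cv, seed=SEED + 1))
        write_timecourse_csv(ds, OUT / name)
        print(f"cv={cv}: {len(ds.frame)} records -> {OUT / name}")
    print("traces per dataset: 5 (Raf cytosol, MEK/ERK x cytosol/nucleus), "
          "5 time points each, unit value at 5 min")


if __name__ == "__main__":
    main()
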