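"""Predict signal output under PP2A and MKP3 titration.

Takes the final rate estimate, switches to the absolute-concentration
system, and sweeps phosphatase scale 0.3-2x against Ras-GTP inputs
0.004-0.4, reading activated Raf, total MEK and total ERK at 5, 10 and
20 min. PP2A couples positively into Ras-Raf binding while scaling the
MEK phosphatase; MKP3 scales the ERK phosphatase fully but only a
quarter of the MEK phosphatase pool.
"""

from pathlib import Path

import pandas as pd

from mapkfit import RasInput, build_canonical_network, build_initial_condition
from mapkfit.io import read_candidates
from mapkfit.scenarios import ScenarioSpec, dose_response

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    network = build_canonical_network()
    init = build_initial_condition("system2")
    ras = RasInput(peak_amplitude=init.ras_amplitude)
    final = read_candidates(OUT / "final.json")[0]

    tables = []
    for phosphatase in ("PP2A", "MKP3"):
        spec = ScenarioSpec(phosphatase=phosphatase)
        tables.append(dose_response(network, final.rates, init, ras, spec))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT / "dose_response.csv", index=False, float_format="%.6g")
    print(f"wrote {len(table)} dose-response rows to {OUT / 'dose_response.csv'}")

    at10 = table[(table["readout_time"] == 10.0) & (table["kinase"] == "ERK")]
    for phosphatase in ("PP2A", "MKP3"):
        sub = at10[at10["phosphatase"] == phosphatase]
        for ras_level, g in sub.groupby("ras_level"):
            lo = g[g["scale"] == g["scale"].min()]["activity"].iloc[0]
            hi = g[g["scale"] == g["scale"].max()]["activity"].iloc[0]
            print(f"{phosphatase} Ras={ras_level}: total ERK at 10 min "
                  f"{lo:.4f} (scale 0.3) -> {hi:.4f} (scale 2.0)")


if __name__ == "__main__":
    main()
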