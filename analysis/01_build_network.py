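"""Assemble the canonical two-compartment MAPK network and export its
reaction table.

Reports the structural facts everything downstream relies on: 33 state
variables (10 free + 10 complexes in the cytosol, 7 free + 6 complexes
in the nucleus), 52 elementary reactions each with its own rate
constant, and the per-protein conservation groups.
"""

from pathlib import Path

from mapkfit import build_canonical_network

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    network = build_canonical_network()
    print(f"species (state variables): {network.n_species}")
    print(f"reactions / rate constants: {len(network.reactions)} / {network.n_rates}")
    for base, members in network.conservation_groups.items():
        print(f"  conserved pool {base}: {len(members)} species")
    frame = network.to_frame()
    frame.to_csv(OUT / "reaction_table.csv", index=False)
    print(f"\nwrote {len(frame)} reactions to {OUT / 'reaction_table.csv'}")


if __name__ == "__main__":
    main()
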