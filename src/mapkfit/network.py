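"""Canonical two-compartment MAPK reaction network.

The model follows the classical three-tier cascade (Raf -> MEK -> ERK)
driven by Ras-GTP, split into a cytosolic and a nuclear subsystem:

* Ras-GTP activates Raf in a single step (via a transient Ras:Raf complex).
* Raf* activates MEK processively (one encounter adds both phosphates;
  the singly-phosphorylated intermediate stays enzyme-bound).
* MEKpp activates ERK distributively (two separate binding events,
  free ERKp is released in between).
* Dedicated phosphatases (Raf-P'ase, MEK-P'ase, ERK-P'ase) reverse each
  activation; MEK dephosphorylation is processive, ERK distributive.
* Free MEK, MEKpp, ERK, ERKp and ERKpp shuttle between cytosol and
  nucleus; phosphatases do not shuttle, so the nuclear phosphatase pools
  are independent conserved quantities.

Ras-GTP is a clamped external input r(t): reactions consuming it multiply
their mass-action propensity by the momentary Ras activity, and the Ras
pool itself is never depleted.

Every nuclear reaction carries its own rate constant (kinetics may differ
between compartments), which makes 52 unknown rate constants for the
33-species network. The rate-constant count is always derived from the
assembled network, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CYTOSOL = "cytosol"
NUCLEUS = "nucleus"

#: base proteins with a conserved total (Ras is external and excluded)
CONSERVED_PROTEINS = (
    "Raf",
    "MEK",
    "ERK",
    "P_Raf",
    "P_MEK",
    "P_ERK",
    "N-P_MEK",
    "N-P_ERK",
)

BINDING = "binding"
DISSOCIATION = "dissociation"
CATALYSIS = "catalysis"
SHUTTLE = "shuttle"


@dataclass(frozen=True)
class Species:
    """One state variable: a protein form or complex in one compartment.

    ``proteins`` is the multiset of base proteins carried, as a sorted
    tuple of (base protein, phospho tag) pairs; tags are ``none``, ``p``,
    ``pp`` or ``active``.
    """

    name: str
    compartment: str
    proteins: tuple[tuple[str, str], ...]

    @property
    def is_complex(self) -> bool:
        return len(self.proteins) >= 2

    def bases(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.proteins)


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants``/``products`` are (species index, stoichiometry) pairs.
    ``ras_driven`` marks reactions whose propensity carries an extra
    factor of the external Ras activity.
    """

    reactants: tuple[tuple[int, int], ...]
    products: tuple[tuple[int, int], ...]
    rate_constant_id: int
    kind: str
    ras_driven: bool = False


@dataclass
class RateVector:
    """Ordered values of every unknown rate constant.

    Units: per-minute for dissociation, catalysis and shuttling constants;
    per-concentration-per-minute for binding constants (concentrations in
    the arbitrary units of the protein table).
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("rate vector length must match the name list")
        if np.any(self.values < 0):
            raise ValueError("rate constants must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **updates: float) -> "RateVector":
        """Return a copy with the named constants replaced."""
        idx = {n: i for i, n in enumerate(self.names)}
        vals = self.values.copy()
        for name, v in updates.items():
            vals[idx[name]] = v
        return RateVector(vals, self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    rate_names: tuple[str, ...]
    conservation_groups: dict[str, dict[int, int]] = field(default_factory=dict)

    # compiled mass-action arrays, filled by _compile()
    _stoich: np.ndarray = field(default=None, repr=False)
    _r1: np.ndarray = field(default=None, repr=False)
    _r2: np.ndarray = field(default=None, repr=False)
    _ras_mask: np.ndarray = field(default=None, repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_rates(self) -> int:
        return len(self.rate_names)

    @property
    def ras_driven_reactions(self) -> list[int]:
        return [i for i, r in enumerate(self.reactions) if r.ras_driven]

    def species_index(self, name: str) -> int:
        return self._index[name]

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("species names must be unique")
        self._validate()
        self._build_conservation_groups()
        self._compile()

    # -- construction-time checks -------------------------------------

    def _validate(self) -> None:
        used = [r.rate_constant_id for r in self.reactions]
        if sorted(used) != list(range(self.n_rates)):
            raise ValueError("every rate constant must be used exactly once")
        for i, rxn in enumerate(self.reactions):
            if rxn.kind == BINDING:
                # a Ras-driven binding takes its second reactant from the
                # clamped external Ras pool
                n_react = sum(s for _, s in rxn.reactants) + (1 if rxn.ras_driven else 0)
                if n_react != 2 or len(rxn.products) != 1:
                    raise ValueError(f"reaction {i}: binding must be 2 -> 1")
            elif rxn.kind in (DISSOCIATION, CATALYSIS):
                if len(rxn.reactants) != 1:
                    raise ValueError(f"reaction {i}: {rxn.kind} must be unimolecular")
            elif rxn.kind == SHUTTLE:
                if len(rxn.reactants) != 1 or len(rxn.products) != 1:
                    raise ValueError(f"reaction {i}: shuttle must be 1 -> 1")
                a = self.species[rxn.reactants[0][0]]
                b = self.species[rxn.products[0][0]]
                if a.compartment == b.compartment:
                    raise ValueError(f"reaction {i}: shuttle must change compartment")
            self._check_protein_balance(i, rxn)

    def _protein_count(self, side: tuple[tuple[int, int], ...]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for idx, stoich in side:
            for base in self.species[idx].bases():
                if base == "Ras":  # external driver, not conserved
                    continue
                counts[base] = counts.get(base, 0) + stoich
        return counts

    def _check_protein_balance(self, i: int, rxn: Reaction) -> None:
        lhs = self._protein_count(rxn.reactants)
        rhs = self._protein_count(rxn.products)
        if lhs != rhs:
            raise ValueError(
                f"reaction {i} does not conserve protein content: {lhs} -> {rhs}"
            )

    def _build_conservation_groups(self) -> None:
        groups: dict[str, dict[int, int]] = {p: {} for p in CONSERVED_PROTEINS}
        for i, sp in enumerate(self.species):
            for base in sp.bases():
                if base in groups:
                    groups[base][i] = groups[base].get(i, 0) + 1
        self.conservation_groups = groups

    def _compile(self) -> None:
        n_s, n_r = self.n_species, len(self.reactions)
        S = np.zeros((n_s, n_r))
        r1 = np.full(n_r, -1, dtype=np.intp)
        r2 = np.full(n_r, -1, dtype=np.intp)
        ras = np.zeros(n_r, dtype=bool)
        for j, rxn in enumerate(self.reactions):
            conc_factors: list[int] = []
            for idx, stoich in rxn.reactants:
                S[idx, j] -= stoich
                conc_factors.extend([idx] * stoich)
            for idx, stoich in rxn.products:
                S[idx, j] += stoich
            if len(conc_factors) > 2:
                raise ValueError("at most bimolecular reactions supported")
            if conc_factors:
                r1[j] = conc_factors[0]
            if len(conc_factors) == 2:
                r2[j] = conc_factors[1]
            ras[j] = rxn.ras_driven
        self._stoich, self._r1, self._r2, self._ras_mask = S, r1, r2, ras

    # -- export ---------------------------------------------------------

    def to_frame(self):
        """Tabular reaction list (one row per reaction)."""
        import pandas as pd

        rows = []
        for i, rxn in enumerate(self.reactions):
            fmt = lambda side: " + ".join(
                (f"{s}*" if s > 1 else "") + self.species[idx].name for idx, s in side
            )
            rows.append(
                {
                    "reaction_id": i,
                    "kind": rxn.kind,
                    "reactants": fmt(rxn.reactants) + (" [+Ras]" if rxn.ras_driven else ""),
                    "products": fmt(rxn.products),
                    "rate_symbol": self.rate_names[rxn.rate_constant_id],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# canonical network
# ---------------------------------------------------------------------


def build_canonical_network() -> ReactionNetwork:
    """Assemble the fixed canonical 33-species two-compartment network.

    Cytosol: single-step Raf activation by clamped Ras-GTP, processive
    MEK (de)activation, distributive ERK (de)activation. Shuttling of
    MEK, MEKpp, ERK, ERKp, ERKpp. Nucleus: distributive ERK activation
    by N-MEKpp, processive N-MEKpp deactivation, distributive N-ERK
    deactivation, all with their own rate constants.
    """
    species: list[Species] = []
    s_index: dict[str, int] = {}

    def add_species(name: str, compartment: str, *proteins: tuple[str, str]) -> int:
        sp = Species(name, compartment, tuple(sorted(proteins)))
        s_index[name] = len(species)
        species.append(sp)
        return s_index[name]

    # cytosolic free forms
    add_species("Raf", CYTOSOL, ("Raf", "none"))
    add_species("Raf*", CYTOSOL, ("Raf", "active"))
    add_species("MEK", CYTOSOL, ("MEK", "none"))
    add_species("MEKpp", CYTOSOL, ("MEK", "pp"))
    add_species("ERK", CYTOSOL, ("ERK", "none"))
    add_species("ERKp", CYTOSOL, ("ERK", "p"))
    add_species("ERKpp", CYTOSOL, ("ERK", "pp"))
    add_species("P_Raf", CYTOSOL, ("P_Raf", "none"))
    add_species("P_MEK", CYTOSOL, ("P_MEK", "none"))
    add_species("P_ERK", CYTOSOL, ("P_ERK", "none"))
    # cytosolic complexes
    add_species("Ras:Raf", CYTOSOL, ("Ras", "none"), ("Raf", "none"))
    add_species("Raf*:P_Raf", CYTOSOL, ("Raf", "active"), ("P_Raf", "none"))
    add_species("Raf*:MEK", CYTOSOL, ("Raf", "active"), ("MEK", "none"))
    add_species("Raf*:MEKp", CYTOSOL, ("Raf", "active"), ("MEK", "p"))
    add_species("P_MEK:MEKpp", CYTOSOL, ("P_MEK", "none"), ("MEK", "pp"))
    add_species("P_MEK:MEKp", CYTOSOL, ("P_MEK", "none"), ("MEK", "p"))
    add_species("MEKpp:ERK", CYTOSOL, ("MEK", "pp"), ("ERK", "none"))
    add_species("MEKpp:ERKp", CYTOSOL, ("MEK", "pp"), ("ERK", "p"))
    add_species("P_ERK:ERKpp", CYTOSOL, ("P_ERK", "none"), ("ERK", "pp"))
    add_species("P_ERK:ERKp", CYTOSOL, ("P_ERK", "none"), ("ERK", "p"))
    # nuclear free forms
    add_species("N-MEK", NUCLEUS, ("MEK", "none"))
    add_species("N-MEKpp", NUCLEUS, ("MEK", "pp"))
    add_species("N-ERK", NUCLEUS, ("ERK", "none"))
    add_species("N-ERKp", NUCLEUS, ("ERK", "p"))
    add_species("N-ERKpp", NUCLEUS, ("ERK", "pp"))
    add_species("N-P_MEK", NUCLEUS, ("N-P_MEK", "none"))
    add_species("N-P_ERK", NUCLEUS, ("N-P_ERK", "none"))
    # nuclear complexes
    add_species("N-MEKpp:N-ERK", NUCLEUS, ("MEK", "pp"), ("ERK", "none"))
    add_species("N-MEKpp:N-ERKp", NUCLEUS, ("MEK", "pp"), ("ERK", "p"))
    add_species("N-P_MEK:N-MEKpp", NUCLEUS, ("N-P_MEK", "none"), ("MEK", "pp"))
    add_species("N-P_MEK:N-MEKp", NUCLEUS, ("N-P_MEK", "none"), ("MEK", "p"))
    add_species("N-P_ERK:N-ERKpp", NUCLEUS, ("N-P_ERK", "none"), ("ERK", "pp"))
    add_species("N-P_ERK:N-ERKp", NUCLEUS, ("N-P_ERK", "none"), ("ERK", "p"))

    reactions: list[Reaction] = []
    rate_names: list[str] = []

    def rid(name: str) -> int:
        rate_names.append(name)
        return len(rate_names) - 1

    def rxn(kind, reactants, products, rate, ras_driven=False):
        reactions.append(
            Reaction(
                tuple((s_index[n], st) for n, st in reactants),
                tuple((s_index[n], st) for n, st in products),
                rid(rate),
                kind,
                ras_driven,
            )
        )

    def enzyme_cycle(enzyme, substrate, complex_, product, a, d, k):
        """Distributive step: E + S <-> E:S -> E + P."""
        rxn(BINDING, [(enzyme, 1), (substrate, 1)], [(complex_, 1)], a)
        rxn(DISSOCIATION, [(complex_, 1)], [(enzyme, 1), (substrate, 1)], d)
        rxn(CATALYSIS, [(complex_, 1)], [(enzyme, 1), (product, 1)], k)

    # (i) single-step Raf activation by clamped Ras-GTP
    rxn(BINDING, [("Raf", 1)], [("Ras:Raf", 1)], "a1", ras_driven=True)
    rxn(DISSOCIATION, [("Ras:Raf", 1)], [("Raf", 1)], "d1")
    rxn(CATALYSIS, [("Ras:Raf", 1)], [("Raf*", 1)], "k1")
    # (ii) Raf* deactivation
    enzyme_cycle("P_Raf", "Raf*", "Raf*:P_Raf", "Raf", "a2", "d2", "k2")
    # (iii) processive MEK activation: intermediate stays Raf*-bound
    rxn(BINDING, [("Raf*", 1), ("MEK", 1)], [("Raf*:MEK", 1)], "a3")
    rxn(DISSOCIATION, [("Raf*:MEK", 1)], [("Raf*", 1), ("MEK", 1)], "d3")
    rxn(CATALYSIS, [("Raf*:MEK", 1)], [("Raf*:MEKp", 1)], "k3")
    rxn(CATALYSIS, [("Raf*:MEKp", 1)], [("Raf*", 1), ("MEKpp", 1)], "k4")
    # (iv) processive MEK deactivation
    rxn(BINDING, [("MEKpp", 1), ("P_MEK", 1)], [("P_MEK:MEKpp", 1)], "a4")
    rxn(DISSOCIATION, [("P_MEK:MEKpp", 1)], [("MEKpp", 1), ("P_MEK", 1)], "d4")
    rxn(CATALYSIS, [("P_MEK:MEKpp", 1)], [("P_MEK:MEKp", 1)], "k5")
    rxn(CATALYSIS, [("P_MEK:MEKp", 1)], [("MEK", 1), ("P_MEK", 1)], "k6")
    # (v, vi) distributive ERK activation by MEKpp
    enzyme_cycle("MEKpp", "ERK", "MEKpp:ERK", "ERKp", "a5", "d5", "k7")
    enzyme_cycle("MEKpp", "ERKp", "MEKpp:ERKp", "ERKpp", "a6", "d6", "k8")
    # (vii, viii) distributive ERK deactivation
    enzyme_cycle("P_ERK", "ERKpp", "P_ERK:ERKpp", "ERKp", "a7", "d7", "k9")
    enzyme_cycle("P_ERK", "ERKp", "P_ERK:ERKp", "ERK", "a8", "d8", "k10")

    # shuttling between compartments (free kinase forms only)
    for cyt, nuc in [
        ("MEK", "N-MEK"),
        ("MEKpp", "N-MEKpp"),
        ("ERK", "N-ERK"),
        ("ERKp", "N-ERKp"),
        ("ERKpp", "N-ERKpp"),
    ]:
        rxn(SHUTTLE, [(cyt, 1)], [(nuc, 1)], f"kin_{cyt}")
        rxn(SHUTTLE, [(nuc, 1)], [(cyt, 1)], f"kout_{cyt}")

    # nuclear distributive ERK activation by N-MEKpp
    enzyme_cycle("N-MEKpp", "N-ERK", "N-MEKpp:N-ERK", "N-ERKp", "a9", "d9", "k11")
    enzyme_cycle("N-MEKpp", "N-ERKp", "N-MEKpp:N-ERKp", "N-ERKpp", "a10", "d10", "k12")
    # nuclear processive MEKpp deactivation
    rxn(BINDING, [("N-MEKpp", 1), ("N-P_MEK", 1)], [("N-P_MEK:N-MEKpp", 1)], "a11")
    rxn(DISSOCIATION, [("N-P_MEK:N-MEKpp", 1)], [("N-MEKpp", 1), ("N-P_MEK", 1)], "d11")
    rxn(CATALYSIS, [("N-P_MEK:N-MEKpp", 1)], [("N-P_MEK:N-MEKp", 1)], "k13")
    rxn(CATALYSIS, [("N-P_MEK:N-MEKp", 1)], [("N-MEK", 1), ("N-P_MEK", 1)], "k14")
    # nuclear distributive ERK deactivation
    enzyme_cycle("N-P_ERK", "N-ERKpp", "N-P_ERK:N-ERKpp", "N-ERKp", "a12", "d12", "k15")
    enzyme_cycle("N-P_ERK", "N-ERKp", "N-P_ERK:N-ERKp", "N-ERK", "a13", "d13", "k16")

    return ReactionNetwork(species, reactions, tuple(rate_names))


def make_rate_vector(network: ReactionNetwork, values) -> RateVector:
    return RateVector(np.asarray(values, dtype=float), network.rate_names)


def evaluate_derivatives(
    network: ReactionNetwork,
    rates: RateVector | np.ndarray,
    state: np.ndarray,
    ras_level: float,
) -> np.ndarray:
    """Mass-action right-hand side dx/dt at one state.

    Each reaction fires at (rate constant) x (product of reactant
    concentrations); Ras-driven reactions carry an extra factor of
    ``ras_level``. Returns the 33-vector of concentration derivatives.
    """
    k = rates.values if isinstance(rates, RateVector) else np.asarray(rates, float)
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(f"state must have length {network.n_species}")
    if k.shape != (network.n_rates,):
        raise ValueError(f"rates must have length {network.n_rates}")
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    if ras_level < 0:
        raise ValueError("Ras activity must be non-negative")
    return _rhs(network, k, state, ras_level)


def _rhs(network: ReactionNetwork, k: np.ndarray, state: np.ndarray, ras: float) -> np.ndarray:
    """Unchecked fast path used inside the integrator loop."""
    c1 = np.where(network._r1 >= 0, state[network._r1], 1.0)
    c2 = np.where(network._r2 >= 0, state[network._r2], 1.0)
    v = k * c1 * c2
    if ras != 1.0:
        v = np.where(network._ras_mask, v * ras, v)
    return network._stoich @ v


def conservation_totals(network: ReactionNetwork, state: np.ndarray) -> dict[str, float]:
    """Total concentration of each conserved base protein.

    Sums free and complex-bound forms across both compartments, counting
    complex stoichiometry (each complex carries one copy of each base).
    """
    state = np.asarray(state, dtype=float)
    totals = {}
    for base, members in network.conservation_groups.items():
        totals[base] = float(
            sum(count * state[idx] for idx, count in members.items())
        )
    return totals
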