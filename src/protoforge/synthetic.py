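"""Synthetic reaction networks with planted logic-gate motifs.

The generator emulates the structure of a merged BRENDA-style metabolic
network at desk scale: a pool of metabolites with pathway context tags, a
set of enzyme-catalysed reactions containing known gate motifs planted
verbatim, and seeded random decoy reactions.  Ground truth is returned
alongside the network so mining recall/soundness can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantError
from .gatedesign import TruthTable
from .kinetics import KineticParameters, RateLaw
from .netio import NetworkModel, Reaction, Species
from .reactorsim import MembraneSpec, ProtosensorModel, Reservoir

GATE_TYPES = ("BUF", "AND", "OR", "ANDN")

_GATE_TABLES = {
    "BUF": {(0,): (0,), (1,): (1,)},
    "AND": {(0, 0): (0,), (0, 1): (0,), (1, 0): (0,), (1, 1): (1,)},
    "OR": {(0, 0): (0,), (0, 1): (1,), (1, 0): (1,), (1, 1): (1,)},
    "ANDN": {(0, 0): (0,), (0, 1): (0,), (1, 0): (1,), (1, 1): (0,)},
}


def gate_table(gate_type: str, n_inputs: int | None = None) -> TruthTable:
    """Canonical truth table for a named gate over logical inputs A, B."""
    rows = _GATE_TABLES[gate_type]
    n = len(next(iter(rows)))
    return TruthTable.from_dict(("A", "B", "C")[:n], ("Y",), rows)


@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted gate."""

    gate_type: str
    reaction_ids: tuple[str, ...]
    input_species: tuple[str, ...]
    output_species: str
    enzymes: tuple[str, ...]


@dataclass
class PlantedNetworkConfig:
    """Random network with gate motifs planted verbatim.

    ``planted_motifs`` entries are (gate_type, input species ids, output
    species id) over the metabolite pool M00..M{n_species-1}.  The number of
    decoy reactions is ``decoy_density`` times the reaction budget left after
    planting, so density 0 yields exactly the planted reactions.
    """

    n_species: int
    n_reactions: int
    planted_motifs: list[tuple[str, tuple[str, ...], str]] = field(
        default_factory=list)
    decoy_density: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.decoy_density <= 1.0:
            raise InvariantError("decoy_density must be in [0, 1]")


def _metabolite_pool(n: int) -> list[str]:
    return [f"M{i:02d}" for i in range(n)]


def generate_planted_network(
        config: PlantedNetworkConfig) -> tuple[NetworkModel,
                                               list[PlantedMotif]]:
    """Deterministic (seeded) network + ground-truth motif list."""
    pool = _metabolite_pool(config.n_species)
    pool_set = set(pool)
    referenced = set()
    for gate, inputs, output in config.planted_motifs:
        if gate not in GATE_TYPES:
            raise InvariantError(f"unknown gate type {gate!r}")
        referenced |= set(inputs) | {output}
    if not referenced <= pool_set:
        raise InvariantError(
            f"planted species {sorted(referenced - pool_set)} exceed the "
            f"n_species={config.n_species} pool")

    rng = np.random.default_rng(config.seed)
    species = {m: Species(id=m, role="metabolite",
                          context_tag=f"pathway_{i % 4}")
               for i, m in enumerate(pool)}
    reactions: list[Reaction] = []
    truths: list[PlantedMotif] = []

    def new_enzyme(tag):
        eid = f"E{len([s for s in species.values() if s.role == 'enzyme']):02d}"
        species[eid] = Species(id=eid, role="enzyme", context_tag=tag)
        return eid

    for k, (gate, inputs, output) in enumerate(config.planted_motifs):
        tag = f"planted_{k}"
        for sp in (*inputs, output):
            species[sp] = Species(id=sp, role=species[sp].role,
                                  context_tag=tag)
        rids = []
        if gate == "BUF":
            e = new_enzyme(tag)
            rids = [f"Rp{k}_0"]
            reactions.append(Reaction(id=rids[0],
                                      substrates=[(inputs[0], 1)],
                                      products=[(output, 1)], enzyme=e))
            enz = (e,)
        elif gate == "AND":
            e = new_enzyme(tag)
            rids = [f"Rp{k}_0"]
            reactions.append(Reaction(
                id=rids[0], substrates=[(inputs[0], 1), (inputs[1], 1)],
                products=[(output, 1)], enzyme=e))
            enz = (e,)
        elif gate == "OR":
            e1, e2 = new_enzyme(tag), new_enzyme(tag)
            rids = [f"Rp{k}_0", f"Rp{k}_1"]
            reactions.append(Reaction(id=rids[0],
                                      substrates=[(inputs[0], 1)],
                                      products=[(output, 1)], enzyme=e1))
            reactions.append(Reaction(id=rids[1],
                                      substrates=[(inputs[1], 1)],
                                      products=[(output, 1)], enzyme=e2))
            enz = (e1, e2)
        else:  # ANDN: first input drives, second inhibits
            e = new_enzyme(tag)
            rids = [f"Rp{k}_0"]
            reactions.append(Reaction(id=rids[0],
                                      substrates=[(inputs[0], 1)],
                                      products=[(output, 1)], enzyme=e,
                                      inhibitors=[inputs[1]]))
            enz = (e,)
        truths.append(PlantedMotif(gate_type=gate,
                                   reaction_ids=tuple(sorted(rids)),
                                   input_species=tuple(inputs),
                                   output_species=output, enzymes=enz))

    n_planted = len(reactions)
    n_decoys = int(round(config.decoy_density
                         * max(config.n_reactions - n_planted, 0)))
    planted_outputs = {m.output_species for m in truths}
    for k in range(n_decoys):
        e = new_enzyme(f"decoy_{k % 5}")
        n_sub = int(rng.integers(1, 3))
        subs = list(rng.choice(pool, size=n_sub, replace=False))
        # decoys never produce a planted output: keeps ground truth exact
        prods = [p for p in rng.permutation(pool)
                 if p not in subs and p not in planted_outputs][:1]
        if not prods:
            continue
        reactions.append(Reaction(
            id=f"Rd{k:03d}", substrates=[(s, 1) for s in subs],
            products=[(p, 1) for p in prods], enzyme=e))

    model = NetworkModel(
        species=sorted(species.values(), key=lambda s: s.id),
        reactions=reactions,
        metadata={"source": f"planted(seed={config.seed})",
                  "planted": [m.gate_type for m in truths]})
    model.validate()
    return model, truths


# ---------------------------------------------------------------------------
# Planted-feasible design problems (optimizer ground truth)
# ---------------------------------------------------------------------------

class PlantedFeasibleProblem:
    """A single-gate protosensor whose nominal concentrations are feasible
    by construction: enzyme E converts the permeable input S into reporter P
    using the pre-loaded co-substrate C; the design spec requires P to cross
    N_on within the deadline.  Used to certify parameter recovery.
    """

    N_ON = 5e-6
    R_OFF = 5e-7

    def __init__(self, input_level: float = 1e-4, t_signal: float = 600.0,
                 horizon: float = 1800.0):
        from .designopt import DesignSpec
        self.input_level = input_level
        self.network = NetworkModel(
            species=[Species(id="S"), Species(id="C"),
                     Species(id="P", role="reporter"),
                     Species(id="Q"),
                     Species(id="E", role="enzyme")],
            reactions=[Reaction(id="R1", substrates=[("S", 1), ("C", 1)],
                                products=[("P", 1), ("Q", 1)], enzyme="E")])
        self.kinetics = KineticParameters(laws={
            "R1": RateLaw(mechanism="ordered_bibi", kcat=20.0,
                          Km_map={"S": 1e-4, "C": 5e-5}, Kia=5e-5)},
            source="synthetic")
        self.membrane = MembraneSpec(permeability={"S": 1.0})
        self.nominal = {"E": 5e-9, "C": 5e-5}
        self.tunables = ("E", "C")
        self.table = TruthTable.from_dict(("S",), ("P",),
                                          {(0,): (0,), (1,): (1,)})
        self.design = DesignSpec(table=self.table,
                                 input_levels={"S": input_level},
                                 thresholds={"P": (self.N_ON, self.R_OFF)},
                                 t_signal=t_signal, horizon=horizon)

    def rows(self):
        return self.table.sorted_rows()

    def _model(self, bits, params):
        interior = {"E": self.nominal["E"], "C": self.nominal["C"]}
        if params:
            interior.update(params)
        exterior = {"S": self.input_level if bits[0] else 0.0}
        return ProtosensorModel(network=self.network, kinetics=self.kinetics,
                                membrane=self.membrane,
                                interior_initial=interior, exterior=exterior,
                                reservoir=Reservoir())

    def simulate(self, bits, params, horizon=None):
        from .reactorsim import simulate_ode
        t_end = horizon if horizon is not None else self.design.horizon
        return simulate_ode(self._model(bits, params), t_end=t_end,
                            dt_out=10.0)

    def row_objective(self, bits, horizon=None):
        return self.design.row_formula(bits, horizon)
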