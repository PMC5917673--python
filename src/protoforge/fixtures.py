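"""The three reference protosensor circuits: GluONe, LacOH, GluNOx.

Each bundle pairs a reaction network with kinetic constants, a membrane
specification, initial interior concentrations and a temporal-logic design
specification at clinically meaningful input levels:

* **GluONe** (inputs glucose, acetone): glucose-1-dehydrogenase (G1DH)
  reduces NAD+ to NADH (output 1, 340 nm absorbance, reports glucose);
  a secondary alcohol dehydrogenase (ADH) spends that NADH reducing acetone
  to isopropanol, an alcohol oxidase (AOX) re-oxidizes isopropanol back to
  acetone releasing H2O2, and a peroxidase (HRP) converts H2O2 + Amplex Red
  into resorufin (output 2, 571-600 nm fluorescence) — so resorufin reports
  glucose AND acetone. 6 encapsulated entities, 4 enzymes.
* **LacOH** (inputs lactate, ethanol): lactate dehydrogenase and an ethanol
  dehydrogenase both reduce the shared NAD+ pool; a diaphorase transfers the
  electrons from NADH to ABTS (output 3, 420 nm) — lactate OR ethanol.
  5 entities, 3 enzymes; the small cycling NAD+ pool carries the
  "biochemical current" and rate-limits the response.
* **GluNOx** (inputs glucose, NOx): G1DH charges the NAD+/NADH carrier from
  glucose; a nitrate/nitrite reductase spends NADH to release NO, captured
  non-enzymatically by DAF into its fluorescent triazole (output 4,
  488-515 nm) — glucose AND NOx. 4 entities, 2 enzymes.

Kinetic constants and permeabilities are repo-curated plausible values in
BRENDA-typical ranges; clinical ON levels (glucose 1.39 mM, ketones 17 μM,
lactate 10 μM, ethanol 17.4 mM, NOx 1 mM) and the 10-μm / 60-min geometry
and horizon are the stated study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .designopt import DesignSpec
from .errors import FixtureLookupError
from .gatedesign import (CircuitImplementation, TruthTable, build_circuits,
                         mine_gates)
from .kinetics import KineticParameters, RateLaw
from .netio import NetworkModel, Reaction, Species, merge_networks
from .reactorsim import (CalibrationCurve, MembraneSpec, ObservedTruthTable,
                         ProtosensorModel, Reservoir, evaluate_truth_table,
                         simulate_ode)
from .synthetic import gate_table

FIXTURE_NAMES = ("gluone", "lacoh", "glunox")

# Clinical pathological ON thresholds, mol/L
ON_LEVELS = {
    "glucose": 1.39e-3,
    "acetone": 17e-6,
    "lactate": 10e-6,
    "ethanol": 17.4e-3,
    "NOx": 1e-3,
}

T_SIGNAL_S = 600.0     # measurable output required in < 10 min
HORIZON_S = 3600.0     # 60-minute simulations

# shared glucose-1-dehydrogenase step (identical in GluONe and GluNOx)
_G1DH_LAW = RateLaw(mechanism="ordered_bibi", kcat=100.0,
                    Km_map={"glucose": 2e-3, "NAD+": 1e-4}, Kia=1e-4)
_R_G1DH = dict(id="R_g1dh", substrates=[("glucose", 1), ("NAD+", 1)],
               products=[("gluconolactone", 1), ("NADH", 1)], enzyme="G1DH")


@dataclass
class FixtureCircuit:
    """A simulatable protosensor bundle; implements the design-problem
    protocol consumed by :mod:`protoforge.designopt`."""

    name: str
    network: NetworkModel
    kinetics: KineticParameters
    membrane: MembraneSpec
    design: DesignSpec
    interior_initial: dict[str, float]
    tunables: tuple[str, ...]
    calibration: dict[str, CalibrationCurve]
    shared_cofactors: frozenset[str] = frozenset()
    diameter_um: float = 10.0
    provenance: dict[str, str] = field(default_factory=dict)

    # -- model construction -------------------------------------------------

    @property
    def nominal(self) -> dict[str, float]:
        return {p: self.interior_initial[p] for p in self.tunables}

    @property
    def input_ids(self) -> tuple[str, ...]:
        return self.design.table.input_ids

    @property
    def output_ids(self) -> tuple[str, ...]:
        return self.design.table.output_ids

    def base_model(self, params: dict | None = None) -> ProtosensorModel:
        interior = dict(self.interior_initial)
        if params:
            interior.update(params)
        return ProtosensorModel(network=self.network, kinetics=self.kinetics,
                                membrane=self.membrane,
                                diameter_um=self.diameter_um,
                                interior_initial=interior, exterior={},
                                reservoir=Reservoir())

    def model_for(self, bits, params: dict | None = None) -> ProtosensorModel:
        levels = {sp: (self.design.input_levels[sp] if b else 0.0)
                  for sp, b in zip(self.input_ids, bits)}
        return self.base_model(params).with_overrides(exterior=levels)

    # -- design-problem protocol --------------------------------------------

    def rows(self):
        return self.design.table.sorted_rows()

    def simulate(self, bits, params=None, horizon=None, dt_out=15.0):
        t_end = horizon if horizon is not None else self.design.horizon
        return simulate_ode(self.model_for(bits, params), t_end=t_end,
                            dt_out=dt_out)

    def row_objective(self, bits, horizon=None):
        return self.design.row_formula(bits, horizon)

    # -- convenience --------------------------------------------------------

    def observed_table(self, params: dict | None = None,
                       levels: dict | None = None,
                       t_read: float | None = None, mode="encapsulated",
                       method="ode", dt_out=30.0) -> ObservedTruthTable:
        model = self.base_model(params)
        return evaluate_truth_table(
            model,
            input_levels={sp: (levels or self.design.input_levels)[sp]
                          for sp in self.input_ids},
            output_thresholds=self.design.thresholds,
            t_read=t_read if t_read is not None else self.design.horizon,
            mode=mode, method=method, dt_out=dt_out)

    def assemble(self, max_reactions: int = 2) -> CircuitImplementation:
        """Re-derive the circuit from its own network by mining + assembly."""
        library = []
        for table in (gate_table("BUF"), gate_table("AND")):
            library.extend(mine_gates(self.network, table, max_reactions))
        circuits = build_circuits(library, self.design.table,
                                  shared_cofactors=self.shared_cofactors)
        if not circuits:
            raise FixtureLookupError(
                f"assembly failed for {self.name}: {circuits.diagnostic}")
        return circuits[0]


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def _sp(sid, role="metabolite", tag=None):
    return Species(id=sid, role=role, context_tag=tag)


def _gluone() -> FixtureCircuit:
    network = NetworkModel(
        species=[
            _sp("glucose", tag="glycolysis"),
            _sp("acetone", tag="ketone_body"),
            _sp("NAD+", tag="redox_carrier"), _sp("NADH", "reporter",
                                                  "redox_carrier"),
            _sp("gluconolactone", tag="glycolysis"),
            _sp("isopropanol", tag="ketone_body"),
            _sp("H2O2", tag="peroxide"), _sp("AmplexRed", tag="peroxide"),
            _sp("Resorufin", "reporter", "peroxide"),
            _sp("G1DH", "enzyme", "glycolysis"),
            _sp("ADH", "enzyme", "ketone_body"),
            _sp("AOX", "enzyme", "ketone_body"),
            _sp("HRP", "enzyme", "peroxide"),
        ],
        reactions=[
            Reaction(**_R_G1DH),
            Reaction(id="R_adh", substrates=[("acetone", 1), ("NADH", 1)],
                     products=[("isopropanol", 1), ("NAD+", 1)],
                     enzyme="ADH"),
            Reaction(id="R_aox", substrates=[("isopropanol", 1)],
                     products=[("acetone", 1), ("H2O2", 1)], enzyme="AOX"),
            Reaction(id="R_hrp", substrates=[("H2O2", 1), ("AmplexRed", 1)],
                     products=[("Resorufin", 1)], enzyme="HRP"),
        ],
        metadata={"source": "fixture:gluone"})
    kinetics = KineticParameters(laws={
        "R_g1dh": _G1DH_LAW,
        "R_adh": RateLaw(mechanism="ordered_bibi", kcat=30.0,
                         Km_map={"acetone": 1.5e-4, "NADH": 1e-4}, Kia=1e-4),
        "R_aox": RateLaw(mechanism="mm_uni", kcat=30.0,
                         Km_map={"isopropanol": 5e-4}),
        "R_hrp": RateLaw(mechanism="pingpong_bibi", kcat=50.0,
                         Km_map={"H2O2": 5e-5, "AmplexRed": 2e-5}),
    }, source="repo-curated (BRENDA-typical ranges)")
    table = TruthTable.from_dict(
        ("glucose", "acetone"), ("NADH", "Resorufin"),
        {(0, 0): (0, 0), (0, 1): (0, 0), (1, 0): (1, 0), (1, 1): (1, 1)})
    design = DesignSpec(
        table=table,
        input_levels={sp: ON_LEVELS[sp] for sp in ("glucose", "acetone")},
        thresholds={"NADH": (2e-4, 2e-5), "Resorufin": (5e-6, 5e-7)},
        t_signal=T_SIGNAL_S, horizon=HORIZON_S)
    return FixtureCircuit(
        name="gluone", network=network, kinetics=kinetics,
        membrane=MembraneSpec(permeability={"glucose": 1.0, "acetone": 2.0}),
        design=design,
        interior_initial={"G1DH": 2e-8, "ADH": 1.5e-8, "AOX": 3e-7,
                          "HRP": 1e-7, "NAD+": 5e-3, "AmplexRed": 1e-4},
        tunables=("G1DH", "ADH", "AOX", "HRP", "NAD+", "AmplexRed"),
        calibration={
            "NADH": CalibrationCurve("NADH", "absorbance", "340",
                                     gain=6.22e3),
            "Resorufin": CalibrationCurve("Resorufin", "fluorescence",
                                          "571-600", gain=1e6)},
        provenance={
            "paper-stated": "inputs, outputs/wavelengths, 6 entities / "
                            "4 enzymes, clinical ON levels, 10 μm, 60 min, "
                            "10-min signal deadline",
            "repo-chosen": "kcat/Km/Kia values, permeabilities, pool sizes, "
                           "output thresholds, calibration gains"})


def _lacoh() -> FixtureCircuit:
    network = NetworkModel(
        species=[
            _sp("lactate", tag="lactate_metabolism"),
            _sp("ethanol", tag="ethanol_metabolism"),
            _sp("NAD+", tag="redox_carrier"), _sp("NADH", "reporter",
                                                  "redox_carrier"),
            _sp("pyruvate", tag="lactate_metabolism"),
            _sp("acetaldehyde", tag="ethanol_metabolism"),
            _sp("ABTSox", tag="reporter_pool"),
            _sp("ABTS", "reporter", "reporter_pool"),
            _sp("LDH", "enzyme", "lactate_metabolism"),
            _sp("ADHe", "enzyme", "ethanol_metabolism"),
            _sp("DIA", "enzyme", "reporter_pool"),
        ],
        reactions=[
            Reaction(id="R_ldh", substrates=[("lactate", 1), ("NAD+", 1)],
                     products=[("pyruvate", 1), ("NADH", 1)], enzyme="LDH"),
            Reaction(id="R_adhe", substrates=[("ethanol", 1), ("NAD+", 1)],
                     products=[("acetaldehyde", 1), ("NADH", 1)],
                     enzyme="ADHe"),
            Reaction(id="R_dia", substrates=[("NADH", 1), ("ABTSox", 1)],
                     products=[("NAD+", 1), ("ABTS", 1)], enzyme="DIA"),
        ],
        metadata={"source": "fixture:lacoh"})
    kinetics = KineticParameters(laws={
        "R_ldh": RateLaw(mechanism="ordered_bibi", kcat=100.0,
                         Km_map={"lactate": 2e-5, "NAD+": 5e-5}, Kia=5e-5),
        "R_adhe": RateLaw(mechanism="ordered_bibi", kcat=50.0,
                          Km_map={"ethanol": 5e-3, "NAD+": 5e-5}, Kia=5e-5),
        "R_dia": RateLaw(mechanism="pingpong_bibi", kcat=50.0,
                         Km_map={"NADH": 2e-4, "ABTSox": 5e-5}),
    }, source="repo-curated (BRENDA-typical ranges)")
    table = TruthTable.from_dict(
        ("lactate", "ethanol"), ("ABTS",),
        {(0, 0): (0,), (0, 1): (1,), (1, 0): (1,), (1, 1): (1,)})
    design = DesignSpec(
        table=table,
        input_levels={sp: ON_LEVELS[sp] for sp in ("lactate", "ethanol")},
        thresholds={"ABTS": (3e-5, 3e-6)},
        t_signal=T_SIGNAL_S, horizon=HORIZON_S)
    return FixtureCircuit(
        name="lacoh", network=network, kinetics=kinetics,
        membrane=MembraneSpec(permeability={"lactate": 1.0, "ethanol": 2.0}),
        design=design,
        interior_initial={"LDH": 2.4e-7, "ADHe": 8e-8, "DIA": 1.3e-7,
                          "NAD+": 2e-5, "ABTSox": 5e-4},
        tunables=("LDH", "ADHe", "DIA", "NAD+", "ABTSox"),
        shared_cofactors=frozenset({"NAD+"}),
        calibration={"ABTS": CalibrationCurve("ABTS", "absorbance", "420",
                                              gain=3.6e4)},
        provenance={
            "paper-stated": "inputs, ABTS output at 420 nm, 5 entities / "
                            "3 enzymes, NAD+ pool as most sensitive "
                            "parameter, clinical ON levels",
            "repo-chosen": "kcat/Km/Kia values, permeabilities, pool sizes, "
                           "output thresholds, calibration gains"})


def _glunox() -> FixtureCircuit:
    network = NetworkModel(
        species=[
            _sp("glucose", tag="glycolysis"),
            _sp("NOx", tag="nitrogen_oxide"),
            _sp("NAD+", tag="redox_carrier"), _sp("NADH", "reporter",
                                                  "redox_carrier"),
            _sp("gluconolactone", tag="glycolysis"),
            _sp("NO", tag="nitrogen_oxide"),
            _sp("DAF", tag="nitrogen_oxide"),
            _sp("DAFT", "reporter", "nitrogen_oxide"),
            _sp("G1DH", "enzyme", "glycolysis"),
            _sp("NR", "enzyme", "nitrogen_oxide"),
        ],
        reactions=[
            Reaction(**_R_G1DH),
            Reaction(id="R_nr", substrates=[("NOx", 1), ("NADH", 1)],
                     products=[("NO", 1), ("NAD+", 1)], enzyme="NR"),
            Reaction(id="R_daf", substrates=[("NO", 1), ("DAF", 1)],
                     products=[("DAFT", 1)], enzyme=None),
        ],
        metadata={"source": "fixture:glunox"})
    kinetics = KineticParameters(laws={
        "R_g1dh": _G1DH_LAW,
        "R_nr": RateLaw(mechanism="ordered_bibi", kcat=40.0,
                        Km_map={"NOx": 2e-4, "NADH": 5e-5}, Kia=1e-4),
        "R_daf": RateLaw(mechanism="mass_action", k=1e5),
    }, source="repo-curated (BRENDA-typical ranges)")
    table = TruthTable.from_dict(
        ("glucose", "NOx"), ("DAFT",),
        {(0, 0): (0,), (0, 1): (0,), (1, 0): (0,), (1, 1): (1,)})
    design = DesignSpec(
        table=table,
        input_levels={sp: ON_LEVELS[sp] for sp in ("glucose", "NOx")},
        thresholds={"DAFT": (5e-6, 5e-7)},
        t_signal=T_SIGNAL_S, horizon=HORIZON_S)
    return FixtureCircuit(
        name="glunox", network=network, kinetics=kinetics,
        membrane=MembraneSpec(permeability={"glucose": 1.0, "NOx": 5.0}),
        design=design,
        interior_initial={"G1DH": 8e-9, "NR": 1.2e-8, "NAD+": 3e-5,
                          "DAF": 5e-5},
        tunables=("G1DH", "NR", "NAD+", "DAF"),
        calibration={"DAFT": CalibrationCurve("DAFT", "fluorescence",
                                              "488-515", gain=1e6)},
        provenance={
            "paper-stated": "inputs, DAF output at 488-515 nm, 4 entities / "
                            "2 enzymes, clinical ON levels",
            "repo-chosen": "kcat/Km/Kia values, permeabilities, pool sizes, "
                           "output thresholds, calibration gains"})


_BUILDERS = {"gluone": _gluone, "lacoh": _lacoh, "glunox": _glunox}


def load_fixture(name: str) -> FixtureCircuit:
    """Load one of the three reference protosensor bundles."""
    try:
        return _BUILDERS[name.lower()]()
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Multiplexing (batch vs encapsulated co-simulation)
# ---------------------------------------------------------------------------

@dataclass
class MultiplexReport:
    """Expected vs observed output bits for co-deployed circuits."""

    mode: str
    inputs_present: tuple[str, ...]
    expected: dict[str, tuple[int, ...]]   # fixture name -> expected bits
    observed: dict[str, tuple[int | None, ...]]
    readouts: dict[str, dict[str, float]]

    def incorrect(self) -> list[str]:
        return [name for name in self.expected
                if self.observed[name] != self.expected[name]]

    @property
    def all_correct(self) -> bool:
        return not self.incorrect()


def _digitize(value, n_on, r_off):
    if value >= n_on:
        return 1
    if value <= r_off:
        return 0
    return None


def multiplex_simulation(fixtures: list[FixtureCircuit],
                         inputs_present: set[str], mode: str,
                         t_read: float = HORIZON_S,
                         dt_out: float = 30.0) -> MultiplexReport:
    """Co-simulate several circuits sharing one sample.

    Batch mode merges all networks into one well-mixed volume (interior
    pools add; shared species such as the NAD+/NADH couple become one pool).
    Encapsulated mode keeps each circuit behind its own membrane facing the
    common infinite reservoir, so the protosensors evolve independently.
    """
    expected, observed, readouts = {}, {}, {}
    levels_all = {sp: ON_LEVELS[sp] for sp in inputs_present}

    if mode == "encapsulated":
        for fx in fixtures:
            bits = tuple(int(sp in inputs_present) for sp in fx.input_ids)
            expected[fx.name] = fx.design.table.rows[bits]
            levels = {sp: levels_all.get(sp, 0.0) for sp in fx.input_ids}
            trace = simulate_ode(fx.base_model().with_overrides(
                exterior=levels), t_end=t_read, dt_out=dt_out)
            obs, vals = [], {}
            for out in fx.output_ids:
                n_on, r_off = fx.design.thresholds[out]
                c = trace.final(out)
                vals[out] = c
                obs.append(_digitize(c, n_on, r_off))
            observed[fx.name] = tuple(obs)
            readouts[fx.name] = vals
    elif mode == "batch":
        network = merge_networks([fx.network for fx in fixtures])
        laws = {}
        for fx in fixtures:
            laws.update(fx.kinetics.laws)
        interior: dict[str, float] = {}
        for fx in fixtures:
            for sp, c in fx.interior_initial.items():
                interior[sp] = interior.get(sp, 0.0) + c
        for sp, c in levels_all.items():
            interior[sp] = interior.get(sp, 0.0) + c
        model = ProtosensorModel(
            network=network, kinetics=KineticParameters(laws=laws),
            membrane=None, interior_initial=interior, exterior={},
            reservoir=Reservoir())
        trace = simulate_ode(model, t_end=t_read, dt_out=dt_out)
        for fx in fixtures:
            bits = tuple(int(sp in inputs_present) for sp in fx.input_ids)
            expected[fx.name] = fx.design.table.rows[bits]
            obs, vals = [], {}
            for out in fx.output_ids:
                n_on, r_off = fx.design.thresholds[out]
                c = trace.final(out)
                vals[out] = c
                obs.append(_digitize(c, n_on, r_off))
            observed[fx.name] = tuple(obs)
            readouts[fx.name] = vals
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return MultiplexReport(mode=mode,
                           inputs_present=tuple(sorted(inputs_present)),
                           expected=expected, observed=observed,
                           readouts=readouts)
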