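"""Simulate circuits inside membrane-bounded spherical microreactors.

A protosensor is a spherical compartment (default diameter 10 μm) whose
membrane is rendered permeable to selected small molecules by pores; the
transport flux follows Fick's law, dC_in/dt = pore_scale * P * (A/V) *
(c_out - c_in) with A/V = 6/d for a sphere.  Macromolecules (enzymes) are
retained (P = 0).  Deterministic dynamics integrate mass-action/Michaelian
rate laws plus transport with a stiff-capable solver; stochastic dynamics
run an exact Gillespie direct method over reaction channels (bi-bi channels
use the mesoscopic Michaelis-Menten propensity, valid when substrate counts
greatly exceed enzyme counts) and per-molecule transport channels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _ssa
from .errors import IntegrityError, InvariantError, SimulationError
from .kinetics import AVOGADRO, KineticParameters, reaction_rate
from .netio import NetworkModel

DEFAULT_DIAMETER_UM = 10.0      # protosensor diameter
DEFAULT_HORIZON_S = 3600.0      # 60-minute runs
DEFAULT_READOUT_S = 3600.0      # truth tables read at 60 min
DEFAULT_N_TRAJ = 5              # trajectories averaged per transfer-map point


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass
class MembraneSpec:
    """Permeabilities in μm/s (absent => retained) and a pore-density scale."""

    permeability: dict[str, float] = field(default_factory=dict)
    pore_scale: float = 1.0

    def __post_init__(self):
        if self.pore_scale < 0:
            raise InvariantError("pore_scale must be >= 0")
        for sp, p in self.permeability.items():
            if p < 0:
                raise InvariantError(f"permeability of {sp!r} must be >= 0")

    def p(self, species_id: str) -> float:
        return self.permeability.get(species_id, 0.0)


@dataclass
class Reservoir:
    mode: str = "infinite"          # "infinite" or "finite"
    volume_L: float | None = None   # exterior volume for finite mode

    def __post_init__(self):
        if self.mode not in ("infinite", "finite"):
            raise InvariantError(f"unknown reservoir mode {self.mode!r}")
        if self.mode == "finite" and (self.volume_L is None
                                      or self.volume_L <= 0):
            raise InvariantError("finite reservoir requires volume_L > 0")


@dataclass
class ProtosensorModel:
    """Circuit + spherical compartment + membrane: the simulatable object."""

    network: NetworkModel
    kinetics: KineticParameters
    membrane: MembraneSpec | None = None
    diameter_um: float = DEFAULT_DIAMETER_UM
    interior_initial: dict[str, float] = field(default_factory=dict)
    exterior: dict[str, float] = field(default_factory=dict)
    reservoir: Reservoir = field(default_factory=Reservoir)

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise InvariantError("diameter must be > 0")
        self.network.validate()
        self.kinetics.validate_against(self.network)
        known = {s.id for s in self.network.species}
        for table in (self.interior_initial, self.exterior):
            for sp, c in table.items():
                if sp not in known:
                    raise IntegrityError(f"unknown species {sp!r}")
                if c < 0:
                    raise InvariantError(f"negative concentration for {sp!r}")
        if self.membrane is not None:
            by_id = self.network.species_by_id()
            for sp, p in self.membrane.permeability.items():
                if p > 0 and sp in by_id and by_id[sp].role == "enzyme":
                    raise InvariantError(
                        f"macromolecule {sp!r} must be retained (P = 0)")

    @property
    def volume_L(self) -> float:
        d_dm = self.diameter_um * 1e-5   # μm -> dm; dm^3 = L
        return math.pi / 6.0 * d_dm ** 3

    def with_overrides(self, interior: dict | None = None,
                       exterior: dict | None = None) -> "ProtosensorModel":
        new_int = dict(self.interior_initial)
        new_ext = dict(self.exterior)
        if interior:
            new_int.update(interior)
        if exterior:
            new_ext.update(exterior)
        return ProtosensorModel(
            network=self.network, kinetics=self.kinetics,
            membrane=self.membrane, diameter_um=self.diameter_um,
            interior_initial=new_int, exterior=new_ext,
            reservoir=self.reservoir)

    def batch_mode(self, inputs: dict[str, float]) -> "ProtosensorModel":
        """Well-mixed, membrane-free variant with inputs in the same volume."""
        interior = dict(self.interior_initial)
        for sp, c in inputs.items():
            interior[sp] = interior.get(sp, 0.0) + c
        return ProtosensorModel(
            network=self.network, kinetics=self.kinetics, membrane=None,
            diameter_um=self.diameter_um, interior_initial=interior,
            exterior={}, reservoir=Reservoir())


@dataclass
class Trace:
    """Time-indexed concentrations (mol/L) of all species."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvariantError("times must start at 0 and strictly increase")

    def at(self, species_id: str, t: float) -> float:
        """Piecewise-constant (last-sample) value at time t."""
        i = int(np.searchsorted(self.times, t, side="right") - 1)
        return float(self.concentrations[species_id][max(i, 0)])

    def final(self, species_id: str) -> float:
        return float(self.concentrations[species_id][-1])


@dataclass
class CalibrationCurve:
    """Affine concentration -> optical signal map for one output species."""

    species_id: str
    modality: str                 # "absorbance" or "fluorescence"
    wavelength_nm: str | float
    gain: float                   # signal per mol/L
    offset: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise InvariantError("calibration gain must be > 0")


def calibrate_signal(curve: CalibrationCurve, concentration: float) -> float:
    """signal = gain * C + offset (AU)."""
    if concentration < 0:
        raise InvariantError("concentration must be >= 0")
    return curve.gain * concentration + curve.offset


# ---------------------------------------------------------------------------
# Fick transport
# ---------------------------------------------------------------------------

def membrane_rate(spec: MembraneSpec, species_id: str, c_out: float,
                  c_in: float, diameter_um: float) -> float:
    """Fick flux into the compartment, mol/L/s; zero for retained species."""
    P = spec.p(species_id)
    if P == 0.0:
        return 0.0
    return spec.pore_scale * P * (6.0 / diameter_um) * (c_out - c_in)


# ---------------------------------------------------------------------------
# Compilation helpers
# ---------------------------------------------------------------------------

class _Compiled:
    def __init__(self, model: ProtosensorModel):
        self.model = model
        self.species = [s.id for s in model.network.species]
        self.index = {sp: i for i, sp in enumerate(self.species)}
        self.reactions = []
        n = len(self.species)
        for r in model.network.reactions:
            law = model.kinetics.law_for(r.id)
            stoich = np.zeros(n)
            for sp, c in r.substrates:
                stoich[self.index[sp]] -= c
            for sp, c in r.products:
                stoich[self.index[sp]] += c
            if law.mechanism == "mass_action":
                slot_ids = [sp for sp, c in r.substrates for _ in range(c)]
            else:
                slot_ids = list(law.slots)
            self.reactions.append({
                "id": r.id, "law": law, "stoich": stoich,
                "enzyme": self.index[r.enzyme] if r.enzyme else None,
                "slots": [(sp, self.index[sp]) for sp in slot_ids],
                "inhibitors": [self.index[i] for i in r.inhibitors]})
        mem = model.membrane
        self.transport = []
        if mem is not None:
            kt = mem.pore_scale * 6.0 / model.diameter_um
            for sp, P in sorted(mem.permeability.items()):
                if P > 0 and sp in self.index:
                    self.transport.append(
                        (self.index[sp], kt * P,
                         model.exterior.get(sp, 0.0)))

    def y0(self):
        y = np.zeros(len(self.species))
        for sp, c in self.model.interior_initial.items():
            y[self.index[sp]] = c
        return y


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------

def simulate_ode(model: ProtosensorModel, t_end: float,
                 dt_out: float = 10.0, rtol: float = 1e-8,
                 atol: float = 1e-14, method: str = "LSODA") -> Trace:
    """Deterministic trajectory; non-negativity enforced by clipping."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    comp = _Compiled(model)
    finite = model.reservoir.mode == "finite"
    n = len(comp.species)
    ratio = (model.volume_L / model.reservoir.volume_L) if finite else 0.0

    def rhs(t, y):
        yc = np.maximum(y[:n], 0.0)
        dy = np.zeros_like(y)
        for rx in comp.reactions:
            law = rx["law"]
            if law.mechanism == "mass_action":
                v = law.k
                for _, i in rx["slots"]:   # stoichiometric multiplicity kept
                    v *= yc[i]
            else:
                enz = yc[rx["enzyme"]] if rx["enzyme"] is not None else 0.0
                v = reaction_rate(law, enz, {sp: yc[i]
                                             for sp, i in rx["slots"]})
            if v != 0.0 and any(yc[i] > 0.0 for i in rx["inhibitors"]):
                v = 0.0  # discrete on/off inhibition
            if v != 0.0:
                dy[:n] += rx["stoich"] * v
        for i, kp, c_out in comp.transport:
            ext = max(y[n + i], 0.0) if finite else c_out
            flux = kp * (ext - yc[i])
            dy[i] += flux
            if finite:
                dy[n + i] -= ratio * flux
        return dy

    y0 = comp.y0()
    if finite:
        yext = np.zeros(n)
        for sp, c in model.exterior.items():
            yext[comp.index[sp]] = c
        y0 = np.concatenate([y0, yext])

    grid = np.arange(0.0, t_end + dt_out / 2, dt_out)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=grid,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}",
                              last_state=(sol.t[-1] if sol.t.size else 0.0,
                                          sol.y[:, -1] if sol.y.size else y0))
    conc = np.maximum(sol.y[:n], 0.0)
    return Trace(times=sol.t,
                 concentrations={sp: conc[i] for sp, i in comp.index.items()})


# ---------------------------------------------------------------------------
# SSA simulation
# ---------------------------------------------------------------------------

_MECH_CODE = {"mass_action": 0, "mm_uni": 1, "ordered_bibi": 2,
              "pingpong_bibi": 3, "random_bibi": 4}


def simulate_ssa(model: ProtosensorModel, t_end: float, seed: int,
                 dt_out: float = 10.0,
                 max_steps: int = 50_000_000) -> Trace:
    """Exact Gillespie direct-method trajectory, reproducible per seed."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if model.reservoir.mode != "infinite":
        raise InvariantError("SSA supports the infinite-reservoir mode only")
    comp = _Compiled(model)
    nav = AVOGADRO * model.volume_L
    nr = len(comp.reactions)
    n = len(comp.species)

    mech = np.zeros(nr, dtype=np.int64)
    kcat = np.zeros(nr)
    km1 = np.zeros(nr)
    km2 = np.zeros(nr)
    kia = np.zeros(nr)
    alpha = np.ones(nr)
    kmass = np.zeros(nr)
    sub1 = np.full(nr, -1, dtype=np.int64)
    sub2 = np.full(nr, -1, dtype=np.int64)
    enz = np.full(nr, -1, dtype=np.int64)
    inh1 = np.full(nr, -1, dtype=np.int64)
    inh2 = np.full(nr, -1, dtype=np.int64)
    stoich = np.zeros((nr, n), dtype=np.int64)

    for r, rx in enumerate(comp.reactions):
        law = rx["law"]
        mech[r] = _MECH_CODE[law.mechanism]
        stoich[r] = np.round(rx["stoich"]).astype(np.int64)
        slots = rx["slots"]
        if len(slots) > 2:
            raise InvariantError(
                f"SSA supports at most bimolecular channels ({rx['id']})")
        if len(rx["inhibitors"]) > 2:
            raise InvariantError(
                f"SSA supports at most two inhibitors ({rx['id']})")
        if slots:
            sub1[r] = slots[0][1]
        if len(slots) == 2:
            sub2[r] = slots[1][1]
        for k, idx in enumerate(rx["inhibitors"][:2]):
            (inh1 if k == 0 else inh2)[r] = idx
        if law.mechanism == "mass_action":
            kmass[r] = law.k
        else:
            kcat[r] = law.kcat
            km1[r] = law.Km_map[law.slots[0]]
            if len(law.slots) == 2:
                km2[r] = law.Km_map[law.slots[1]]
            kia[r] = law.Kia if law.Kia is not None else 0.0
            alpha[r] = law.alpha
            if rx["enzyme"] is not None:
                enz[r] = rx["enzyme"]

    trans_sp = np.array([i for i, _, _ in comp.transport], dtype=np.int64)
    trans_kout = np.array([kp for _, kp, _ in comp.transport])
    trans_kin = np.array([kp * c_out * nav
                          for _, kp, c_out in comp.transport])

    grid = np.arange(0.0, t_end + dt_out / 2, dt_out)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    n0 = np.round(comp.y0() * nav).astype(np.int64)

    counts, steps, status = _ssa.ssa_kernel(
        n0, float(t_end), grid, mech, kcat, km1, km2, kia, alpha, kmass,
        sub1, sub2, enz, inh1, inh2, stoich, trans_sp, trans_kin, trans_kout,
        float(nav), int(seed) & 0x7FFFFFFF, int(max_steps))
    if status == _ssa.STATUS_MAX_STEPS:
        raise SimulationError(
            f"SSA exceeded {max_steps} events; molecule counts are too "
            "large for an exact trajectory — use simulate_ode instead",
            last_state=counts)
    return Trace(times=grid,
                 concentrations={sp: counts[:, i] / nav
                                 for sp, i in comp.index.items()},
                 seed=seed)


# ---------------------------------------------------------------------------
# Truth tables and transfer maps
# ---------------------------------------------------------------------------

@dataclass
class ObservedTruthTable:
    """Digitized readouts: bit 1 iff C >= N_on, 0 iff C <= R_off, else None."""

    input_ids: tuple[str, ...]
    output_ids: tuple[str, ...]
    rows: dict[tuple[int, ...], tuple[int | None, ...]]
    margins: dict[tuple[int, ...], dict[str, float]]
    readouts: dict[tuple[int, ...], dict[str, float]]
    t_read: float

    def indeterminate_rows(self):
        return [bits for bits, out in self.rows.items() if None in out]

    def matches(self, expected: dict[tuple[int, ...], tuple[int, ...]]) -> bool:
        return all(self.rows.get(bits) == tuple(out)
                   for bits, out in expected.items())

    def incorrect_rows(self, expected) -> list[tuple[int, ...]]:
        return [bits for bits, out in expected.items()
                if self.rows.get(bits) != tuple(out)]


def evaluate_truth_table(model: ProtosensorModel,
                         input_levels: dict[str, float],
                         output_thresholds: dict[str, tuple[float, float]],
                         t_read: float = DEFAULT_READOUT_S,
                         mode: str = "encapsulated",
                         method: str = "ode", dt_out: float = 30.0,
                         seed: int = 0) -> ObservedTruthTable:
    """Simulate every input combination and digitize outputs at ``t_read``.

    Encapsulated mode puts ON inputs in the exterior reservoir; batch mode
    removes the membrane and mixes inputs into one well-mixed volume.
    The digitization margin is C - N_on for an ON call and R_off - C for an
    OFF call; levels between the thresholds are reported as indeterminate
    (None), never silently rounded.
    """
    for out, (n_on, r_off) in output_thresholds.items():
        if not n_on > r_off >= 0:
            raise InvariantError(
                f"thresholds for {out!r} must satisfy N_on > R_off >= 0")
    inputs = tuple(input_levels)
    outputs = tuple(output_thresholds)
    rows, margins, readouts = {}, {}, {}
    for bits in itertools.product((0, 1), repeat=len(inputs)):
        levels = {sp: (input_levels[sp] if b else 0.0)
                  for sp, b in zip(inputs, bits)}
        if mode == "encapsulated":
            m = model.with_overrides(exterior=levels)
        elif mode == "batch":
            m = model.batch_mode(levels)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if method == "ode":
            trace = simulate_ode(m, t_end=t_read, dt_out=dt_out)
        else:
            trace = simulate_ssa(m, t_end=t_read, seed=seed, dt_out=dt_out)
        out_bits, row_margin, row_val = [], {}, {}
        for out in outputs:
            n_on, r_off = output_thresholds[out]
            c = trace.final(out)
            row_val[out] = c
            if c >= n_on:
                out_bits.append(1)
                row_margin[out] = c - n_on
            elif c <= r_off:
                out_bits.append(0)
                row_margin[out] = r_off - c
            else:
                out_bits.append(None)
                row_margin[out] = -min(n_on - c, c - r_off)
        rows[bits] = tuple(out_bits)
        margins[bits] = row_margin
        readouts[bits] = row_val
    return ObservedTruthTable(inputs, outputs, rows, margins, readouts,
                              t_read)


@dataclass
class TransferMap:
    """Mean calibrated output signals over a grid of input concentrations."""

    input_ids: tuple[str, ...]
    grids: dict[str, np.ndarray]
    outputs: dict[str, np.ndarray]   # output species -> ndarray over grid
    t_read: float
    n_traj: int

    def to_frame(self):
        import pandas as pd
        recs = []
        shape = next(iter(self.outputs.values())).shape
        for idx in np.ndindex(*shape):
            rec = {sp: self.grids[sp][k]
                   for sp, k in zip(self.input_ids, idx)}
            for out, arr in self.outputs.items():
                rec[out] = arr[idx]
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def transfer_map(model: ProtosensorModel, input_grids: dict[str, np.ndarray],
                 output_ids: tuple[str, ...], t_read: float = DEFAULT_READOUT_S,
                 n_traj: int = DEFAULT_N_TRAJ, base_seed: int = 0,
                 method: str = "ssa", dt_out: float = 60.0,
                 curves: dict[str, CalibrationCurve] | None = None,
                 mode: str = "encapsulated") -> TransferMap:
    """Per grid point, mean over ``n_traj`` seeded trajectories at ``t_read``."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if any(len(g) == 0 for g in input_grids.values()):
        raise ValueError("grids must be non-empty")
    inputs = tuple(input_grids)
    shape = tuple(len(input_grids[sp]) for sp in inputs)
    outputs = {out: np.zeros(shape) for out in output_ids}
    for idx in np.ndindex(*shape):
        levels = {sp: float(input_grids[sp][k])
                  for sp, k in zip(inputs, idx)}
        if mode == "encapsulated":
            m = model.with_overrides(exterior=levels)
        else:
            m = model.batch_mode(levels)
        vals = {out: [] for out in output_ids}
        if method == "ode":
            trace = simulate_ode(m, t_end=t_read, dt_out=dt_out)
            for out in output_ids:
                vals[out].append(trace.final(out))
        else:
            for k in range(n_traj):
                trace = simulate_ssa(m, t_end=t_read, seed=base_seed + k,
                                     dt_out=dt_out)
                for out in output_ids:
                    vals[out].append(trace.final(out))
        for out in output_ids:
            mean = float(np.mean(vals[out]))
            if curves and out in curves:
                mean = calibrate_signal(curves[out], mean)
            outputs[out][idx] = mean
    return TransferMap(inputs, {sp: np.asarray(g)
                                for sp, g in input_grids.items()},
                       outputs, t_read, n_traj)


# ---------------------------------------------------------------------------
# Signal-to-noise
# ---------------------------------------------------------------------------

def signal_to_noise_db(on_values, off_values) -> float:
    """SNR_dB = 10*log10((mu_ON - mu_OFF)^2 / sigma^2_pooled).

    Pooled variance is the mean of the two group variances (sample, ddof=1).
    Returns -inf when the group means coincide.
    """
    on = np.asarray(on_values, dtype=float)
    off = np.asarray(off_values, dtype=float)
    if on.size < 2 or off.size < 2:
        raise InvariantError("signal_to_noise_db needs >= 2 values per group")
    dmu = on.mean() - off.mean()
    if dmu == 0.0:
        return -math.inf
    pooled = (on.var(ddof=1) + off.var(ddof=1)) / 2.0
    if pooled == 0.0:
        return math.inf
    return 10.0 * math.log10(dmu * dmu / pooled)
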