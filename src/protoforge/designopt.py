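"""Sensitivity ranking, satisfaction-degree landscapes and CMA-ES tuning of
initial concentrations against a temporal-logic design specification.

A *design problem* is any object exposing:

- ``rows()``                      -> iterable of input bit tuples
- ``simulate(bits, params, horizon)`` -> Trace (ODE, deterministic)
- ``row_objective(bits, horizon)``    -> (Formula, objective dict)
- ``tunables``                    -> ordered tuple of parameter names
- ``nominal``                     -> dict name -> nominal value (mol/L)

The fitness of a parameter vector is the aggregate satisfaction degree: the
minimum over truth-table rows of the distance-based degree of that row's
formula.  Once a vector satisfies the full specification (sd = 1), the
optimizer keeps improving the robustness margin — the minimum normalized
distance from the objective thresholds to the boundary of each row's
validity domain — so the returned design is not merely feasible but
centred in the feasible region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantError, SimulationError
from .gatedesign import TruthTable
from .tlogic import (And, Atom, Formula, Temporal, domain_margin, formula,
                     satisfaction_degree)

log = logging.getLogger(__name__)

DEFAULT_T_EVAL_S = 300.0     # landscape maps computed at 5 min
DEFAULT_SWEEP_POINTS = 9     # one-at-a-time sweep, +/- 1 decade
DEFAULT_BOUND_DECADES = 3.0  # search bounds nominal x/÷ 10^3


# ---------------------------------------------------------------------------
# Design specifications
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Per-row temporal-logic requirements derived from a truth table.

    ON outputs must cross N_on within ``t_signal`` seconds; OFF outputs must
    stay at or below R_off throughout the horizon.  The aggregate rule over
    rows is the minimum.
    """

    table: TruthTable
    input_levels: dict[str, float]                 # ON concentrations, mol/L
    thresholds: dict[str, tuple[float, float]]     # output -> (N_on, R_off)
    t_signal: float = 600.0                        # s
    horizon: float = 3600.0                        # s

    def __post_init__(self):
        for out, (n_on, r_off) in self.thresholds.items():
            if not n_on > r_off >= 0:
                raise InvariantError(
                    f"{out!r}: N_on > R_off >= 0 required")
        if self.t_signal > self.horizon:
            raise InvariantError("t_signal must not exceed the horizon")

    def row_formula(self, bits: tuple[int, ...],
                    horizon: float | None = None) -> tuple[Formula, dict]:
        """Formula + objective thresholds for one input combination."""
        h = self.horizon if horizon is None else horizon
        deadline = min(self.t_signal, h)
        expected = self.table.rows[tuple(bits)]
        parts, objective = [], {}
        for out, bit in zip(self.table.output_ids, expected):
            n_on, r_off = self.thresholds[out]
            if bit:
                var = f"N_{out}"
                parts.append(Temporal("F", Atom(out, ">=", var), 0.0,
                                      deadline))
                objective[var] = n_on
            else:
                var = f"R_{out}"
                parts.append(Temporal("G", Atom(out, "<=", var), 0.0, h))
                objective[var] = r_off
        root = parts[0]
        for p in parts[1:]:
            root = And(root, p)
        return formula(root), objective


# ---------------------------------------------------------------------------
# Aggregate satisfaction degree
# ---------------------------------------------------------------------------

def _row_scores(problem, params, horizon):
    """Per-row (sd, margin); margin is 0 for an unsatisfied row."""
    scores = []
    for bits in problem.rows():
        try:
            trace = problem.simulate(bits, params, horizon)
        except SimulationError as exc:
            log.warning("simulation failed for row %s: %s", bits, exc)
            scores.append((0.0, 0.0))
            continue
        f, objective = problem.row_objective(bits, horizon)
        res = satisfaction_degree(trace, f, objective)
        margin = 0.0
        if res.boolean_value:
            margin = domain_margin(res.domain, objective)
        scores.append((res.satisfaction_degree, margin))
    return scores


def aggregate_sd(problem, params: dict[str, float] | None = None,
                 horizon: float | None = None) -> float:
    """Minimum satisfaction degree over all truth-table rows."""
    return min(sd for sd, _ in _row_scores(problem, params or {}, horizon))


def aggregate_scores(problem, params=None, horizon=None):
    scores = _row_scores(problem, params or {}, horizon)
    return min(s for s, _ in scores), min(m for _, m in scores)


# ---------------------------------------------------------------------------
# Sensitivity analysis (one-at-a-time log sweeps)
# ---------------------------------------------------------------------------

@dataclass
class SensitivityEntry:
    name: str
    grid: np.ndarray
    sds: np.ndarray
    score: float     # max sd - min sd over the sweep


@dataclass
class SensitivityRanking:
    entries: list[SensitivityEntry]

    def ranked(self) -> list[SensitivityEntry]:
        return sorted(self.entries, key=lambda e: (-e.score, e.name))

    def top(self, k: int = 2) -> list[str]:
        return [e.name for e in self.ranked()[:k]]


def sensitivity_rank(problem, tunables: list[str] | None = None,
                     points: int = DEFAULT_SWEEP_POINTS,
                     decades: float = 1.0,
                     horizon: float | None = None) -> SensitivityRanking:
    """Score each parameter by the sd range over a log sweep about nominal."""
    tunables = list(tunables if tunables is not None else problem.tunables)
    if len(tunables) < 2:
        raise InvariantError("sensitivity_rank needs >= 2 tunable parameters")
    entries = []
    for name in tunables:
        nominal = problem.nominal[name]
        grid = nominal * np.power(10.0, np.linspace(-decades, decades, points))
        sds = np.array([aggregate_sd(problem, {name: float(v)}, horizon)
                        for v in grid])
        entries.append(SensitivityEntry(name=name, grid=grid, sds=sds,
                                        score=float(sds.max() - sds.min())))
    return SensitivityRanking(entries=entries)


# ---------------------------------------------------------------------------
# 2-D satisfaction-degree landscapes
# ---------------------------------------------------------------------------

@dataclass
class LandscapeMap:
    """Per-cell satisfaction degrees over two log-spaced parameter axes."""

    p1: str
    p2: str
    grid1: np.ndarray
    grid2: np.ndarray
    per_row: dict[tuple[int, ...], np.ndarray]
    aggregate: np.ndarray
    t_eval: float

    def to_frame(self):
        import pandas as pd
        recs = []
        for i, v1 in enumerate(self.grid1):
            for j, v2 in enumerate(self.grid2):
                rec = {self.p1: v1, self.p2: v2,
                       "aggregate_sd": self.aggregate[i, j]}
                for bits, arr in self.per_row.items():
                    rec["sd_row_" + "".join(map(str, bits))] = arr[i, j]
                recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def plot(self, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        pm = ax.pcolormesh(self.grid2, self.grid1, self.aggregate,
                           vmin=0.0, vmax=1.0, shading="nearest")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"{self.p2} (mol/L)")
        ax.set_ylabel(f"{self.p1} (mol/L)")
        ax.set_title(f"aggregate satisfaction degree at {self.t_eval:.0f} s")
        fig.colorbar(pm, ax=ax, label="sd")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def landscape_map(problem, p1: str, p2: str, grid1, grid2,
                  t_eval: float = DEFAULT_T_EVAL_S) -> LandscapeMap:
    """Satisfaction-degree map over the two most sensitive parameters."""
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    if grid1.size < 1 or grid2.size < 1:
        raise ValueError("grids must be non-empty")
    rows = list(problem.rows())
    per_row = {tuple(b): np.zeros((grid1.size, grid2.size)) for b in rows}
    agg = np.zeros((grid1.size, grid2.size))
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            params = {p1: float(v1), p2: float(v2)}
            scores = _row_scores(problem, params, t_eval)
            for bits, (sd, _) in zip(rows, scores):
                per_row[tuple(bits)][i, j] = sd
            agg[i, j] = min(sd for sd, _ in scores)
    return LandscapeMap(p1, p2, grid1, grid2, per_row, agg, t_eval)


# ---------------------------------------------------------------------------
# CMA-ES
# ---------------------------------------------------------------------------

class CMAES:
    """(mu/mu_w, lambda) covariance matrix adaptation evolution strategy.

    Minimizes over a box in R^n; ask/tell interface; samples outside the
    bounds are projected onto them before evaluation.
    """

    def __init__(self, x0, sigma0, lower, upper, popsize=None, rng=None):
        self.n = len(x0)
        self.mean = np.array(x0, dtype=float)
        self.sigma = float(sigma0)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.rng = rng if rng is not None else np.random.default_rng()

        n = self.n
        self.lam = popsize or (4 + int(3 * math.log(n)))
        self.mu = self.lam // 2
        w = np.log((self.lam + 1) / 2) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.ds = 1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) \
            + self.cs
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

        self.C = np.eye(n)
        self.ps = np.zeros(n)
        self.pc = np.zeros(n)
        self.gen = 0

    def ask(self):
        vals, vecs = np.linalg.eigh(self.C)
        vals = np.maximum(vals, 1e-20)
        self._B = vecs
        self._D = np.sqrt(vals)
        z = self.rng.standard_normal((self.lam, self.n))
        y = z * self._D[None, :]
        y = y @ self._B.T
        x = self.mean[None, :] + self.sigma * y
        return np.clip(x, self.lower[None, :], self.upper[None, :])

    def tell(self, xs, fitnesses):
        order = np.argsort(fitnesses, kind="stable")
        sel = np.asarray(xs)[order[:self.mu]]
        old_mean = self.mean
        self.mean = self.weights @ sel

        y = (self.mean - old_mean) / self.sigma
        c_inv_half = self._B @ np.diag(1.0 / self._D) @ self._B.T
        self.ps = (1 - self.cs) * self.ps + \
            math.sqrt(self.cs * (2 - self.cs) * self.mueff) * (c_inv_half @ y)
        self.gen += 1
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * self.gen))
                / self.chiN) < (1.4 + 2 / (self.n + 1))
        self.pc = (1 - self.cc) * self.pc + \
            (math.sqrt(self.cc * (2 - self.cc) * self.mueff) * y
             if hsig else 0.0)

        artmp = (sel - old_mean[None, :]) / self.sigma
        rank_mu = sum(w * np.outer(a, a) for w, a in zip(self.weights, artmp))
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (0 if hsig else 1) * self.cc
                               * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.C = (self.C + self.C.T) / 2
        self.sigma *= math.exp(
            (self.cs / self.ds)
            * (np.linalg.norm(self.ps) / self.chiN - 1))


# ---------------------------------------------------------------------------
# Optimization of initial concentrations
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    best_params: dict[str, float]
    best_sd: float
    best_margin: float
    evaluations: int
    seed: int
    history: list[float] = field(default_factory=list)  # best-so-far sd
    warning: str | None = None


def optimize_parameters(problem, bounds: dict | None = None, seed: int = 0,
                        budget: int = 30, sigma0: float = 0.5,
                        popsize: int | None = None,
                        horizon: float | None = None,
                        x0: dict | None = None) -> OptimizationResult:
    """CMA-ES over log10 concentrations maximizing the aggregate sd.

    ``budget`` counts generations.  Fitness is 1 - sd while the spec is
    unsatisfied, then switches to -margin so any satisfying vector dominates
    and the robustness margin keeps improving; a fixed seed yields an
    identical trajectory.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1 generation")
    names = list(problem.tunables)
    nominal = np.array([problem.nominal[p] for p in names])
    if np.any(nominal <= 0):
        raise InvariantError("nominal concentrations must be positive")
    if bounds is None:
        lo = nominal / 10.0 ** DEFAULT_BOUND_DECADES
        hi = nominal * 10.0 ** DEFAULT_BOUND_DECADES
    else:
        lo = np.array([bounds[p][0] for p in names])
        hi = np.array([bounds[p][1] for p in names])
    if np.any(lo <= 0) or np.any(~np.isfinite(hi)):
        raise InvariantError("bounds must be finite and positive")

    llo, lhi = np.log10(lo), np.log10(hi)
    start = np.log10(np.array([x0[p] for p in names])) if x0 \
        else np.log10(np.clip(nominal, lo, hi))
    rng = np.random.default_rng(seed)

    evals = 0

    def fitness(logx):
        nonlocal evals
        params = {p: float(10.0 ** v) for p, v in zip(names, logx)}
        sd, margin = aggregate_scores(problem, params, horizon)
        evals += 1
        return ((1.0 - sd) if sd < 1.0 else -margin), sd, margin, params

    f0, sd0, m0, p0 = fitness(start)
    best = (f0, sd0, m0, p0)
    history = [sd0]

    es = CMAES(start, sigma0, llo, lhi, popsize=popsize, rng=rng)
    for _ in range(budget):
        xs = es.ask()
        fits = []
        for x in xs:
            f, sd, margin, params = fitness(x)
            fits.append(f)
            if f < best[0]:
                best = (f, sd, margin, params)
        es.tell(xs, fits)
        history.append(max(history[-1], best[1]))

    warning = None
    if best[1] < 1.0 and best[1] <= sd0:
        warning = "no satisfying vector found within budget"
    return OptimizationResult(best_params=best[3], best_sd=best[1],
                              best_margin=best[2], evaluations=evals,
                              seed=seed, history=history, warning=warning)


# ---------------------------------------------------------------------------
# Threshold-crossing helper (deadline verification)
# ---------------------------------------------------------------------------

def first_crossing_time(trace, species_id: str, threshold: float) -> float:
    """First sampled time at which the species reaches the threshold (inf if
    never)."""
    c = np.asarray(trace.concentrations[species_id])
    idx = np.nonzero(c >= threshold)[0]
    if idx.size == 0:
        return math.inf
    i = int(idx[0])
    if i == 0:
        return float(trace.times[0])
    # linear interpolation between the bracketing samples
    t0, t1 = trace.times[i - 1], trace.times[i]
    c0, c1 = c[i - 1], c[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (threshold - c0) / (c1 - c0) * (t1 - t0))
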