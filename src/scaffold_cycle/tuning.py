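"""Tuning analysis: the scaffold as a control knob of response dynamics.

For a fixed kinetic parameter set, sweeping total scaffold concentration
(T_total) — or resampling the four scaffold-enzyme binding constants
k7..k10 — can move the motif between adaptive (w above threshold) and
ultrasensitive (F above threshold) behaviour.  "Modulation" is declared
when the two thresholds are reached at two *different* points of the same
sweep.

A pinned boundary-regime parameter set (found by pre-screening for sets
jointly close to both thresholds; see ``data/boundary_set.json``) serves
as the repository's reproducible witness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from scaffold_cycle import _kernel
from scaffold_cycle.motif_model import ConcentrationTotals, RateConstants
from scaffold_cycle.screen import (
    F_THRESHOLD,
    W_THRESHOLD,
    evaluate_parameter_set,
)
from scaffold_cycle.scoring import PulseProtocol, StaircaseProtocol

DEFAULT_T_GRID = (1e-4, 10.0, 64)        # lo, hi, points (log-spaced)
DEFAULT_S_TOTALS = (0.1, 0.3, 1.0, 3.0)  # uM, log-spaced in the feasible range


@dataclass(frozen=True)
class SweepSpec:
    """A sweep of one tuning quantity around a fixed base parameter set."""

    rates: RateConstants
    totals: ConcentrationTotals              # base totals (T_total = base point)
    sweep: str = "t_total"                   # "t_total" | "affinity"
    t_grid: tuple = DEFAULT_T_GRID           # (lo, hi, n) for t_total sweeps
    n_affinity: int = 64                     # resampling count for affinity sweeps
    affinity_range: tuple = (1e-3, 1e3)      # log-uniform range for k7..k10
    seed: int = 0

    def __post_init__(self):
        if self.sweep not in ("t_total", "affinity"):
            raise ValueError("sweep must be 't_total' or 'affinity'")
        lo, hi, n = self.t_grid
        if not (0 < lo < hi) or int(n) < 1:
            raise ValueError("invalid t_total grid")

    def grid_values(self) -> np.ndarray:
        lo, hi, n = self.t_grid
        return np.geomspace(lo, hi, int(n))


@dataclass
class SweepResult:
    """Scores along a sweep, plus the modulation verdict's raw material."""

    spec: SweepSpec
    swept: np.ndarray        # (n,) T_total values or (n, 4) affinity draws
    table: pd.DataFrame      # full per-point screen records
    F: np.ndarray
    w: np.ndarray
    ok: np.ndarray


def _evaluate_grid(spec: SweepSpec, rate_sets, total_sets,
                   staircase, pulses) -> SweepResult:
    rows = []
    for i, (r, t) in enumerate(zip(rate_sets, total_sets)):
        rows.append(evaluate_parameter_set(
            r, t, staircase, pulses, index=i, seed=spec.seed,
            regime="sweep",
        ))
    table = pd.DataFrame(rows)
    return table


def sweep_scaffold_concentration(spec: SweepSpec,
                                 staircase: StaircaseProtocol | None = None,
                                 pulses: PulseProtocol | None = None,
                                 ) -> SweepResult:
    """Score the base set at every T_total grid point, all else fixed.

    Per-point solver failures are flagged in the table and the sweep
    continues.  Deterministic given the spec.
    """
    grid = spec.grid_values()
    totals = [ConcentrationTotals(spec.totals.S_total, 0.0,
                                  spec.totals.P_total, float(t))
              for t in grid]
    table = _evaluate_grid(spec, [spec.rates] * len(grid), totals,
                           staircase, pulses)
    table.insert(0, "T_total_swept", grid)
    return SweepResult(
        spec=spec, swept=grid, table=table,
        F=table["F"].to_numpy(), w=table["w"].to_numpy(),
        ok=(table["ok_staircase"] & table["ok_pulse"]).to_numpy(),
    )


def sweep_affinities(spec: SweepSpec,
                     staircase: StaircaseProtocol | None = None,
                     pulses: PulseProtocol | None = None) -> SweepResult:
    """Resample the scaffold-enzyme constants k7..k10 log-uniformly.

    All other rates and totals stay at the base set's values.  The first
    grid point is the unperturbed base set itself (so a zero-width range
    degenerates to the base scores).
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.rates.as_array()
    lo, hi = spec.affinity_range
    draws = np.empty((spec.n_affinity, 4))
    rate_sets = []
    for i in range(spec.n_affinity):
        k = base.copy()
        if i > 0:
            if lo < hi:
                aff = np.exp(rng.uniform(np.log(lo), np.log(hi), size=4))
            else:
                aff = np.full(4, lo)
            k[6], k[7], k[8], k[9] = aff
        draws[i] = k[[6, 7, 8, 9]]
        rate_sets.append(RateConstants.from_array(k))
    totals = [spec.totals.with_K_total(0.0)] * spec.n_affinity
    table = _evaluate_grid(spec, rate_sets, totals, staircase, pulses)
    for j, name in enumerate(("k7_swept", "k8_swept", "k9_swept",
                              "k10_swept")):
        table.insert(j, name, draws[:, j])
    return SweepResult(
        spec=spec, swept=draws, table=table,
        F=table["F"].to_numpy(), w=table["w"].to_numpy(),
        ok=(table["ok_staircase"] & table["ok_pulse"]).to_numpy(),
    )


@dataclass(frozen=True)
class ModulationVerdict:
    modulated: bool
    adaptive_idx: int | None     # witnessing grid point with w >= threshold
    ultra_idx: int | None        # different grid point with F >= threshold
    same_point_only: bool        # both thresholds met, but only at one point
    w_threshold: float
    f_threshold: float

    def __bool__(self):
        return self.modulated


def detect_modulation(result: SweepResult,
                      w_threshold: float = W_THRESHOLD,
                      f_threshold: float = F_THRESHOLD) -> ModulationVerdict:
    """Does the sweep reach both dynamic regimes at distinct points?

    True iff there exist grid points a != b with w(a) >= w_threshold and
    F(b) >= f_threshold.  A single point clearing both thresholds does not
    count as modulation (the point is reported separately).
    """
    if len(result.F) == 0:
        raise ValueError("empty sweep result")
    w = np.where(result.ok, result.w, -np.inf)
    F = np.where(result.ok, result.F, -np.inf)
    w_hits = np.flatnonzero(w >= w_threshold)
    f_hits = np.flatnonzero(F >= f_threshold)
    for a in w_hits:
        for b in f_hits:
            if a != b:
                return ModulationVerdict(True, int(a), int(b), False,
                                         w_threshold, f_threshold)
    same = bool(len(w_hits) and len(f_hits))
    return ModulationVerdict(False,
                             int(w_hits[0]) if len(w_hits) else None,
                             int(f_hits[0]) if len(f_hits) else None,
                             same, w_threshold, f_threshold)


def threshold_interval_lengths(result: SweepResult,
                               w_threshold: float = W_THRESHOLD,
                               f_threshold: float = F_THRESHOLD) -> dict:
    """Log-length of the swept-grid regions exceeding each threshold.

    Used to test how substrate level stretches the ultrasensitive vs
    adaptive T_total windows.  Counts grid points (log-uniform grid, so
    point counts are proportional to log-interval length).
    """
    w = np.where(result.ok, result.w, -np.inf)
    F = np.where(result.ok, result.F, -np.inf)
    return {
        "n_adaptive": int((w >= w_threshold).sum()),
        "n_ultrasensitive": int((F >= f_threshold).sum()),
    }


def _sweep_objective(k_arr, S_total, P_total, seed,
                     n_grid: int = 12) -> float:
    """min(best-F/0.8, best-w/0.3) over a coarse scaffold sweep.

    >= 1 means the set modulates between both dynamic regimes somewhere
    along the scaffold axis.
    """
    rates = RateConstants.from_array(k_arr)
    totals = ConcentrationTotals(S_total, 0.0, P_total, 1.0)
    spec = SweepSpec(rates=rates, totals=totals,
                     t_grid=(1e-4, 10.0, n_grid), seed=seed)
    res = sweep_scaffold_concentration(spec)
    F = np.where(res.ok, res.F, 0.0)
    w = np.where(res.ok, res.w, 0.0)
    return min(np.max(F) / F_THRESHOLD, np.max(w) / W_THRESHOLD)


def find_boundary_set(n_samples: int = 2000, seed: int = 0,
                      regime: str = "saturated",
                      n_candidates: int = 5,
                      refine_steps: int = 1200) -> dict:
    """Locate a boundary-regime witness by screening plus local refinement.

    Screens ``n_samples`` sets and ranks them by min(F/0.8, w/0.3) (jointly
    close to both dynamic regimes).  Because randomly sampled sets rarely
    reach the adaptive threshold outright, the top candidates are refined
    by a seeded stochastic hill-climb on the kinetic constants, maximising
    the same joint criterion evaluated at each candidate's best scaffold
    level (the scaffold axis is left to the sweep).  The first refined set
    whose 64-point scaffold sweep and affinity resweep each clear both
    thresholds at distinct grid points is returned with full provenance.
    """
    from scaffold_cycle.screen import SamplingSpec, run_screen

    spec = SamplingSpec(n_samples=n_samples, seed=seed, regime=regime)
    table, _ = run_screen(spec)
    ok = table[table["ok_staircase"] & table["ok_pulse"]].copy()
    ok["boundary_rank"] = np.minimum(ok["F"] / F_THRESHOLD,
                                     ok["w"] / W_THRESHOLD)
    ok = ok.sort_values("boundary_rank", ascending=False)
    log_lo, log_hi = np.log(1e-3), np.log(1e3)
    rng = np.random.default_rng(seed)
    for _, row in ok.head(n_candidates).iterrows():
        g = np.log(np.array([row[f"k{i}"] for i in range(1, 11)]))
        S_total, P_total = float(row["S_total"]), float(row["P_total"])
        q = _sweep_objective(np.exp(g), S_total, P_total, seed)
        for _ in range(refine_steps):
            g2 = g.copy()
            idx = rng.integers(0, 10, size=rng.integers(1, 4))
            g2[idx] = np.clip(g2[idx] + rng.normal(0.0, 0.6, size=len(idx)),
                              log_lo, log_hi)
            q2 = _sweep_objective(np.exp(g2), S_total, P_total, seed)
            if q2 >= q:
                g, q = g2, q2
            if q >= 1.05:
                break
        if q < 1.0:
            continue
        rates = RateConstants.from_array(np.exp(g))
        totals = ConcentrationTotals(S_total, 0.0, P_total, 1.0)
        sweep_spec = SweepSpec(rates=rates, totals=totals, seed=seed)
        t_verdict = detect_modulation(sweep_scaffold_concentration(sweep_spec))
        if not t_verdict:
            continue
        a_verdict = detect_modulation(sweep_affinities(sweep_spec))
        if not a_verdict:
            continue
        k_final = np.exp(g)
        return {
            "rates": {f"k{i}": float(k_final[i - 1]) for i in range(1, 11)},
            "totals": {"S_total": S_total, "P_total": P_total,
                       "T_total": 1.0},
            "provenance": {"screen_seed": int(seed),
                           "screen_regime": regime,
                           "screen_index": int(row["index"]),
                           "screen_F": float(row["F"]),
                           "screen_w": float(row["w"]),
                           "refined": True,
                           "refine_objective": float(q)},
            "sweep_seed": int(seed),
            "t_sweep_witness": {"adaptive_idx": t_verdict.adaptive_idx,
                                "ultra_idx": t_verdict.ultra_idx},
            "affinity_witness": {"adaptive_idx": a_verdict.adaptive_idx,
                                 "ultra_idx": a_verdict.ultra_idx},
        }
    raise RuntimeError("no boundary-regime witness found; enlarge the "
                       "screen or refinement budget")


def load_boundary_fixture() -> SweepSpec:
    """The pinned boundary-regime base set (repository witness).

    Located by pre-screening saturated-regime samples for the set
    maximising min(F/0.8, w/0.3) across a scaffold sweep; full provenance
    (screen seed and index) is stored alongside the parameters.
    """
    path = resources.files("scaffold_cycle").joinpath(
        "data/boundary_set.json")
    payload = json.loads(path.read_text())
    rates = RateConstants.from_array([payload["rates"][f"k{i}"]
                                      for i in range(1, 11)])
    totals = ConcentrationTotals(
        S_total=payload["totals"]["S_total"],
        K_total=0.0,
        P_total=payload["totals"]["P_total"],
        T_total=payload["totals"]["T_total"],
    )
    return SweepSpec(rates=rates, totals=totals,
                     seed=int(payload.get("sweep_seed", 0)))
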