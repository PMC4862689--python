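"""Origin-fixation evolutionary walk over the motif's kinetic parameters.

In the weak-mutation / large-population regime, evolution reduces to a
random walk of sequentially fixed single mutants: one resident genotype,
mutant proposals, and acceptance with the Kimura fixation probability
computed from the fitness difference.  The genotype here is the motif's
ten rate constants plus the scaffold level T_total (network topology is
fixed); fitness is either the ultrasensitivity score F or the adaptation
fitness w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scaffold_cycle.motif_model import ConcentrationTotals, RateConstants
from scaffold_cycle.screen import (
    BIMOLECULAR_IDX,
    CONCENTRATION_RANGE,
    FIRST_ORDER_RANGE,
    BIMOLECULAR_RANGE,
    REGIMES,
    evaluate_parameter_set,
)

#: genotype layout: log-space vector of (k1..k10, T_total)
GENOTYPE_SIZE = 11


@dataclass(frozen=True)
class EvolutionConfig:
    """Walk settings: population, mutation kernel, fitness, budget."""

    N: int = 1000                     # effective (haploid) population size
    sigma: float = 0.5                # log-normal multiplier sd (ln-space)
    mutation_prob: float = 0.25       # per-parameter mutation probability
    fitness: str = "ultrasensitivity"  # or "adaptation"
    steps: int = 500
    seed: int = 0
    regime: str = "saturated"
    relative_s: bool = True           # pop-gen convention: s = (f_m - f_r)/f_r
    hill_climb: bool = False          # N -> infinity surrogate: accept iff s > 0
    first_order_range: tuple = FIRST_ORDER_RANGE
    bimolecular_range: tuple = BIMOLECULAR_RANGE
    concentration_range: tuple = CONCENTRATION_RANGE

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.fitness not in ("ultrasensitivity", "adaptation"):
            raise ValueError("fitness must be 'ultrasensitivity' or "
                             "'adaptation'")
        if self.steps < 0:
            raise ValueError("step budget must be >= 0")

    def log_bounds(self) -> np.ndarray:
        """(11, 2) array of ln-space [lo, hi] per genotype coordinate."""
        b = np.empty((GENOTYPE_SIZE, 2))
        for j in range(10):
            lo, hi = (self.bimolecular_range if j in BIMOLECULAR_IDX
                      else self.first_order_range)
            b[j] = (math.log(lo), math.log(hi))
        b[10] = (math.log(self.concentration_range[0]),
                 math.log(self.concentration_range[1]))
        return b


def fixation_probability(f_resident: float, f_mutant: float, N: int,
                         relative: bool = False) -> float:
    """Kimura fixation probability of a new mutant in a haploid population.

    p = (1 - exp(-2 s)) / (1 - exp(-2 N s)) with selection differential
    s = f_mutant - f_resident (or (f_m - f_r)/f_r when ``relative``).
    The neutral limit s -> 0 gives p = 1/N.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (math.isfinite(f_resident) and math.isfinite(f_mutant)):
        raise ValueError("fitnesses must be finite")
    s = f_mutant - f_resident
    if relative:
        if f_resident == 0.0:
            # relative s undefined at zero resident fitness: fall back to raw
            pass
        else:
            s = s / abs(f_resident)
    if abs(s) < 1e-14:
        return 1.0 / N
    num = -math.expm1(-2.0 * s)          # 1 - e^{-2s}
    with np.errstate(over="ignore"):
        den = -np.expm1(-2.0 * N * s)    # 1 - e^{-2Ns}; may overflow to -inf
    if not np.isfinite(den):
        return 0.0 if s < 0 else float(num)
    p = num / float(den)
    return float(min(max(p, 0.0), 1.0))


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a value back into [lo, hi] (reflecting boundaries)."""
    width = hi - lo
    if width <= 0:
        return lo
    t = (v - lo) % (2.0 * width)
    if t < 0:
        t += 2.0 * width
    return lo + (t if t <= width else 2.0 * width - t)


def mutate_parameters(genotype: np.ndarray, config: EvolutionConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Propose a mutant: per-parameter log-normal kicks, reflected in bounds.

    ``genotype`` is the ln-space vector (ln k1..k10, ln T_total).  Each
    coordinate mutates independently with probability ``mutation_prob`` by
    a Normal(0, sigma) increment in ln-space (a log-normal multiplier on
    the natural scale); proposals outside the feasible ranges reflect back.
    """
    g = np.asarray(genotype, dtype=float).copy()
    bounds = config.log_bounds()
    mask = rng.random(GENOTYPE_SIZE) < config.mutation_prob
    kicks = rng.normal(0.0, config.sigma, size=GENOTYPE_SIZE)
    for j in range(GENOTYPE_SIZE):
        if mask[j]:
            g[j] = _reflect(g[j] + kicks[j], bounds[j, 0], bounds[j, 1])
    return g


def genotype_from(rates: RateConstants, T_total: float) -> np.ndarray:
    return np.log(np.concatenate([rates.as_array(), [T_total]]))


def genotype_to(genotype: np.ndarray, regime: str
                ) -> tuple[RateConstants, ConcentrationTotals]:
    vals = np.exp(np.asarray(genotype, dtype=float))
    s_tot, p_tot = REGIMES[regime]
    return (RateConstants.from_array(vals[:10]),
            ConcentrationTotals(S_total=s_tot, K_total=0.0,
                                P_total=p_tot, T_total=float(vals[10])))


def _score(genotype: np.ndarray, config: EvolutionConfig) -> float:
    rates, totals = genotype_to(genotype, config.regime)
    rec = evaluate_parameter_set(rates, totals)
    if config.fitness == "ultrasensitivity":
        return float(rec["F"]) if rec["ok_staircase"] else float("nan")
    return float(rec["w"]) if rec["ok_pulse"] else float("nan")


@dataclass
class WalkTrajectory:
    """Per-step record of an origin-fixation walk."""

    config: EvolutionConfig
    start_genotype: np.ndarray
    steps: pd.DataFrame       # step, resident_f, proposal_f, fixation_p, accepted, flagged
    resident_genotype: np.ndarray
    resident_fitness: float

    @property
    def n_accepted(self) -> int:
        return int(self.steps["accepted"].sum()) if len(self.steps) else 0


def evolve_walk(start: np.ndarray | tuple, config: EvolutionConfig
                ) -> WalkTrajectory:
    """Run the mutation/fixation walk from a starting genotype.

    ``start`` is either a ln-space genotype vector or a
    (RateConstants, T_total) pair.  Fully reproducible from (start,
    config): one RNG drives mutation, and a second (derived) RNG drives
    acceptance.  Proposals whose scoring fails are rejected and flagged.
    """
    if isinstance(start, (tuple, list)):
        genotype = genotype_from(start[0], float(start[1]))
    else:
        genotype = np.asarray(start, dtype=float).copy()
    rng = np.random.default_rng(config.seed)
    f_res = _score(genotype, config)
    if not math.isfinite(f_res):
        raise ValueError("starting genotype failed to score")
    rows = []
    for step in range(config.steps):
        proposal = mutate_parameters(genotype, config, rng)
        f_mut = _score(proposal, config)
        flagged = not math.isfinite(f_mut)
        if flagged:
            p = 0.0
            accepted = False
        elif config.hill_climb:
            p = 1.0 if f_mut > f_res else 0.0
            accepted = f_mut > f_res
        else:
            p = fixation_probability(f_res, f_mut, config.N,
                                     config.relative_s)
            accepted = rng.random() < p
        rows.append({
            "step": step, "resident_f": f_res,
            "proposal_f": f_mut, "fixation_p": p,
            "accepted": accepted, "flagged": flagged,
        })
        if accepted:
            genotype = proposal
            f_res = f_mut
    steps = pd.DataFrame(
        rows, columns=["step", "resident_f", "proposal_f", "fixation_p",
                       "accepted", "flagged"])
    return WalkTrajectory(
        config=config,
        start_genotype=(np.asarray(start, dtype=float)
                        if not isinstance(start, (tuple, list))
                        else genotype_from(start[0], float(start[1]))),
        steps=steps,
        resident_genotype=genotype,
        resident_fitness=f_res,
    )
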