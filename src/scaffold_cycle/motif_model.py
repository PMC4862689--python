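"""The 9-species mass-action motif: a covalent-modification cycle with an
enzyme-sequestering scaffold.

Species
-------
S, Sp        free unphosphorylated / phosphorylated substrate
K, P         free kinase / phosphatase
T            free scaffold
SK, SpP      catalytic (enzyme-substrate) complexes
KT, PT       sequestered (enzyme-scaffold) complexes

Reactions (10 rate constants)
-----------------------------
S + K  <-> SK   (k1 association, k2 dissociation);  SK  -> Sp + K (k3)
Sp + P <-> SpP  (k4, k5);                           SpP -> S  + P (k6)
K + T  <-> KT   (k7, k8)
P + T  <-> PT   (k9, k10)

Scaffold-bound enzymes are catalytically inert; the scaffold binds each
enzyme 1:1 and exclusively (no ternary complex).  Four moieties are
conserved: total substrate, kinase, phosphatase and scaffold.

Units: concentrations in uM, time in s, bimolecular constants in 1/(uM s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.integrate import solve_ivp

from scaffold_cycle import _kernel

SPECIES = ("S", "Sp", "K", "P", "T", "SK", "SpP", "KT", "PT")
N_SPECIES = 9
N_RATES = 10

# unidirectional reactions as (stoichiometry column, rate-law factory)
# column order matches RATE_NAMES; species order matches SPECIES
RATE_NAMES = tuple(f"k{i}" for i in range(1, 11))

_S, _Sp, _K, _P, _T, _SK, _SpP, _KT, _PT = range(9)

#: stoichiometry matrix (9 species x 10 reactions), reaction j carries k_{j+1}
STOICHIOMETRY = np.zeros((9, 10), dtype=float)
for _j, (_subs, _prods) in enumerate([
    ((_S, _K), (_SK,)),      # k1: S+K -> SK
    ((_SK,), (_S, _K)),      # k2: SK -> S+K
    ((_SK,), (_Sp, _K)),     # k3: SK -> Sp+K
    ((_Sp, _P), (_SpP,)),    # k4
    ((_SpP,), (_Sp, _P)),    # k5
    ((_SpP,), (_S, _P)),     # k6
    ((_K, _T), (_KT,)),      # k7
    ((_KT,), (_K, _T)),      # k8
    ((_P, _T), (_PT,)),      # k9
    ((_PT,), (_P, _T)),      # k10
]):
    for _i in _subs:
        STOICHIOMETRY[_i, _j] -= 1.0
    for _i in _prods:
        STOICHIOMETRY[_i, _j] += 1.0

#: conservation-law matrix (4 moieties x 9 species); L @ STOICHIOMETRY == 0
CONSERVATION = np.array([
    [1, 1, 0, 0, 0, 1, 1, 0, 0],   # substrate: S+Sp+SK+SpP
    [0, 0, 1, 0, 0, 1, 0, 1, 0],   # kinase: K+SK+KT
    [0, 0, 0, 1, 0, 0, 1, 0, 1],   # phosphatase: P+SpP+PT
    [0, 0, 0, 0, 1, 0, 0, 1, 1],   # scaffold: T+KT+PT
], dtype=float)


class InvalidParameterError(ValueError):
    """A rate constant or total violates its validity constraints."""


class IntegrationError(RuntimeError):
    """ODE integration failed; diagnostics carried in args."""


class ConvergenceError(RuntimeError):
    """Neither root-finding nor long integration reached a steady state."""


@dataclass(frozen=True)
class RateConstants:
    """The ten mass-action rate constants k1..k10 of the motif."""

    k1: float   # substrate-kinase association, 1/(uM s)
    k2: float   # SK dissociation, 1/s
    k3: float   # phosphorylation catalysis, 1/s
    k4: float   # phosphosubstrate-phosphatase association, 1/(uM s)
    k5: float   # SpP dissociation, 1/s
    k6: float   # dephosphorylation catalysis, 1/s
    k7: float   # kinase-scaffold association, 1/(uM s)
    k8: float   # KT dissociation, 1/s
    k9: float   # phosphatase-scaffold association, 1/(uM s)
    k10: float  # PT dissociation, 1/s

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not (v > 0.0) or not math.isfinite(v):
                raise InvalidParameterError(
                    f"rate constant {f.name} must be strictly positive and "
                    f"finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "RateConstants":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (10,):
            raise InvalidParameterError("expected 10 rate constants")
        return cls(*arr)


@dataclass(frozen=True)
class ConcentrationTotals:
    """Conserved moiety totals (uM).  K_total is the input/signal variable."""

    S_total: float
    K_total: float
    P_total: float
    T_total: float

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0.0 or not math.isfinite(v):
                raise InvalidParameterError(
                    f"total {f.name} must be finite and non-negative, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S_total, self.K_total, self.P_total, self.T_total],
            dtype=float,
        )

    def with_K_total(self, K_total: float) -> "ConcentrationTotals":
        return ConcentrationTotals(self.S_total, K_total,
                                   self.P_total, self.T_total)


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (uM) of the nine species at one time point."""

    S: float
    Sp: float
    K: float
    P: float
    T: float
    SK: float
    SpP: float
    KT: float
    PT: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "SpeciesState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise InvalidParameterError("expected 9 species concentrations")
        return cls(*arr)

    def reduced(self) -> np.ndarray:
        """Independent coordinates (Sp, SK, SpP, KT, PT)."""
        return np.array([self.Sp, self.SK, self.SpP, self.KT, self.PT])

    @classmethod
    def from_reduced(cls, x, totals: ConcentrationTotals) -> "SpeciesState":
        Sp, SK, SpP, KT, PT = np.asarray(x, dtype=float)
        return cls(
            S=totals.S_total - Sp - SK - SpP,
            Sp=Sp,
            K=totals.K_total - SK - KT,
            P=totals.P_total - SpP - PT,
            T=totals.T_total - KT - PT,
            SK=SK, SpP=SpP, KT=KT, PT=PT,
        )

    def conservation_residual(self, totals: ConcentrationTotals) -> np.ndarray:
        """Moiety-sum residuals (substrate, kinase, phosphatase, scaffold)."""
        return CONSERVATION @ self.as_array() - totals.as_array()


@dataclass(frozen=True)
class DerivedConstants:
    """Michaelis and dissociation constants implied by the rates (uM)."""

    KM_K: float  # (k2+k3)/k1, kinase Michaelis constant
    KM_P: float  # (k5+k6)/k4, phosphatase Michaelis constant
    KD_K: float  # k8/k7, kinase-scaffold dissociation constant
    KD_P: float  # k10/k9, phosphatase-scaffold dissociation constant


@dataclass(frozen=True)
class MotifModel:
    """The compiled motif: species, reactions, stoichiometry, rates."""

    rates: RateConstants
    species: tuple = SPECIES
    rate_names: tuple = RATE_NAMES
    stoichiometry: np.ndarray = field(default_factory=lambda: STOICHIOMETRY)
    conservation: np.ndarray = field(default_factory=lambda: CONSERVATION)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_rates(self) -> int:
        return len(self.rate_names)

    def rate_array(self) -> np.ndarray:
        return self.rates.as_array()


@dataclass
class Timecourse:
    """A simulated trajectory on an ordered time grid."""

    times: np.ndarray                 # (n,) strictly increasing, s
    states: np.ndarray                # (n, 9) species concentrations, uM
    totals: np.ndarray                # (n, 4) totals in force at each point
    diagnostics: dict = field(default_factory=dict)

    def species_trace(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def max_conservation_residual(self) -> float:
        """Max relative moiety residual over all stored points."""
        resid = self.states @ CONSERVATION.T - self.totals
        scale = np.maximum(self.totals, 1e-30)
        return float(np.max(np.abs(resid) / scale))

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        for j, n in enumerate(("S_total", "K_total", "P_total", "T_total")):
            df[n] = self.totals[:, j]
        return df


def build_model(rates: RateConstants) -> MotifModel:
    """Construct the motif model from validated rate constants."""
    if not isinstance(rates, RateConstants):
        rates = RateConstants.from_array(np.asarray(rates, dtype=float))
    return MotifModel(rates=rates)


def reaction_rates(model: MotifModel, y: np.ndarray) -> np.ndarray:
    """Mass-action flux of each of the ten unidirectional reactions."""
    k = model.rate_array()
    S, Sp, K, P, T, SK, SpP, KT, PT = y
    return np.array([
        k[0] * S * K, k[1] * SK, k[2] * SK,
        k[3] * Sp * P, k[4] * SpP, k[5] * SpP,
        k[6] * K * T, k[7] * KT,
        k[8] * P * T, k[9] * PT,
    ])


def rhs(model: MotifModel, state) -> np.ndarray:
    """Time derivatives of all nine species under mass-action kinetics.

    Pure function; the four conservation-law combinations of the output are
    exactly zero because each reaction column conserves every moiety.
    """
    if isinstance(state, SpeciesState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    return model.stoichiometry @ reaction_rates(model, y)


def jacobian(model: MotifModel, y: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the full 9-species rhs."""
    k = model.rate_array()
    S, Sp, K, P, T, SK, SpP, KT, PT = y
    dv = np.zeros((10, 9))
    dv[0, _S] = k[0] * K
    dv[0, _K] = k[0] * S
    dv[1, _SK] = k[1]
    dv[2, _SK] = k[2]
    dv[3, _Sp] = k[3] * P
    dv[3, _P] = k[3] * Sp
    dv[4, _SpP] = k[4]
    dv[5, _SpP] = k[5]
    dv[6, _K] = k[6] * T
    dv[6, _T] = k[6] * K
    dv[7, _KT] = k[7]
    dv[8, _P] = k[8] * T
    dv[8, _T] = k[8] * P
    dv[9, _PT] = k[9]
    return model.stoichiometry @ dv


def derived_constants(rates: RateConstants) -> DerivedConstants:
    """Michaelis constants of the two enzymes and scaffold affinities."""
    return DerivedConstants(
        KM_K=(rates.k2 + rates.k3) / rates.k1,
        KM_P=(rates.k5 + rates.k6) / rates.k4,
        KD_K=rates.k8 / rates.k7,
        KD_P=rates.k10 / rates.k9,
    )


def saturation_index(derived: DerivedConstants, S_total: float):
    """Substrate-normalised Michaelis constants (kinase, phosphatase).

    Values below 1 indicate the enzyme is saturated by substrate (the
    zero-order regime).  For multi-enzyme networks the convention is the
    geometric mean of the normalised constants; with a single kinase and a
    single phosphatase each index is just its own normalised K_M.
    """
    if not S_total > 0.0:
        raise InvalidParameterError("S_total must be positive")
    return derived.KM_K / S_total, derived.KM_P / S_total


def geometric_mean_saturation(km_values, S_total: float) -> float:
    """Geometric mean of substrate-normalised K_M values (multi-enzyme form)."""
    if not S_total > 0.0:
        raise InvalidParameterError("S_total must be positive")
    vals = np.asarray(km_values, dtype=float) / S_total
    if np.any(vals <= 0.0):
        raise InvalidParameterError("K_M values must be positive")
    return float(np.exp(np.mean(np.log(vals))))


class UndefinedFractionError(ZeroDivisionError):
    """Enzyme fractions are undefined when the enzyme total is zero."""


def sequestration_fractions(state: SpeciesState, totals: ConcentrationTotals):
    """Partition of each enzyme among substrate-bound / scaffold-bound / free.

    Returns {"kinase": (SK/K_tot, KT/K_tot, K/K_tot),
             "phosphatase": (SpP/P_tot, PT/P_tot, P/P_tot)}; each triple sums
    to 1 up to the conservation tolerance of the state.
    """
    if totals.K_total <= 0.0 or totals.P_total <= 0.0:
        raise UndefinedFractionError(
            "sequestration fractions undefined for zero enzyme total"
        )
    return {
        "kinase": (state.SK / totals.K_total,
                   state.KT / totals.K_total,
                   state.K / totals.K_total),
        "phosphatase": (state.SpP / totals.P_total,
                        state.PT / totals.P_total,
                        state.P / totals.P_total),
    }


def apply_kinase_change(state: SpeciesState, totals: ConcentrationTotals,
                        new_K_total: float, policy: str = "free-first"):
    """Instantaneous signal event changing the kinase level.

    Raising adds free kinase.  Lowering semantics by ``policy``:

    * "free-first" (default): empty the free pool first, any shortfall pro
      rata from SK and KT — the new total is exact and the free-kinase drop
      (hence the output transient) is maximal;
    * "proportional": remove pro rata from free K, SK and KT;
    * "free-only": remove from free K alone, flooring at zero (the new
      total may then sit above the requested level).

    Substrate and scaffold from dissolved complexes rejoin their free
    pools, so no other moiety changes and nothing goes negative.
    """
    x = state.reduced()
    tot = totals.as_array()
    if policy in ("free-first", "proportional"):
        code = 0 if policy == "free-first" else 1
        xn, tn = _kernel.apply_kinase_change(x, tot, float(new_K_total),
                                             code)
    elif policy == "free-only":
        removable = state.K
        deficit = totals.K_total - new_K_total
        if deficit > removable:
            new_K_total = totals.K_total - removable  # floor at zero free K
        xn, tn = x.copy(), tot.copy()
        tn[1] = new_K_total
    else:
        raise InvalidParameterError(f"unknown kinase-removal policy {policy!r}")
    new_totals = ConcentrationTotals(*tn)
    return SpeciesState.from_reduced(xn, new_totals), new_totals


def initial_state(totals: ConcentrationTotals) -> SpeciesState:
    """All-free initial condition: no complexes, no phosphosubstrate."""
    return SpeciesState(
        S=totals.S_total, Sp=0.0, K=totals.K_total, P=totals.P_total,
        T=totals.T_total, SK=0.0, SpP=0.0, KT=0.0, PT=0.0,
    )


def simulate_timecourse(model: MotifModel, totals: ConcentrationTotals,
                        initial: SpeciesState, horizon: float,
                        events=None, n_points: int = 200,
                        rtol: float = 1e-8, atol: float = 1e-12,
                        method: str = "LSODA",
                        removal_policy: str = "proportional") -> Timecourse:
    """Integrate the full 9-species system, honouring timed kinase events.

    ``events`` is a list of (time, new_K_total) pairs; each is applied
    instantaneously with the proportional-removal policy and integration
    resumes.  The trajectory is stored on a grid of ~``n_points`` per
    segment.  Conservation residuals are a genuine accuracy check here
    (nothing enforces them along the integration).
    """
    resid = initial.conservation_residual(totals)
    scale = np.maximum(totals.as_array(), 1e-30)
    if np.max(np.abs(resid) / scale) > 1e-8:
        raise InvalidParameterError(
            f"initial state violates conservation for totals: residual {resid}"
        )
    events = sorted(events or [], key=lambda e: e[0])
    for t_ev, _ in events:
        if not 0.0 <= t_ev <= horizon:
            raise InvalidParameterError("event time outside [0, horizon]")

    seg_bounds = [0.0] + [t for t, _ in events] + [horizon]
    times_out = []
    states_out = []
    totals_out = []
    diagnostics = {"segments": [], "method": method}

    y = initial.as_array()
    cur_totals = totals
    for si in range(len(seg_bounds) - 1):
        t0, t1 = seg_bounds[si], seg_bounds[si + 1]
        if si > 0:
            _, new_K = events[si - 1]
            st, cur_totals = apply_kinase_change(
                SpeciesState.from_array(y), cur_totals, new_K,
                policy=removal_policy,
            )
            y = st.as_array()
        if t1 > t0:
            t_eval = np.linspace(t0, t1, max(2, n_points))
            sol = solve_ivp(
                lambda t, yy: rhs(model, yy), (t0, t1), y,
                method=method, t_eval=t_eval,
                jac=lambda t, yy: jacobian(model, yy),
                rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"integration failed in segment {si}: {sol.message}",
                    {"segment": si, "t_span": (t0, t1), "message": sol.message},
                )
            diagnostics["segments"].append(
                {"t_span": (t0, t1), "nfev": sol.nfev, "njev": sol.njev}
            )
            y = sol.y[:, -1].copy()
            times_out.append(sol.t)
            states_out.append(sol.y.T)
            totals_out.append(
                np.tile(cur_totals.as_array(), (sol.t.size, 1))
            )
        else:
            times_out.append(np.array([t0]))
            states_out.append(y[None, :].copy())
            totals_out.append(cur_totals.as_array()[None, :])

    times = np.concatenate(times_out)
    keep = np.concatenate(([True], np.diff(times) > 0))
    tc = Timecourse(
        times=times[keep],
        states=np.concatenate(states_out)[keep],
        totals=np.concatenate(totals_out)[keep],
        diagnostics=diagnostics,
    )
    floor = -1e-9 * max(1.0, float(np.max(tc.totals)))
    if tc.states.min() < floor:
        diagnostics["negative_clip"] = float(tc.states.min())
    tc.states = np.clip(tc.states, 0.0, None)
    return tc


def steady_state(model: MotifModel, totals: ConcentrationTotals,
                 guess: SpeciesState | None = None,
                 horizon: float = _kernel.DEFAULT_HORIZON) -> SpeciesState:
    """Steady state of the motif at the given totals.

    Damped Newton on the 5 conservation-reduced coordinates, with long
    stiff integration as fallback (so the dynamically reached branch is
    selected when Newton wanders off the physical set).  Conservation holds
    exactly by construction.
    """
    x0 = guess.reduced() if guess is not None else np.zeros(5)
    x, ok = _kernel.steady5(model.rate_array(), totals.as_array(), x0,
                            horizon)
    if not ok:
        raise ConvergenceError(
            "steady state not found by Newton or long integration",
            {"totals": totals, "best_x": x},
        )
    return SpeciesState.from_reduced(x, totals)


def goldbeter_koshland_fraction(v_K: float, v_P: float,
                                KM_K: float, KM_P: float,
                                S_total: float) -> float:
    """Closed-form steady-state phosphofraction of the scaffold-free cycle
    in the low-enzyme (Michaelis-Menten validity) limit.

    Solves v_K*(1-f)/(km1 + 1 - f) = v_P*f/(km2 + f) for f = Sp/S_total,
    with km1 = KM_K/S_total, km2 = KM_P/S_total; the textbook quadratic
    whose root in [0,1] gives the zero-order ultrasensitivity curve.
    """
    u = v_K / v_P
    km1 = KM_K / S_total
    km2 = KM_P / S_total
    # steady state: u*(1-f)/(km1+1-f) = f/(km2+f)  ->  a f^2 + b f + c = 0
    a = 1.0 - u
    b = u - u * km2 - km1 - 1.0
    c = u * km2
    if abs(a) < 1e-12 * (1.0 + abs(b)):
        f = -c / b
    else:
        disc = math.sqrt(max(b * b - 4.0 * a * c, 0.0))
        f = (-b + disc) / (2.0 * a)
        if not 0.0 <= f <= 1.0:
            f = (-b - disc) / (2.0 * a)
    return min(max(f, 0.0), 1.0)
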