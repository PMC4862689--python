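"""Response-dynamics scoring: ultrasensitivity and adaptation.

Two signal protocols drive the motif through changes in total kinase
(the input), reading out phosphorylated substrate Sp (the output):

* a **staircase** of three ramp-up and three ramp-down input steps, whose
  plateau-to-plateau output differences yield the ultrasensitivity score
  F = S_amp * S_ult in [0, 1] — high when the dose-response is switch-like
  with its threshold at the middle step;
* a train of **square pulses** of increasing magnitude, whose transient
  peaks and residual steady-state offsets yield the adaptation fitness
  w in [0, 1] — high when every pulse produces a large transient that
  relaxes back to the pre-stimulus output (sensitive yet precise).

The arithmetic of both scores is kept in pure functions of recorded
plateau/pulse values, so it can be exercised on closed-form (e.g. Hill)
response stubs independently of the ODE layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from scaffold_cycle import _kernel
from scaffold_cycle.motif_model import (
    ConcentrationTotals,
    MotifModel,
    SpeciesState,
)

#: Table-range-derived defaults: the staircase spans the sampled
#: concentration range [1e-4, 10] uM in factor-10 plateaus centred so the
#: middle level sits at the range's geometric mean.
DEFAULT_STAIRCASE_LEVELS = (10.0 ** -2.5, 10.0 ** -1.5, 10.0 ** -0.5)
DEFAULT_STAIRCASE_BASELINE = 10.0 ** -3.5
#: pulse magnitudes are the normalised input changes (I1-I0)/I0 of the
#: sensitivity/precision definitions; the baseline sits at the geometric
#: mean of the feasible concentration range (like the staircase's middle
#: level), so the largest pulse stays within scaffold-absorbable levels
DEFAULT_PULSE_MAGNITUDES = (1.0, 10.0, 100.0)
DEFAULT_PULSE_BASELINE = 10.0 ** -1.5
DEFAULT_RU = 1.0
S_CAP = 1e6          # saturation cap for s_u ratios on floored denominators
A_PREC_CAP = 1e6     # reported precision for perfect adaptation
DENOM_FLOOR_FACTOR = 1e-12


class ScoringError(RuntimeError):
    """A protocol plateau or transient failed to converge."""


@dataclass(frozen=True)
class StaircaseProtocol:
    """Three-up/three-down staircase of total-kinase levels (uM)."""

    baseline: float = DEFAULT_STAIRCASE_BASELINE
    levels: tuple = DEFAULT_STAIRCASE_LEVELS

    def __post_init__(self):
        lv = tuple(float(v) for v in self.levels)
        if len(lv) != 3 or not (0.0 < lv[0] < lv[1] < lv[2]):
            raise ValueError("need exactly 3 strictly increasing levels")
        if not 0.0 <= self.baseline < lv[0]:
            raise ValueError("baseline must lie below the first level")

    def visiting_order(self) -> np.ndarray:
        """K_total sequence: baseline, L1, L2, L3, L2, L1, baseline."""
        b = self.baseline
        l1, l2, l3 = self.levels
        return np.array([b, l1, l2, l3, l2, l1, b], dtype=float)


@dataclass(frozen=True)
class PulseProtocol:
    """Square pulses of total kinase around a fixed baseline level.

    ``magnitudes`` are relative input changes (I1-I0)/I0 by default, i.e.
    the pulse raises K_total from baseline b to b*(1+m) — the same
    normalised step that enters the sensitivity/precision definitions.
    Set ``relative=False`` to treat them as absolute additions in uM.
    ``removal`` selects the down-step semantics: "free-first" empties the
    free kinase pool before touching complexes (producing the canonical
    post-pulse undershoot of an adapting system), "proportional" removes
    pro rata from free, substrate-bound and scaffold-bound kinase.
    """

    baseline: float = DEFAULT_PULSE_BASELINE
    magnitudes: tuple = DEFAULT_PULSE_MAGNITUDES
    relative: bool = True
    removal: str = "free-first"

    def __post_init__(self):
        if not all(m > 0 for m in self.magnitudes):
            raise ValueError("pulse magnitudes must be strictly positive")
        if not self.baseline > 0:
            raise ValueError("pulse baseline must be strictly positive")
        if self.removal not in ("free-first", "proportional"):
            raise ValueError("removal must be 'free-first' or 'proportional'")

    def absolute_increments(self):
        """Kinase increments in uM for each configured magnitude."""
        if self.relative:
            return tuple(self.baseline * m for m in self.magnitudes)
        return tuple(self.magnitudes)

    @property
    def removal_code(self) -> int:
        return 0 if self.removal == "free-first" else 1


@dataclass(frozen=True)
class UltrasensitivityResult:
    dy_up: tuple      # (dy1+, dy2+, dy3+), uM
    dy_down: tuple    # (dy1-, dy2-, dy3-), uM
    S_amp: float
    S_ult: float
    s_u1: float
    s_u3: float
    r_u: float
    y_total: float
    F: float


@dataclass(frozen=True)
class PulseRecord:
    """Measured response of one square pulse."""

    magnitude: float
    dO_max_up: float   # peak |Sp - pre-up steady| during the up phase, uM
    dO_ss_up: float    # |post-up steady - pre-up steady|, uM
    dO_max_down: float
    dO_ss_down: float
    O_0: float         # pre-pulse steady-state output, uM
    O_1: float = 0.0   # on-pulse (post-up-step) steady-state output, uM


@dataclass(frozen=True)
class AdaptationResult:
    records: tuple      # PulseRecord per magnitude
    w_i: tuple          # per-pulse adaptive-response level
    C: float
    K_thresh: float
    w: float            # geometric mean of w_i
    A_sens: tuple       # per-pulse sensitivity (up-step), Eq-4 style
    A_prec: tuple       # per-pulse precision (up-step), capped


@dataclass
class StaircasePlateaus:
    """Steady-state outputs along the staircase visiting order."""

    levels: np.ndarray           # K_total at each plateau (7 entries)
    outputs: np.ndarray          # steady-state Sp at each plateau, uM
    mean_fractions: np.ndarray   # staircase-averaged enzyme partitioning
    converged: bool = True


# ---------------------------------------------------------------------------
# protocol drivers (kernel-backed)
# ---------------------------------------------------------------------------

def run_staircase(model: MotifModel, totals: ConcentrationTotals,
                  protocol: StaircaseProtocol | None = None,
                  horizon: float = _kernel.DEFAULT_HORIZON,
                  raise_on_failure: bool = True) -> StaircasePlateaus:
    """Drive the staircase protocol and record plateau steady states.

    ``totals.K_total`` is ignored: the protocol owns the input variable.
    """
    protocol = protocol or StaircaseProtocol()
    order = protocol.visiting_order()
    plateaus, fracs, ok = _kernel.staircase_eval(
        model.rate_array(), totals.S_total, totals.P_total, totals.T_total,
        order, horizon,
    )
    if not ok and raise_on_failure:
        raise ScoringError("a staircase plateau failed to converge",
                           {"levels": order, "partial": plateaus})
    return StaircasePlateaus(levels=order, outputs=plateaus,
                             mean_fractions=fracs, converged=bool(ok))


def run_pulse_train(model: MotifModel, totals: ConcentrationTotals,
                    protocol: PulseProtocol | None = None,
                    horizon: float = _kernel.DEFAULT_HORIZON,
                    raise_on_failure: bool = True) -> list[PulseRecord]:
    """Drive the square-pulse protocol and record peak/steady responses."""
    protocol = protocol or PulseProtocol()
    adds = np.asarray(protocol.absolute_increments(), dtype=float)
    rec, ok = _kernel.pulse_eval(
        model.rate_array(), totals.S_total, totals.P_total, totals.T_total,
        protocol.baseline, adds, horizon, protocol.removal_code,
    )
    if not ok and raise_on_failure:
        raise ScoringError("a pulse phase failed to converge",
                           {"increments": adds, "partial": rec})
    return [
        PulseRecord(magnitude=float(m), dO_max_up=float(r[0]),
                    dO_ss_up=float(r[1]), dO_max_down=float(r[2]),
                    dO_ss_down=float(r[3]), O_0=float(r[4]),
                    O_1=float(r[5]))
        for m, r in zip(protocol.magnitudes, rec)
    ]


# ---------------------------------------------------------------------------
# score arithmetic (pure, stub-testable)
# ---------------------------------------------------------------------------

def staircase_deltas(outputs) -> tuple[tuple, tuple]:
    """Per-step output magnitudes along the visiting order.

    ``outputs`` are the 7 plateau outputs [base, L1, L2, L3, L2, L1, base].
    Step i covers the interval between levels i-1 and i; the down-ramp step
    magnitudes are indexed by the same interval.
    """
    o = np.asarray(outputs, dtype=float)
    if o.shape != (7,):
        raise ValueError("expected 7 plateau outputs")
    dy_up = (abs(o[1] - o[0]), abs(o[2] - o[1]), abs(o[3] - o[2]))
    dy_down = (abs(o[6] - o[5]), abs(o[5] - o[4]), abs(o[4] - o[3]))
    return dy_up, dy_down


def ultrasensitivity_score(plateaus, y_total: float,
                           r_u: float = DEFAULT_RU) -> UltrasensitivityResult:
    """Score a set of staircase plateaus for switch-like response.

    ``plateaus`` is either a StaircasePlateaus or the 7 plateau outputs.
    S_amp rewards a large swing at the middle step; S_ult rewards that
    swing dwarfing the flanking steps; F = S_amp * S_ult.
    """
    if isinstance(plateaus, StaircasePlateaus):
        outputs = plateaus.outputs
    else:
        outputs = plateaus
    if not y_total > 0:
        raise ValueError("y_total must be positive")
    dy_up, dy_down = staircase_deltas(outputs)
    num = dy_up[1] + dy_down[1]
    S_amp = num / (2.0 * y_total)
    floor = DENOM_FLOOR_FACTOR * y_total
    den1 = dy_up[0] + dy_down[0]
    den3 = dy_up[2] + dy_down[2]
    if den1 < floor:
        s_u1 = S_CAP if num > floor else 0.0
    else:
        s_u1 = min(num / den1, S_CAP)
    if den3 < floor:
        s_u3 = S_CAP if num > floor else 0.0
    else:
        s_u3 = min(num / den3, S_CAP)
    S_ult = (s_u1 / (r_u + s_u1)) * (s_u3 / (r_u + s_u3))
    F = S_amp * S_ult
    return UltrasensitivityResult(
        dy_up=dy_up, dy_down=dy_down, S_amp=float(S_amp), S_ult=float(S_ult),
        s_u1=float(s_u1), s_u3=float(s_u3), r_u=float(r_u),
        y_total=float(y_total), F=float(F),
    )


def adaptation_sensitivity(O_0: float, O_star: float,
                           I_0: float, I_1: float) -> float:
    """Normalised peak deflection per normalised input change.

    A_sens = |((O*-O_0)/O_0) / ((I_1-I_0)/I_0)|.
    """
    if O_0 <= 0.0 or I_0 <= 0.0:
        raise ZeroDivisionError("A_sens undefined for O_0 <= 0 or I_0 <= 0")
    if I_1 == I_0:
        raise ZeroDivisionError("A_sens undefined for I_1 == I_0")
    return abs(((O_star - O_0) / O_0) / ((I_1 - I_0) / I_0))


def adaptation_precision(O_0: float, O_1: float, I_0: float, I_1: float,
                         cap: float = A_PREC_CAP) -> float:
    """Reciprocal normalised residual offset after adaptation.

    A_prec = |((O_1-O_0)/O_0) / ((I_1-I_0)/I_0)|^-1; an exact return to the
    pre-stimulus output (perfect adaptation) is reported as the cap.
    """
    if O_0 <= 0.0 or I_0 <= 0.0:
        raise ZeroDivisionError("A_prec undefined for O_0 <= 0 or I_0 <= 0")
    if I_1 == I_0:
        raise ZeroDivisionError("A_prec undefined for I_1 == I_0")
    denom = abs(((O_1 - O_0) / O_0) / ((I_1 - I_0) / I_0))
    if denom < 1.0 / cap:
        return cap
    return 1.0 / denom


def pulse_level(rec: PulseRecord, C: float | None, K_thresh: float,
                y_total: float = 1.0) -> float:
    """Per-pulse adaptive-response level w_i, in [0, 1].

    Each direction contributes its normalised peak response times a
    saturating precision penalty K/(K + offset); the two directions
    multiply, so w_i = 1 requires a full-range, exactly-returning response
    both on pulse onset and on pulse release.

    Normalisation (the "scale to [0, 1]" convention): with ``C`` None
    (default) each direction's deflection and residual offset are divided
    by the output room available to that direction — ``y_total - O_0`` for
    the onset, ``O_1`` (the on-pulse operating level) for the release —
    and ``K_thresh`` is dimensionless on that scale.  With an explicit
    constant ``C`` both directions use it verbatim (then K_thresh is in
    concentration units).  Isolated here so the reading of the fitness
    formula can be revised in one place.
    """
    if C is None:
        eps = 1e-12 * max(y_total, 1e-30)
        room_up = max(y_total - rec.O_0, eps)
        room_dn = max(rec.O_1, eps)
        p_up = min(rec.dO_max_up / room_up, 1.0)
        p_dn = min(rec.dO_max_down / room_dn, 1.0)
        e_up = rec.dO_ss_up / room_up
        e_dn = rec.dO_ss_down / room_dn
    else:
        p_up = min(rec.dO_max_up * C, 1.0)
        p_dn = min(rec.dO_max_down * C, 1.0)
        e_up = rec.dO_ss_up
        e_dn = rec.dO_ss_down
    up = p_up * (K_thresh / (K_thresh + e_up))
    dn = p_dn * (K_thresh / (K_thresh + e_dn))
    return up * dn


def adaptation_fitness(records, C: float | None = None,
                       K_thresh: float = 0.1,
                       baseline: float = DEFAULT_PULSE_BASELINE,
                       relative: bool = True,
                       y_total: float = 1.0) -> AdaptationResult:
    """Adaptation fitness w: geometric mean of per-pulse levels w_i.

    ``records`` is a sequence of PulseRecord (one per magnitude); peaks
    and offsets are normalised per ``pulse_level`` (direction-wise room
    normalisation by default, a constant C if given) and K_thresh forces a
    minimal tolerated residual offset.  ``baseline`` is the pre-pulse
    input level used for the per-pulse A_sens/A_prec diagnostics;
    ``y_total`` the maximum possible output (fully phosphorylated
    substrate).
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one pulse record")
    w_i = tuple(pulse_level(r, C, K_thresh, y_total) for r in records)
    prod = 1.0
    for v in w_i:
        prod *= v
    w = prod ** (1.0 / len(w_i)) if prod > 0.0 else 0.0
    A_sens = []
    A_prec = []
    for r in records:
        # up-step diagnostics; defined only for a nonzero pre-pulse output
        if r.O_0 > 0.0:
            O_star = r.O_0 + r.dO_max_up
            O_1 = r.O_0 + r.dO_ss_up
            I_0 = baseline
            I_1 = baseline * (1.0 + r.magnitude) if relative \
                else baseline + r.magnitude
            A_sens.append(adaptation_sensitivity(r.O_0, O_star, I_0, I_1))
            A_prec.append(adaptation_precision(r.O_0, O_1, I_0, I_1))
        else:
            A_sens.append(float("nan"))
            A_prec.append(float("nan"))
    return AdaptationResult(
        records=tuple(records), w_i=w_i,
        C=None if C is None else float(C),
        K_thresh=float(K_thresh), w=float(w),
        A_sens=tuple(A_sens), A_prec=tuple(A_prec),
    )


def score_ultrasensitivity(model: MotifModel, totals: ConcentrationTotals,
                           protocol: StaircaseProtocol | None = None,
                           r_u: float = DEFAULT_RU,
                           y_total: float | None = None,
                           horizon: float = _kernel.DEFAULT_HORIZON,
                           ) -> tuple[UltrasensitivityResult, StaircasePlateaus]:
    """Run the staircase and score it; y_total defaults to S_total."""
    plat = run_staircase(model, totals, protocol, horizon)
    yt = totals.S_total if y_total is None else y_total
    return ultrasensitivity_score(plat, yt, r_u), plat


def score_adaptation(model: MotifModel, totals: ConcentrationTotals,
                     protocol: PulseProtocol | None = None,
                     C: float | None = None, K_thresh: float | None = None,
                     horizon: float = _kernel.DEFAULT_HORIZON,
                     ) -> AdaptationResult:
    """Run the pulse train and compute the adaptation fitness.

    Defaults: direction-wise room normalisation of peaks/offsets (C None)
    with dimensionless K_thresh = 0.1 — residual offsets an order of
    magnitude below the available output range are tolerated, larger ones
    penalised.
    """
    protocol = protocol or PulseProtocol()
    recs = run_pulse_train(model, totals, protocol, horizon)
    K_thresh = 0.1 if K_thresh is None else K_thresh
    return adaptation_fitness(recs, C, K_thresh, baseline=protocol.baseline,
                              relative=protocol.relative,
                              y_total=totals.S_total)
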