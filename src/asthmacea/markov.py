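"""Deterministic Markov cohort engine.

Six ordered states: CONTROLLED, EXAC_OCS, EXAC_ED, EXAC_HOSP (single-cycle
tunnel states for the three exacerbation severities), DEATH_ASTHMA and
DEATH_OTHER (absorbing). Each 2-week cycle a controlled patient may start an
OCS-burst exacerbation (probability reduced by the treatment RR while on
triple therapy); an exacerbation may escalate one level, end in asthma death,
or resolve back to the controlled state. Background mortality from the life
table acts first within a cycle; disease transitions share the remaining
(1 − q) mass, so every row is a probability vector by construction.

The cohort starts 100% controlled at ``start_age`` and is run to ``max_age``
(or until the alive mass is numerically extinct). At cycle 26 (52 weeks) the
arm splits into a persistent sub-cohort, which keeps the treatment effect and
drug cost, and a discontinued sub-cohort (RR = 1, reference-arm drug cost).
Costs are drug acquisition per cycle alive plus per-episode event costs
charged on entry to an exacerbation state; QALYs weight state occupancy by the
state utilities. Both streams are discounted at the annual rate and, by
default, half-cycle corrected with trapezoid weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .lifetable import LifeTable, make_life_table
from .parameters import (
    ParameterBundle,
    StrategyParams,
    strategy_drug_cost_per_cycle,
)

__all__ = [
    "State",
    "STATE_NAMES",
    "ModelConstructionError",
    "per_cycle_background_mortality",
    "build_transition_matrix",
    "CohortTrace",
    "StrategyResult",
    "IncrementalResult",
    "run_cohort",
    "incremental",
]

_ALIVE_TOL = 1e-9


class State(IntEnum):
    CONTROLLED = 0
    EXAC_OCS = 1
    EXAC_ED = 2
    EXAC_HOSP = 3
    DEATH_ASTHMA = 4
    DEATH_OTHER = 5


STATE_NAMES = [s.name for s in State]
_EXAC = [State.EXAC_OCS, State.EXAC_ED, State.EXAC_HOSP]
_DEAD = [State.DEATH_ASTHMA, State.DEATH_OTHER]


class ModelConstructionError(ValueError):
    """A composed transition probability left [0, 1]; names the offending row."""


def per_cycle_background_mortality(
    life_table: LifeTable, age: float, cycles_per_year: int
) -> float:
    """Convert the annual death probability at ``age`` to a per-cycle one.

    Uses the constant-hazard-within-year identity
    ``q_cycle = 1 − (1 − q_annual)^(1/cycles_per_year)``.
    """
    q = life_table.annual_probability(age)
    if q >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q) ** (1.0 / cycles_per_year)


def build_transition_matrix(
    bundle: ParameterBundle,
    strategy: StrategyParams,
    age: float,
    on_treatment: bool,
    life_table: LifeTable | None = None,
) -> np.ndarray:
    """The 6x6 per-cycle transition matrix for one age/strategy/adherence cell.

    Background mortality is applied first; disease transitions are scaled by
    the surviving (1 − q) mass. The treatment RR multiplies the
    controlled-to-OCS probability only while ``on_treatment``.
    """
    if life_table is None:
        life_table = make_life_table()
    q = per_cycle_background_mortality(life_table, age, bundle.settings.cycles_per_year)
    return _compose_matrix(bundle, strategy, q, on_treatment)


def _compose_matrix(
    bundle: ParameterBundle, strategy: StrategyParams, q: float, on_treatment: bool
) -> np.ndarray:
    t = bundle.transitions
    rr = strategy.rr_exacerbation.base if on_treatment else 1.0
    p_exac = t.p_controlled_to_ocs.base * rr
    p_death = t.p_asthma_death.base

    m = np.zeros((6, 6))
    alive = 1.0 - q
    # CONTROLLED
    m[State.CONTROLLED, State.EXAC_OCS] = p_exac * alive
    m[State.CONTROLLED, State.DEATH_OTHER] = q
    m[State.CONTROLLED, State.CONTROLLED] = (1.0 - p_exac) * alive
    # tunnel states: escalate, die, or resolve to CONTROLLED
    for state, p_up, target in (
        (State.EXAC_OCS, t.p_ocs_to_ed.base, State.EXAC_ED),
        (State.EXAC_ED, t.p_ed_to_hosp.base, State.EXAC_HOSP),
        (State.EXAC_HOSP, 0.0, None),
    ):
        if target is not None:
            m[state, target] = p_up * alive
        m[state, State.DEATH_ASTHMA] = p_death * alive
        m[state, State.DEATH_OTHER] = q
        m[state, State.CONTROLLED] = (1.0 - p_up - p_death) * alive
    for state in _DEAD:
        m[state, state] = 1.0

    if np.any(m < -1e-15) or np.any(m > 1.0 + 1e-15):
        bad = STATE_NAMES[int(np.where((m < 0) | (m > 1))[0][0])]
        raise ModelConstructionError(f"composed probability outside [0, 1] in row {bad}")
    rowsum = m.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-12):
        bad = STATE_NAMES[int(np.argmax(np.abs(rowsum - 1.0)))]
        raise ModelConstructionError(f"row {bad} does not sum to 1")
    return m


def _matrices_by_age(
    bundle: ParameterBundle, strategy: StrategyParams, life_table: LifeTable, on_treatment: bool
) -> np.ndarray:
    """Stack of transition matrices for integer ages start_age..max_age-1."""
    s = bundle.settings
    ages = np.arange(s.start_age, s.max_age)
    qs = 1.0 - (1.0 - life_table.annual_probabilities(ages)) ** (1.0 / s.cycles_per_year)
    return np.stack([_compose_matrix(bundle, strategy, q, on_treatment) for q in qs])


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the closed cohort (rows 0..N)."""

    occupancy: np.ndarray  # (N+1, 6)
    start_age: float
    cycles_per_year: int

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) / self.cycles_per_year

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, : State.DEATH_ASTHMA].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_NAMES)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "year", self.years)
        df.insert(2, "age", self.start_age + self.years)
        return df


@dataclass
class StrategyResult:
    """Lifetime outcomes of one arm (USD and QALYs, discounted and not)."""

    strategy: str
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cycle_cost_discounted: np.ndarray
    cycle_qaly_discounted: np.ndarray
    cycle_cost_undiscounted: np.ndarray
    cycle_qaly_undiscounted: np.ndarray
    trace: CohortTrace
    exacerbation_free_1yr: float
    life_years_discounted: float
    life_years_undiscounted: float

    @property
    def cost_effectiveness_ratio(self) -> float:
        """Average cost per QALY of the arm on its own (the C/E column)."""
        return self.discounted_cost / self.discounted_qaly

    @property
    def cost_per_year_alive(self) -> float:
        return self.discounted_cost / self.life_years_discounted

    @property
    def qaly_per_year_alive(self) -> float:
        return self.discounted_qaly / self.life_years_discounted

    def cycle_frame(self) -> pd.DataFrame:
        df = self.trace.to_frame()
        df["cost_discounted"] = self.cycle_cost_discounted
        df["qaly_discounted"] = self.cycle_qaly_discounted
        df["cost_undiscounted"] = self.cycle_cost_undiscounted
        df["qaly_undiscounted"] = self.cycle_qaly_undiscounted
        return df


@dataclass
class IncrementalResult:
    """Incremental comparison of intervention vs reference."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    icer_defined: bool
    classification: str  # dominant / dominated / tradeoff_NE / tradeoff_SW / indifferent
    ce_intervention: float
    ce_reference: float


# ---------------------------------------------------------------------------
# cohort run
# ---------------------------------------------------------------------------


def _propagate(x0: np.ndarray, m_on: np.ndarray, m_off: np.ndarray, switch_cycle: int,
               n_cycles: int, cycles_per_year: int) -> np.ndarray:
    """Trace rows 0..n for one sub-cohort switching from on- to off-treatment
    matrices at ``switch_cycle`` (use n_cycles+1 for never)."""
    trace = np.empty((n_cycles + 1, 6))
    x = x0
    for t in range(n_cycles):
        trace[t] = x
        stack = m_on if t < switch_cycle else m_off
        x = x @ stack[t // cycles_per_year]
    trace[n_cycles] = x
    return trace


def run_cohort(
    bundle: ParameterBundle,
    strategy: str | StrategyParams,
    life_table: LifeTable | None = None,
) -> StrategyResult:
    """Run the deterministic cohort model for one arm over the lifetime horizon.

    Returns discounted and undiscounted totals plus the per-cycle detail and
    the aggregated trace. See the module docstring for the accounting
    conventions (half-cycle correction, entry-charged event costs, the 52-week
    persistence split).
    """
    if isinstance(strategy, str):
        strategy = bundle.strategies[strategy]
    if life_table is None:
        life_table = make_life_table()
    s = bundle.settings
    cpy = s.cycles_per_year
    n_cycles = (s.max_age - s.start_age) * cpy
    split_cycle = cpy  # 52 weeks

    m_on = _matrices_by_age(bundle, strategy, life_table, on_treatment=True)
    m_off = _matrices_by_age(bundle, strategy, life_table, on_treatment=False)

    persistence = strategy.persistence_52wk.base
    x0 = np.zeros(6)
    x0[State.CONTROLLED] = 1.0
    # two sub-cohorts from t=0: identical until the 52-week split, then the
    # discontinued one switches to RR=1 and the reference arm's drug cost
    trace_pers = _propagate(persistence * x0, m_on, m_off, n_cycles + 1, n_cycles, cpy)
    trace_disc = _propagate((1.0 - persistence) * x0, m_on, m_off, split_cycle, n_cycles, cpy)
    occupancy = trace_pers + trace_disc

    # truncate once the cohort is numerically extinct
    alive = occupancy[:, : State.DEATH_ASTHMA].sum(axis=1)
    dead_rows = np.nonzero(alive < _ALIVE_TOL)[0]
    if dead_rows.size:
        n_cycles = int(dead_rows[0])
        occupancy = occupancy[: n_cycles + 1]
        trace_pers = trace_pers[: n_cycles + 1]
        trace_disc = trace_disc[: n_cycles + 1]

    n_rows = n_cycles + 1
    if s.half_cycle_correction:
        weights = np.ones(n_rows)
        weights[0] = weights[-1] = 0.5
    else:  # beginning-of-cycle accrual
        weights = np.ones(n_rows)
        weights[-1] = 0.0
    tt = np.arange(n_rows)
    discount = (1.0 + s.annual_discount.base) ** (-tt / cpy)

    u = np.asarray(bundle.utilities.state_utilities())
    event_cost = np.zeros(6)
    event_cost[State.EXAC_OCS] = bundle.costs.c_ocs_burst.base
    event_cost[State.EXAC_ED] = bundle.costs.c_ed_visit.base
    event_cost[State.EXAC_HOSP] = bundle.costs.c_hosp_episode

    drug_on = strategy_drug_cost_per_cycle(strategy, bundle.costs, s)
    drug_off = strategy_drug_cost_per_cycle(bundle.strategies[bundle.reference], bundle.costs, s)
    drug_disc_by_row = np.where(tt < split_cycle, drug_on, drug_off)

    alive_pers = trace_pers[:, : State.DEATH_ASTHMA].sum(axis=1)
    alive_disc = trace_disc[:, : State.DEATH_ASTHMA].sum(axis=1)
    cycle_cost = (
        occupancy @ event_cost + alive_pers * drug_on + alive_disc * drug_disc_by_row
    )
    cycle_qaly = (occupancy @ u) * s.cycle_length_years
    cycle_ly = occupancy[:, : State.DEATH_ASTHMA].sum(axis=1) * s.cycle_length_years

    cost_disc = weights * discount * cycle_cost
    qaly_disc = weights * discount * cycle_qaly
    cost_undisc = weights * cycle_cost
    qaly_undisc = weights * cycle_qaly

    if not (np.isfinite(cost_disc).all() and np.isfinite(qaly_disc).all()):
        bad = int(np.nonzero(~(np.isfinite(cost_disc) & np.isfinite(qaly_disc)))[0][0])
        raise FloatingPointError(f"non-finite accumulation at cycle {bad}")

    trace = CohortTrace(occupancy, float(s.start_age), cpy)
    rowsum_err = np.abs(occupancy.sum(axis=1) - 1.0).max()
    if rowsum_err > 1e-10:
        raise ModelConstructionError(f"cohort trace row sum error {rowsum_err:.2e}")

    return StrategyResult(
        strategy=strategy.name,
        discounted_cost=float(cost_disc.sum()),
        discounted_qaly=float(qaly_disc.sum()),
        undiscounted_cost=float(cost_undisc.sum()),
        undiscounted_qaly=float(qaly_undisc.sum()),
        cycle_cost_discounted=cost_disc,
        cycle_qaly_discounted=qaly_disc,
        cycle_cost_undiscounted=cost_undisc,
        cycle_qaly_undiscounted=qaly_undisc,
        trace=trace,
        exacerbation_free_1yr=_exacerbation_free_1yr(bundle, strategy, life_table),
        life_years_discounted=float((weights * discount * cycle_ly).sum()),
        life_years_undiscounted=float((weights * cycle_ly).sum()),
    )


def _exacerbation_free_1yr(
    bundle: ParameterBundle, strategy: StrategyParams, life_table: LifeTable
) -> float:
    """Probability of no exacerbation entry during the first model year.

    Computed by making the exacerbation states absorbing, so their mass after
    26 cycles is exactly the probability of having ever exacerbated.
    """
    s = bundle.settings
    q = per_cycle_background_mortality(life_table, s.start_age, s.cycles_per_year)
    m = _compose_matrix(bundle, strategy, q, on_treatment=True).copy()
    for state in _EXAC:
        m[state] = 0.0
        m[state, state] = 1.0
    x = np.zeros(6)
    x[State.CONTROLLED] = 1.0
    for _ in range(s.cycles_per_year):
        x = x @ m
    return float(1.0 - x[list(_EXAC)].sum())


def incremental(
    result_intervention: StrategyResult,
    result_reference: StrategyResult,
    settings=None,
) -> IncrementalResult:
    """Incremental cost, QALYs and ICER of intervention vs reference.

    The ICER is reported only on the north-east quadrant (more costly, more
    effective); dominance and the south-west trade-off are flagged instead of
    dividing. A zero QALY difference leaves the ICER undefined; differences
    below numerical round-off (1e-9 QALYs / 1e-6 USD on lifetime totals) are
    treated as zero so identical strategies never divide by noise.
    """
    dc = result_intervention.discounted_cost - result_reference.discounted_cost
    de = result_intervention.discounted_qaly - result_reference.discounted_qaly
    if abs(de) < 1e-9:
        de = 0.0
    if abs(dc) < 1e-6:
        dc = 0.0
    icer: float | None = None
    defined = False
    if de > 0 and dc > 0:
        classification = "tradeoff_NE"
        icer = dc / de
        defined = True
    elif de > 0:
        classification = "dominant"
    elif de < 0 and dc < 0:
        classification = "tradeoff_SW"
    elif de < 0:
        classification = "dominated"
    else:
        classification = "dominated" if dc > 0 else ("dominant" if dc < 0 else "indifferent")
    return IncrementalResult(
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        icer_defined=defined,
        classification=classification,
        ce_intervention=result_intervention.cost_effectiveness_ratio,
        ce_reference=result_reference.cost_effectiveness_ratio,
    )
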