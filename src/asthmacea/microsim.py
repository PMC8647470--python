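"""Individual-level Monte Carlo simulator and synthetic-data generators.

The microsimulation walks individual patients through the exact per-cycle
transition matrices of the cohort engine, applying the same reward conventions
(entry-charged event costs, per-cycle drug cost while alive, trapezoid
half-cycle weights, the 52-week persistence split). Its sample means are
therefore unbiased estimators of the cohort model's expectations, which makes
it the brute-force validation oracle for the engine.

Also here: the packaged synthetic Gompertz–Makeham life table (re-exported
from :mod:`asthmacea.lifetable`) and a random-but-valid parameter-bundle
generator for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable, make_life_table
from .markov import State, _matrices_by_age
from .parameters import (
    ParameterBundle,
    Role,
    StrategyParams,
    TransitionParams,
    UtilityParams,
    CostParams,
    EconomicSettings,
    ParameterBundle as _Bundle,
    param_range,
    strategy_drug_cost_per_cycle,
    validate_bundle,
)

__all__ = [
    "MicrosimResult",
    "simulate_patients",
    "make_life_table",
    "random_parameter_table",
]

_N_ALIVE = int(State.DEATH_ASTHMA)  # states below this index are alive


@dataclass
class MicrosimResult:
    """Aggregate outcomes of an individual-level simulation run."""

    strategy: str
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_cost_undiscounted: float
    mean_qaly_undiscounted: float
    ocs_bursts_per_year: float
    ed_visits_per_year: float
    hospitalizations_per_year: float
    survival: np.ndarray  # fraction of patients alive at each cycle row


def simulate_patients(
    bundle: ParameterBundle,
    strategy: str | StrategyParams,
    n: int,
    seed: int,
    life_table: LifeTable | None = None,
) -> MicrosimResult:
    """Simulate ``n`` independent patient paths for one arm.

    Returns mean discounted cost and QALYs with Monte Carlo standard errors,
    annualized exacerbation event rates (events per person-year alive), and
    the empirical survival curve. Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(strategy, str):
        strategy = bundle.strategies[strategy]
    if life_table is None:
        life_table = make_life_table()
    s = bundle.settings
    cpy = s.cycles_per_year
    n_cycles = (s.max_age - s.start_age) * cpy
    split_cycle = cpy

    m_on = _matrices_by_age(bundle, strategy, life_table, on_treatment=True)
    m_off = _matrices_by_age(bundle, strategy, life_table, on_treatment=False)
    cum_on = np.cumsum(m_on, axis=2)
    cum_off = np.cumsum(m_off, axis=2)

    u = np.asarray(bundle.utilities.state_utilities())
    event_cost = np.zeros(6)
    event_cost[State.EXAC_OCS] = bundle.costs.c_ocs_burst.base
    event_cost[State.EXAC_ED] = bundle.costs.c_ed_visit.base
    event_cost[State.EXAC_HOSP] = bundle.costs.c_hosp_episode
    drug_on = strategy_drug_cost_per_cycle(strategy, bundle.costs, s)
    drug_off = strategy_drug_cost_per_cycle(bundle.strategies[bundle.reference], bundle.costs, s)
    persistence = strategy.persistence_52wk.base
    r = s.annual_discount.base
    dt_years = s.cycle_length_years

    rng = np.random.default_rng(seed)
    state = np.zeros(n, dtype=np.int8)  # everyone starts CONTROLLED
    on_drug = np.ones(n, dtype=bool)
    cost_d = np.zeros(n)
    qaly_d = np.zeros(n)
    cost_u = np.zeros(n)
    qaly_u = np.zeros(n)
    events = np.zeros(3)  # OCS, ED, HOSP entries
    person_years = 0.0
    survival = np.zeros(n_cycles + 1)

    hcc = s.half_cycle_correction
    for t in range(n_cycles + 1):
        alive = state < _N_ALIVE
        n_alive = int(alive.sum())
        survival[t] = n_alive / n
        if n_alive == 0:
            break
        if t == split_cycle:
            # the 52-week adherence split: discontinuers lose the treatment
            # effect and revert to the reference arm's drug cost
            stay = rng.random(n) < persistence
            on_drug &= stay
        if hcc:
            w = 0.5 if (t == 0 or t == n_cycles) else 1.0
        else:
            w = 0.0 if t == n_cycles else 1.0
        if w > 0.0:
            disc = (1.0 + r) ** (-t / cpy)
            st = state[alive]
            drug = np.where(on_drug[alive], drug_on, drug_off)
            reward_cost = event_cost[st] + drug
            reward_qaly = u[st] * dt_years
            cost_u[alive] += w * reward_cost
            qaly_u[alive] += w * reward_qaly
            cost_d[alive] += w * disc * reward_cost
            qaly_d[alive] += w * disc * reward_qaly
        if t == n_cycles:
            break
        person_years += n_alive * dt_years
        # transition the alive patients
        age_idx = t // cpy
        rows_on = cum_on[age_idx]
        rows_off = cum_off[age_idx]
        idx = np.nonzero(alive)[0]
        uni = rng.random(idx.size)
        cum_rows = np.where(on_drug[idx, None], rows_on[state[idx]], rows_off[state[idx]])
        new_state = (uni[:, None] > cum_rows).sum(axis=1).astype(np.int8)
        for k, which in enumerate((State.EXAC_OCS, State.EXAC_ED, State.EXAC_HOSP)):
            events[k] += int(np.count_nonzero(new_state == which))
        state[idx] = new_state

    rates = events / person_years if person_years > 0 else np.zeros(3)
    return MicrosimResult(
        strategy=strategy.name,
        n=n,
        seed=seed,
        mean_cost=float(cost_d.mean()),
        se_cost=float(cost_d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly_d.mean()),
        se_qaly=float(qaly_d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_cost_undiscounted=float(cost_u.mean()),
        mean_qaly_undiscounted=float(qaly_u.mean()),
        ocs_bursts_per_year=float(rates[0]),
        ed_visits_per_year=float(rates[1]),
        hospitalizations_per_year=float(rates[2]),
        survival=survival,
    )


def random_parameter_table(seed: int) -> ParameterBundle:
    """A random but always-valid parameter bundle for property tests.

    Probabilities are drawn in (0, 0.9), utilities in (0.3, 1), costs in
    (1, 500), the treatment RR in (0.5, 1); ranges are the +/-25% rule. Every
    bundle passes :func:`asthmacea.parameters.validate_bundle`.
    """
    rng = np.random.default_rng(seed)

    def prob() -> float:
        return float(rng.uniform(1e-6, 0.9))

    u_controlled = float(rng.uniform(0.3, 1.0))
    decs = sorted(float(rng.uniform(0.0, 0.45)) * u_controlled for _ in range(3))
    rr = float(rng.uniform(0.5, 1.0))
    cost = lambda: float(rng.uniform(1.0, 500.0))

    P = param_range
    triple = StrategyParams(
        "triple", True,
        rr_exacerbation=P(rr, Role.RELATIVE_RISK),
        persistence_52wk=P(float(rng.uniform(0.3, 0.9)), Role.PROPORTION),
    )
    dual = StrategyParams(
        "dual", False,
        rr_exacerbation=P(1.0, Role.RELATIVE_RISK, 1.0, 1.0),
        persistence_52wk=P(float(rng.uniform(0.3, 0.9)), Role.PROPORTION),
    )
    bundle = _Bundle(
        strategies={"triple": triple, "dual": dual},
        transitions=TransitionParams(
            p_controlled_to_ocs=P(prob(), Role.PROBABILITY),
            p_ocs_to_ed=P(prob(), Role.PROBABILITY),
            p_ed_to_hosp=P(prob(), Role.PROBABILITY),
            p_asthma_death=P(float(rng.uniform(1e-6, 0.01)), Role.PROBABILITY),
        ),
        utilities=UtilityParams(
            u_controlled=P(u_controlled, Role.UTILITY),
            d_ocs=P(decs[0], Role.UTILITY_DECREMENT),
            d_ed=P(decs[1], Role.UTILITY_DECREMENT),
            d_hosp=P(decs[2], Role.UTILITY_DECREMENT),
        ),
        costs=CostParams(
            c_tiotropium=P(cost(), Role.COST),
            c_umeclidinium=P(cost(), Role.COST),
            c_glycopyrronium=P(cost(), Role.COST),
            c_ics_laba=P(cost(), Role.COST),
            c_ed_visit=P(cost(), Role.COST),
            c_hosp_day=P(cost(), Role.COST),
            c_ocs_burst=P(float(rng.uniform(0.0, 100.0)), Role.COST),
            hosp_los_days=float(rng.uniform(1.0, 10.0)),
        ),
        settings=EconomicSettings(
            annual_discount=P(float(rng.uniform(0.0, 0.08)), Role.RATE),
            start_age=int(rng.integers(18, 60)),
            max_age=100,
        ),
    )
    validate_bundle(bundle)
    return bundle
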