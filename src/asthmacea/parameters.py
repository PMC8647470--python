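"""Model parameters for the triple- versus dual-inhaler cost-utility model.

The whole analysis is driven by a single :class:`ParameterBundle` holding every
quantity of the published base case as a :class:`ParamRange` (central value plus
a low/high range used by the deterministic and probabilistic sensitivity
analyses), together with the economic settings (cycle length, discounting,
willingness to pay, horizon).

Conventions
-----------
* Drug acquisition costs are quoted in USD per 4-week pack and converted to the
  2-week model cycle by :func:`strategy_drug_cost_per_cycle`.
* Ranges left unspecified are filled by the +/-25% rule, clipped to the role's
  natural bounds (probabilities, proportions and utilities to [0, 1], costs to
  [0, inf)).
* One published row prints its high equal to its base (the controlled-to-OCS
  transition probability); by default the printed value is kept, while the
  ``strict_25pct`` setting recomputes the high as base x 1.25 instead.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "Role",
    "ParamRange",
    "param_range",
    "expand_range",
    "StrategyParams",
    "TransitionParams",
    "UtilityParams",
    "CostParams",
    "EconomicSettings",
    "ParameterBundle",
    "ParameterValidationError",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "strategy_drug_cost_per_cycle",
    "get_param",
    "set_param",
    "UNCERTAIN_PARAMETERS",
]


class Role(str, Enum):
    """Semantic role of a parameter; determines bounds and its PSA distribution."""

    COST = "cost"
    UTILITY = "utility"
    UTILITY_DECREMENT = "utility_decrement"
    PROBABILITY = "probability"
    RELATIVE_RISK = "relative_risk"
    PROPORTION = "proportion"
    RATE = "rate"


#: roles whose values live on the closed unit interval
_UNIT_ROLES = {Role.UTILITY, Role.UTILITY_DECREMENT, Role.PROBABILITY, Role.PROPORTION}


def _role_bounds(role: Role) -> tuple[float, float]:
    if role in _UNIT_ROLES:
        return 0.0, 1.0
    return 0.0, float("inf")


class ParameterValidationError(ValueError):
    """A parameter set violates its invariants.

    Attributes
    ----------
    keys : list of str
        Names of the offending parameters / settings.
    """

    def __init__(self, keys: Iterable[str], message: str = ""):
        self.keys = sorted(set(keys))
        detail = message or "invalid parameter value(s)"
        super().__init__(f"{detail}: {', '.join(self.keys)}")


@dataclass(frozen=True)
class ParamRange:
    """A central value with its sensitivity-analysis range.

    Invariant: ``low <= base <= high`` and all three within the role's bounds.
    Use :func:`param_range` to build one (it fills missing range ends with the
    +/-25% rule and normalizes a swapped low/high pair).
    """

    base: float
    low: float
    high: float
    role: Role
    source: str = ""

    def __post_init__(self) -> None:
        lo, hi = _role_bounds(self.role)
        if not (self.low <= self.base <= self.high):
            raise ParameterValidationError(
                [self.source or "param"], "range must satisfy low <= base <= high"
            )
        if self.low < lo or self.high > hi:
            raise ParameterValidationError(
                [self.source or "param"], f"value outside [{lo}, {hi}] for role {self.role.value}"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def degenerate(self) -> bool:
        """True when the range carries no uncertainty (low == high)."""
        return self.high == self.low

    def at(self, direction: str) -> float:
        if direction not in ("low", "high"):
            raise ValueError(f"direction must be 'low' or 'high', got {direction!r}")
        return self.low if direction == "low" else self.high


def _expand(base: float, role: Role, direction: str) -> float:
    lo, hi = _role_bounds(role)
    value = base * (0.75 if direction == "low" else 1.25)
    return min(max(value, lo), hi)


def expand_range(value: ParamRange, direction: str) -> float:
    """+/-25% of the central value, clipped to the role's bounds.

    This is the default rule used to construct sensitivity ranges when no
    explicit low/high is given.
    """
    if direction not in ("low", "high"):
        raise ValueError(f"direction must be 'low' or 'high', got {direction!r}")
    return _expand(value.base, value.role, direction)


def param_range(
    base: float,
    role: Role | str,
    low: float | None = None,
    high: float | None = None,
    source: str = "",
) -> ParamRange:
    """Build a validated :class:`ParamRange`.

    Missing range ends are filled with the +/-25% rule; a swapped (low, high)
    pair is normalized so that ``low <= high`` (the published relative-risk row
    prints its ends in the opposite order).
    """
    role = Role(role)
    if low is None:
        low = _expand(base, role, "low")
    if high is None:
        high = _expand(base, role, "high")
    if low > high:
        low, high = high, low
    return ParamRange(float(base), float(low), float(high), role, source)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class StrategyParams:
    """One treatment arm.

    ``rr_exacerbation`` multiplies the controlled-to-OCS-burst transition
    probability while the patient is on treatment; the reference arm carries a
    fixed RR of 1. ``persistence_52wk`` is the fraction still on treatment
    after 52 weeks (the complements of the published discontinuation rates).
    """

    name: str
    includes_lama: bool
    rr_exacerbation: ParamRange
    persistence_52wk: ParamRange


@dataclass
class TransitionParams:
    """Per-cycle (2-week) disease transition probabilities."""

    p_controlled_to_ocs: ParamRange
    p_ocs_to_ed: ParamRange
    p_ed_to_hosp: ParamRange
    p_asthma_death: ParamRange


@dataclass
class UtilityParams:
    """Controlled-state utility and the exacerbation decrements.

    State utilities are ``u_controlled`` minus the decrement for the full cycle
    spent in the exacerbation state; death states carry utility 0.
    """

    u_controlled: ParamRange
    d_ocs: ParamRange
    d_ed: ParamRange
    d_hosp: ParamRange

    def state_utilities(self) -> list[float]:
        u = self.u_controlled.base
        return [u, u - self.d_ocs.base, u - self.d_ed.base, u - self.d_hosp.base, 0.0, 0.0]


@dataclass
class CostParams:
    """Drug and event costs (USD).

    Drug costs are per 4-week pack. Hospitalization cost is per day and is
    charged for ``hosp_los_days`` days per admission. The OCS-burst episode
    cost is not published; it defaults to 0 and is then excluded from the
    sensitivity analyses. ``triple_drug_mix`` weights the three LAMA options
    (tiotropium, umeclidinium, glycopyrronium) in the triple arm's drug cost.
    """

    c_tiotropium: ParamRange
    c_umeclidinium: ParamRange
    c_glycopyrronium: ParamRange
    c_ics_laba: ParamRange
    c_ed_visit: ParamRange
    c_hosp_day: ParamRange
    c_ocs_burst: ParamRange
    hosp_los_days: float = 5.0
    triple_drug_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    @property
    def c_hosp_episode(self) -> float:
        return self.c_hosp_day.base * self.hosp_los_days

    def lama_cost_4wk(self) -> float:
        w = self.triple_drug_mix
        return (
            w[0] * self.c_tiotropium.base
            + w[1] * self.c_umeclidinium.base
            + w[2] * self.c_glycopyrronium.base
        )


@dataclass
class EconomicSettings:
    """Cycle structure, discounting, horizon and the decision threshold."""

    annual_discount: ParamRange
    wtp_per_qaly: float = 19_000.0
    cycle_length_weeks: float = 2.0
    cycles_per_year: int = 26
    start_age: int = 18
    max_age: int = 100
    half_cycle_correction: bool = True
    strict_25pct: bool = False
    currency_note: str = "US$1.00 = COP$ 3,500"

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_weeks / 52.0


@dataclass
class ParameterBundle:
    """The complete, validated parameter set: single source of truth for the
    base case, the one-way DSA and the PSA."""

    strategies: dict[str, StrategyParams]
    transitions: TransitionParams
    utilities: UtilityParams
    costs: CostParams
    settings: EconomicSettings
    intervention: str = "triple"
    reference: str = "dual"

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)

    def to_frame(self) -> pd.DataFrame:
        """One row per named parameter: name, role, base, low, high, source."""
        rows = []
        for name in PARAM_ACCESSORS:
            pr = get_param(self, name)
            rows.append(
                {
                    "name": name,
                    "role": pr.role.value,
                    "base": pr.base,
                    "low": pr.low,
                    "high": pr.high,
                    "source": pr.source,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flat parameter registry (drives config I/O, DSA and PSA)
# ---------------------------------------------------------------------------

# name -> (section, attribute); 'strategy:<name>' sections address one arm
PARAM_ACCESSORS: dict[str, tuple[str, str]] = {
    "cost_tiotropium": ("costs", "c_tiotropium"),
    "cost_umeclidinium": ("costs", "c_umeclidinium"),
    "cost_glycopyrronium": ("costs", "c_glycopyrronium"),
    "cost_ics_laba": ("costs", "c_ics_laba"),
    "cost_ed_visit": ("costs", "c_ed_visit"),
    "cost_hosp_day": ("costs", "c_hosp_day"),
    "cost_ocs_burst": ("costs", "c_ocs_burst"),
    "u_controlled": ("utilities", "u_controlled"),
    "d_ocs_burst": ("utilities", "d_ocs"),
    "d_ed_visit": ("utilities", "d_ed"),
    "d_hospitalization": ("utilities", "d_hosp"),
    "rr_exacerbation_triple": ("strategy:triple", "rr_exacerbation"),
    "persistence_triple": ("strategy:triple", "persistence_52wk"),
    "persistence_dual": ("strategy:dual", "persistence_52wk"),
    "p_controlled_to_ocs": ("transitions", "p_controlled_to_ocs"),
    "p_ocs_to_ed": ("transitions", "p_ocs_to_ed"),
    "p_ed_to_hosp": ("transitions", "p_ed_to_hosp"),
    "p_asthma_death": ("transitions", "p_asthma_death"),
    "annual_discount": ("settings", "annual_discount"),
}

#: parameters varied in the DSA / sampled in the PSA (zero-valued costs are
#: dropped at run time, and the discount rate is DSA-only)
UNCERTAIN_PARAMETERS: tuple[str, ...] = tuple(PARAM_ACCESSORS)


def _section_obj(bundle: ParameterBundle, section: str):
    if section.startswith("strategy:"):
        return bundle.strategies[section.split(":", 1)[1]]
    return getattr(bundle, section)


def get_param(bundle: ParameterBundle, name: str) -> ParamRange:
    section, attr = PARAM_ACCESSORS[name]
    return getattr(_section_obj(bundle, section), attr)


def set_param(bundle: ParameterBundle, name: str, value: ParamRange) -> None:
    section, attr = PARAM_ACCESSORS[name]
    setattr(_section_obj(bundle, section), attr, value)


# ---------------------------------------------------------------------------
# defaults: the published base case
# ---------------------------------------------------------------------------


def default_parameters(strict_25pct: bool = False) -> ParameterBundle:
    """The packaged base-case parameter set.

    Every value is the published central estimate with its published range;
    the two gaps in the source (OCS-burst episode cost, hospital length of
    stay) take the documented defaults of 0 and 5 days.
    """
    P = param_range
    triple = StrategyParams(
        name="triple",
        includes_lama=True,
        # published range printed in reverse order; normalized here
        rr_exacerbation=P(0.85, Role.RELATIVE_RISK, 0.78, 0.92, source="meta-analysis RR"),
        persistence_52wk=P(0.63, Role.PROPORTION, 0.47, 0.79, source="adherence study"),
    )
    dual = StrategyParams(
        name="dual",
        includes_lama=False,
        rr_exacerbation=P(1.0, Role.RELATIVE_RISK, 1.0, 1.0, source="reference arm"),
        persistence_52wk=P(0.56, Role.PROPORTION, 0.42, 0.70, source="adherence study"),
    )
    # the printed high for controlled->OCS equals its base; strict_25pct
    # recomputes it with the generic rule instead
    p_c_ocs_high = 0.15 if strict_25pct else 0.12
    transitions = TransitionParams(
        p_controlled_to_ocs=P(0.12, Role.PROBABILITY, 0.07, p_c_ocs_high, source="trial data"),
        p_ocs_to_ed=P(0.47, Role.PROBABILITY, 0.35, 0.59, source="trial data"),
        p_ed_to_hosp=P(0.15, Role.PROBABILITY, 0.11, 0.19, source="trial data"),
        p_asthma_death=P(0.0002, Role.PROBABILITY, 0.00014, 0.00024, source="vital statistics"),
    )
    utilities = UtilityParams(
        u_controlled=P(0.74, Role.UTILITY, 0.56, 0.93, source="utility review"),
        d_ocs=P(0.10, Role.UTILITY_DECREMENT, 0.08, 0.13, source="utility review"),
        d_ed=P(0.15, Role.UTILITY_DECREMENT, 0.11, 0.19, source="utility review"),
        d_hosp=P(0.20, Role.UTILITY_DECREMENT, 0.15, 0.25, source="utility review"),
    )
    costs = CostParams(
        c_tiotropium=P(60.0, Role.COST, 45.0, 75.0, source="national price registry"),
        c_umeclidinium=P(32.0, Role.COST, 24.0, 40.0, source="national price registry"),
        c_glycopyrronium=P(32.0, Role.COST, 24.0, 40.0, source="national price registry"),
        c_ics_laba=P(27.0, Role.COST, 20.0, 34.0, source="national price registry"),
        c_ed_visit=P(26.0, Role.COST, 20.0, 33.0, source="costing study"),
        c_hosp_day=P(80.0, Role.COST, 60.0, 100.0, source="costing study"),
        c_ocs_burst=P(0.0, Role.COST, 0.0, 0.0, source="not published; default 0"),
    )
    settings = EconomicSettings(
        annual_discount=P(0.05, Role.RATE, 0.0, 0.06, source="national guideline"),
        strict_25pct=strict_25pct,
    )
    bundle = ParameterBundle(
        strategies={"triple": triple, "dual": dual},
        transitions=transitions,
        utilities=utilities,
        costs=costs,
        settings=settings,
    )
    validate_bundle(bundle)
    return bundle


def validate_bundle(bundle: ParameterBundle) -> None:
    """Check every cross-parameter invariant; raise with the offending keys."""
    bad: list[str] = []
    ref = bundle.strategies[bundle.reference]
    if ref.rr_exacerbation.base != 1.0:
        bad.append("rr_exacerbation_dual")
    u = bundle.utilities
    max_dec = max(u.d_ocs.base, u.d_ed.base, u.d_hosp.base)
    if u.u_controlled.base - max_dec < 0:
        bad.append("u_controlled")
    if abs(sum(bundle.costs.triple_drug_mix) - 1.0) > 1e-9:
        bad.append("triple_drug_mix")
    if any(w < 0 for w in bundle.costs.triple_drug_mix):
        bad.append("triple_drug_mix")
    if bundle.costs.hosp_los_days < 0:
        bad.append("hosp_los_days")
    s = bundle.settings
    if abs(s.cycles_per_year * s.cycle_length_weeks - 52.0) > 1e-9:
        bad.append("cycles_per_year")
    if not 0.0 <= s.annual_discount.base <= 1.0:
        bad.append("annual_discount")
    if s.start_age >= s.max_age:
        bad.append("start_age")
    # a sampled/overridden escalation pair must still fit in one row
    t = bundle.transitions
    if t.p_ocs_to_ed.base + t.p_asthma_death.base > 1.0 or (
        t.p_ed_to_hosp.base + t.p_asthma_death.base > 1.0
    ):
        bad.append("p_ocs_to_ed")
    if bad:
        raise ParameterValidationError(bad)


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_SETTING_SCALARS = (
    "wtp_per_qaly",
    "cycle_length_weeks",
    "cycles_per_year",
    "start_age",
    "max_age",
    "half_cycle_correction",
    "strict_25pct",
    "currency_note",
)


def load_parameters(config_path: str | Path | None = None) -> ParameterBundle:
    """Load a validated bundle; with no config the packaged defaults are used.

    The config file is YAML with two optional blocks::

        parameters:
          u_controlled: {base: 0.8}          # low/high refilled by +/-25%
          rr_exacerbation_triple: {base: 0.85, low: 0.77, high: 0.90}
        settings:
          start_age: 40
          annual_discount: {base: 0.0}
          hosp_los_days: 3
          triple_drug_mix: [1, 0, 0]
    """
    raw: dict = {}
    if config_path is not None:
        text = Path(config_path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ParameterValidationError(["<config>"], "config must be a mapping")
    unknown = set(raw) - {"parameters", "settings"}
    if unknown:
        raise ParameterValidationError(unknown, "unknown top-level config keys")

    settings_block = dict(raw.get("settings") or {})
    bundle = default_parameters(strict_25pct=bool(settings_block.get("strict_25pct", False)))

    params_block = raw.get("parameters") or {}
    bad_keys = set(params_block) - set(PARAM_ACCESSORS)
    if bad_keys:
        raise ParameterValidationError(bad_keys, "unknown parameter names")
    for name, spec in params_block.items():
        if not isinstance(spec, dict) or "base" not in spec:
            raise ParameterValidationError([name], "parameter override needs a 'base' key")
        current = get_param(bundle, name)
        try:
            pr = param_range(
                float(spec["base"]),
                current.role,
                low=spec.get("low"),
                high=spec.get("high"),
                source=spec.get("source", current.source),
            )
        except ParameterValidationError as err:
            raise ParameterValidationError([name], str(err)) from err
        set_param(bundle, name, pr)

    for key, value in settings_block.items():
        if key in _SETTING_SCALARS:
            setattr(bundle.settings, key, value)
        elif key == "annual_discount":
            if not isinstance(value, dict) or "base" not in value:
                raise ParameterValidationError(["annual_discount"], "needs a 'base' key")
            bundle.settings.annual_discount = param_range(
                float(value["base"]),
                Role.RATE,
                low=value.get("low"),
                high=value.get("high"),
                source=value.get("source", bundle.settings.annual_discount.source),
            )
        elif key == "hosp_los_days":
            bundle.costs.hosp_los_days = float(value)
        elif key == "cost_ocs_burst":  # convenience scalar override
            bundle.costs.c_ocs_burst = param_range(float(value), Role.COST)
        elif key == "triple_drug_mix":
            bundle.costs.triple_drug_mix = tuple(float(w) for w in value)  # type: ignore[assignment]
        else:
            raise ParameterValidationError([key], "unknown settings key")

    validate_bundle(bundle)
    return bundle


def write_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    """Serialize a bundle so that ``load_parameters`` round-trips it exactly."""
    params = {
        name: {
            "base": pr.base,
            "low": pr.low,
            "high": pr.high,
            "source": pr.source,
        }
        for name, pr in ((n, get_param(bundle, n)) for n in PARAM_ACCESSORS)
        if name != "annual_discount"
    }
    s = bundle.settings
    doc = {
        "parameters": params,
        "settings": {
            "annual_discount": {
                "base": s.annual_discount.base,
                "low": s.annual_discount.low,
                "high": s.annual_discount.high,
                "source": s.annual_discount.source,
            },
            "wtp_per_qaly": s.wtp_per_qaly,
            "cycle_length_weeks": s.cycle_length_weeks,
            "cycles_per_year": s.cycles_per_year,
            "start_age": s.start_age,
            "max_age": s.max_age,
            "half_cycle_correction": s.half_cycle_correction,
            "strict_25pct": s.strict_25pct,
            "currency_note": s.currency_note,
            "hosp_los_days": bundle.costs.hosp_los_days,
            "triple_drug_mix": list(bundle.costs.triple_drug_mix),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def strategy_drug_cost_per_cycle(
    strategy: StrategyParams, costs: CostParams, settings: EconomicSettings
) -> float:
    """Drug acquisition cost per model cycle (USD).

    The 4-week pack cost (mix-weighted LAMA plus ICS+LABA for the triple arm,
    ICS+LABA alone for the dual arm) scaled by cycle_length_weeks / 4.
    """
    four_wk = costs.c_ics_laba.base
    if strategy.includes_lama:
        four_wk += costs.lama_cost_4wk()
    return four_wk * settings.cycle_length_weeks / 4.0
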