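"""Parameter uncertainty: one-way DSA (tornado) and probabilistic SA.

Distribution choice follows standard health-economic practice: beta for
relative risks, utilities and adherence proportions, gamma for costs, and
Dirichlet for the multinomial transition probabilities. Each published
low/high range is read as a 95% interval, so the implied standard deviation is
(high − low)/3.92, and distributions are moment-matched to (base, sd). A
degenerate range collapses to a fixed (non-sampled) parameter.

The PSA is a second-order Monte Carlo: each replicate draws one value per
uncertain parameter (utilities, event costs and transition probabilities are
shared across arms within a replicate), reruns the cohort model for both arms,
and records the (cost, QALY) pair. The headline probabilistic ICER is the
ratio of mean increments, not the mean of per-replicate ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import LifeTable, make_life_table
from .markov import IncrementalResult, ModelConstructionError, incremental, run_cohort
from .parameters import (
    ParamRange,
    ParameterBundle,
    ParameterValidationError,
    Role,
    UNCERTAIN_PARAMETERS,
    get_param,
    set_param,
    validate_bundle,
)

__all__ = [
    "DistributionSpec",
    "DistributionFitError",
    "fit_beta",
    "fit_gamma",
    "fit_dirichlet",
    "fit_distribution",
    "build_distributions",
    "PSAResult",
    "run_psa",
    "quadrant_proportions",
    "nmb",
    "CEACPoint",
    "CEACResult",
    "ceac",
    "default_wtp_grid",
    "TornadoRow",
    "one_way_dsa",
]

#: a printed low/high range is read as a central 95% interval
RANGE_TO_SD = 3.92


class DistributionFitError(ValueError):
    """Moment matching failed (implied shape parameters non-positive)."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    family: str  # beta | gamma | dirichlet | fixed
    params: dict
    source: ParamRange
    name: str = ""

    def mean(self) -> float:
        if self.family == "fixed":
            return self.params["value"]
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "dirichlet":
            alpha = self.params["alpha"]
            return alpha[0] / sum(alpha)  # marginal mean of the named branch
        raise ValueError(self.family)

    def sd(self) -> float:
        if self.family == "fixed":
            return 0.0
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return math.sqrt(self.params["shape"]) * self.params["scale"]
        if self.family == "dirichlet":
            alpha = self.params["alpha"]
            n = sum(alpha)
            p = alpha[0] / n
            return math.sqrt(p * (1 - p) / (n + 1))
        raise ValueError(self.family)

    def sample(self, rng: np.random.Generator) -> float:
        """One draw; for a Dirichlet spec, the named (first) branch marginal."""
        if self.family == "fixed":
            return self.params["value"]
        if self.family == "beta":
            return float(rng.beta(self.params["alpha"], self.params["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(self.params["shape"], self.params["scale"]))
        if self.family == "dirichlet":
            return float(rng.dirichlet(self.params["alpha"])[0])
        raise ValueError(self.family)


def _sd_from_range(pr: ParamRange) -> float:
    return pr.width / RANGE_TO_SD


def fit_beta(pr: ParamRange) -> DistributionSpec:
    """Moment-matched beta: mean = base, sd = (high − low)/3.92."""
    if pr.degenerate:
        return DistributionSpec("fixed", {"value": pr.base}, pr, pr.source)
    m, s = pr.base, _sd_from_range(pr)
    if not 0.0 < m < 1.0:
        raise DistributionFitError(f"beta needs 0 < base < 1, got {m}")
    nu = m * (1.0 - m) / s**2 - 1.0
    alpha, beta = m * nu, (1.0 - m) * nu
    if alpha <= 0 or beta <= 0:
        raise DistributionFitError(
            f"implied beta shapes non-positive for base {m}, sd {s:.4g}; "
            "narrow the range or widen it toward the bounds"
        )
    return DistributionSpec("beta", {"alpha": alpha, "beta": beta}, pr, pr.source)


def fit_gamma(pr: ParamRange) -> DistributionSpec:
    """Moment-matched gamma: shape = (m/s)^2, scale = s^2/m."""
    if pr.degenerate:
        return DistributionSpec("fixed", {"value": pr.base}, pr, pr.source)
    m, s = pr.base, _sd_from_range(pr)
    if m <= 0:
        raise DistributionFitError(f"gamma needs base > 0 with a non-degenerate range, got {m}")
    return DistributionSpec(
        "gamma", {"shape": (m / s) ** 2, "scale": s**2 / m}, pr, pr.source
    )


def fit_dirichlet(branch_probs: list[ParamRange]) -> DistributionSpec:
    """Dirichlet over the branches of one source state plus its residual.

    The effective sample size N is solved from the beta-marginal identity
    p(1 − p)/(N + 1) = s^2 for the branch with the largest base (s from that
    branch's range); concentrations are alpha_i = p_i * N with the residual
    ("stay/return") branch absorbing the remaining mass.
    """
    if not branch_probs:
        raise DistributionFitError("need at least one branch")
    total = sum(pr.base for pr in branch_probs)
    if total > 1.0:
        raise DistributionFitError("branch probabilities exceed 1")
    lead = max(branch_probs, key=lambda pr: pr.base)
    if lead.degenerate:
        if len(branch_probs) == 1:
            return DistributionSpec("fixed", {"value": lead.base}, lead, lead.source)
        raise DistributionFitError("leading branch has a degenerate range")
    p, s = lead.base, _sd_from_range(lead)
    n = p * (1.0 - p) / s**2 - 1.0
    if n <= 0:
        raise DistributionFitError(
            f"no positive effective sample size solves sd {s:.4g} at p {p}"
        )
    alpha = [pr.base * n for pr in branch_probs] + [(1.0 - total) * n]
    if any(a <= 0 for a in alpha):
        raise DistributionFitError("non-positive Dirichlet concentration")
    return DistributionSpec("dirichlet", {"alpha": alpha}, lead, lead.source)


def fit_distribution(pr: ParamRange) -> DistributionSpec:
    """Family by role: beta for unit-interval roles and RR, gamma for costs,
    Dirichlet (single branch + residual) for transition probabilities."""
    if pr.degenerate:
        return DistributionSpec("fixed", {"value": pr.base}, pr, pr.source)
    if pr.role is Role.COST:
        return fit_gamma(pr)
    if pr.role is Role.PROBABILITY:
        return fit_dirichlet([pr])
    if pr.role in (Role.UTILITY, Role.UTILITY_DECREMENT, Role.PROPORTION, Role.RELATIVE_RISK):
        return fit_beta(pr)
    raise DistributionFitError(f"no sampling family for role {pr.role.value}")


def build_distributions(bundle: ParameterBundle) -> dict[str, DistributionSpec]:
    """Fit a distribution for every sampled parameter of the bundle.

    Zero-valued costs and degenerate ranges are excluded; the discount rate is
    a DSA-only parameter and is never sampled.
    """
    specs: dict[str, DistributionSpec] = {}
    for name in UNCERTAIN_PARAMETERS:
        if name == "annual_discount":
            continue
        pr = get_param(bundle, name)
        if pr.role is Role.COST and pr.base == 0.0:
            continue
        if pr.degenerate:
            continue
        spec = fit_distribution(pr)
        specs[name] = DistributionSpec(spec.family, spec.params, pr, name)
    return specs


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-replicate (cost, QALY) pairs per arm plus the increments."""

    cost: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_reps: int
    seed: int
    n_rejected: int
    intervention: str = "triple"
    reference: str = "dual"

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.delta_qaly.mean())

    @property
    def icer_of_means(self) -> float:
        """The probabilistic ICER: mean ΔC over mean ΔE."""
        return self.mean_delta_cost / self.mean_delta_qaly

    def to_frame(self, wtp: float | None = None) -> pd.DataFrame:
        rows = []
        for arm in (self.intervention, self.reference):
            df = pd.DataFrame(
                {
                    "replicate": np.arange(self.n_reps),
                    "strategy": arm,
                    "cost": self.cost[arm],
                    "qaly": self.qaly[arm],
                    "delta_cost": self.delta_cost,
                    "delta_qaly": self.delta_qaly,
                }
            )
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        if wtp is not None:
            out["nmb"] = wtp * out["delta_qaly"] - out["delta_cost"]
        return out


def _apply_draws(bundle: ParameterBundle, draws: dict[str, float]) -> ParameterBundle:
    drawn = bundle.copy()
    for name, value in draws.items():
        pr = get_param(drawn, name)
        set_param(drawn, name, ParamRange(value, value, value, pr.role, pr.source))
    validate_bundle(drawn)
    return drawn


def run_psa(
    bundle: ParameterBundle,
    n_reps: int = 1000,
    seed: int = 0,
    life_table: LifeTable | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over the fitted parameter distributions.

    Parameters common to both arms share a single draw per replicate. A
    replicate whose draw produces an invalid transition row is rejected and
    redrawn; more than 5% rejections aborts the run.
    """
    if life_table is None:
        life_table = make_life_table()
    specs = build_distributions(bundle)
    rng = np.random.default_rng(seed)
    arms = (bundle.intervention, bundle.reference)
    cost = {arm: np.empty(n_reps) for arm in arms}
    qaly = {arm: np.empty(n_reps) for arm in arms}
    n_rejected = 0
    max_rejected = max(1, int(0.05 * n_reps))
    for i in range(n_reps):
        while True:
            draws = {name: spec.sample(rng) for name, spec in specs.items()}
            try:
                drawn = _apply_draws(bundle, draws)
                results = {arm: run_cohort(drawn, arm, life_table) for arm in arms}
            except (ModelConstructionError, ParameterValidationError):
                n_rejected += 1
                if n_rejected > max_rejected:
                    raise RuntimeError(
                        f"more than 5% of PSA draws rejected ({n_rejected} rejections)"
                    )
                continue
            break
        for arm in arms:
            cost[arm][i] = results[arm].discounted_cost
            qaly[arm][i] = results[arm].discounted_qaly
    dc = cost[arms[0]] - cost[arms[1]]
    de = qaly[arms[0]] - qaly[arms[1]]
    return PSAResult(
        cost=cost,
        qaly=qaly,
        delta_cost=dc,
        delta_qaly=de,
        n_reps=n_reps,
        seed=seed,
        n_rejected=n_rejected,
        intervention=arms[0],
        reference=arms[1],
    )


def quadrant_proportions(psa: PSAResult) -> dict[str, float]:
    """Fractions of replicates per cost-effectiveness-plane quadrant.

    q1: ΔE>0, ΔC>0 (more effective, more costly); q2: ΔE>0, ΔC<0;
    q3: ΔE<0, ΔC<0; q4: ΔE<0, ΔC>0. Boundary points (exact zeros) are
    assigned to q1, the reading least favourable to the intervention.
    """
    if psa.n_reps == 0:
        raise ValueError("empty PSA")
    de, dc = psa.delta_qaly, psa.delta_cost
    q2 = np.mean((de > 0) & (dc < 0))
    q3 = np.mean((de < 0) & (dc < 0))
    q4 = np.mean((de < 0) & (dc > 0))
    q1 = 1.0 - q2 - q3 - q4
    return {"q1": float(q1), "q2": float(q2), "q3": float(q3), "q4": float(q4)}


def nmb(wtp: float, delta_qaly: float, delta_cost: float) -> float:
    """Net monetary benefit wtp × ΔE − ΔC; positive iff cost-effective."""
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float


@dataclass
class CEACResult:
    points: list[CEACPoint]
    crossing_wtp: float | None  # smallest grid WTP with probability >= 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": [p.wtp for p in self.points],
                "prob_cost_effective": [p.prob_cost_effective for p in self.points],
            }
        )


def default_wtp_grid(wtp_per_qaly: float = 19_000.0) -> np.ndarray:
    """$0–$2,000 in $50 steps, plus the decision threshold itself."""
    grid = np.arange(0.0, 2000.0 + 1e-9, 50.0)
    if wtp_per_qaly not in grid:
        grid = np.append(grid, wtp_per_qaly)
    return grid


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACResult:
    """Cost-effectiveness acceptability curve of the intervention.

    A replicate counts as cost-effective only with strictly positive net
    monetary benefit (ties count against the intervention).
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    if np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("WTP grid must be strictly increasing")
    points = []
    crossing = None
    for w in wtp_grid:
        prob = float(np.mean(w * psa.delta_qaly - psa.delta_cost > 0.0))
        points.append(CEACPoint(float(w), prob))
        if crossing is None and prob >= 0.5:
            crossing = float(w)
    return CEACResult(points, crossing)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoRow:
    parameter: str
    icer_at_low: float | None
    icer_at_high: float | None
    annotation_low: str = ""
    annotation_high: str = ""

    @property
    def spread(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_with(bundle: ParameterBundle, name: str, value: float,
               life_table: LifeTable) -> IncrementalResult:
    varied = bundle.copy()
    pr = get_param(varied, name)
    set_param(varied, name, ParamRange(value, min(pr.low, value), max(pr.high, value),
                                       pr.role, pr.source))
    validate_bundle(varied)
    res_i = run_cohort(varied, varied.intervention, life_table)
    res_r = run_cohort(varied, varied.reference, life_table)
    return incremental(res_i, res_r)


def one_way_dsa(
    bundle: ParameterBundle,
    life_table: LifeTable | None = None,
    parameters: list[str] | None = None,
) -> tuple[list[TornadoRow], bool]:
    """Recompute the deterministic ICER at each parameter's low and high.

    Returns the tornado rows sorted by non-increasing spread, plus a flag that
    is True when any one-way ICER exceeds the willingness-to-pay threshold
    (i.e. the base-case verdict is NOT robust). Zero-valued costs are skipped;
    an undefined ICER at an extreme is annotated with the dominance
    classification instead of a number.
    """
    if life_table is None:
        life_table = make_life_table()
    if parameters is None:
        parameters = [
            name
            for name in UNCERTAIN_PARAMETERS
            if not (get_param(bundle, name).role is Role.COST
                    and get_param(bundle, name).base == 0.0)
        ]
    rows: list[TornadoRow] = []
    exceeds = False
    for name in parameters:
        pr = get_param(bundle, name)
        values: dict[str, tuple[float | None, str]] = {}
        for direction in ("low", "high"):
            inc = _icer_with(bundle, name, pr.at(direction), life_table)
            if inc.icer_defined:
                values[direction] = (inc.icer, "")
                if inc.icer > bundle.settings.wtp_per_qaly:
                    exceeds = True
            else:
                values[direction] = (None, inc.classification)
        rows.append(
            TornadoRow(
                parameter=name,
                icer_at_low=values["low"][0],
                icer_at_high=values["high"][0],
                annotation_low=values["low"][1],
                annotation_high=values["high"][1],
            )
        )
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows, exceeds


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "icer_at_low": [r.icer_at_low for r in rows],
            "icer_at_high": [r.icer_at_high for r in rows],
            "spread": [r.spread for r in rows],
            "annotation_low": [r.annotation_low for r in rows],
            "annotation_high": [r.annotation_high for r in rows],
        }
    )
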