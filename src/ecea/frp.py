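"""Financial-risk-protection metrics: catastrophic costs, impoverishment, insurance value.

Three alternative estimators of the financial protection a policy affords:

1. **Catastrophic-cost cases averted** — an out-of-pocket payment is
   catastrophic when it exceeds a stated fraction Th of the payer's income,
   strictly: (c_DM + c_DNM) > y * Th.
2. **Poverty cases averted** — a paying individual is impoverished when
   income is strictly above the poverty line before payment and strictly
   below it after: y > Pl and y - (c_DM + c_DNM) < Pl.  Individuals already
   below the line never count.
3. **Money-metric value of insurance** — the CRRA risk premium
   E(y) - y* of the gamble "pay c with probability p = i_k * u_k", summed
   over the population; the policy's benefit is the premium reduction.

Both counting metrics are *expected* (real-valued) counts: each stratum's
paying caseload is spread over its income grid and the threshold indicator
integrated.  Ties break toward "not a case" (strict inequalities).  The
post-policy state multiplies out-of-pocket costs by (1 - crowd_out); event
probabilities are unchanged unless the insurance metric's optional
prevention mode is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .scenario import FrpConfig, Policy, Scenario, Stratum

__all__ = [
    "GambleSpec",
    "FrpOutcome",
    "certainty_equivalent",
    "risk_premium",
    "catastrophic_cases",
    "poverty_cases",
    "catastrophic_cases_averted",
    "poverty_cases_averted",
    "insurance_value_population",
    "compute_frp",
]


@dataclass(frozen=True)
class GambleSpec:
    """The individual-level gamble: lose ``cost`` with probability ``event_probability``.

    ``income`` is annual disposable income y; ``event_probability`` is the
    composite p = incidence x care-seeking; ``risk_aversion`` is the
    Arrow-Pratt coefficient r of the CRRA utility w(y) = y^(1-r) / (1-r).
    Requires income > cost so that post-payment income stays positive
    (CRRA utility with r > 1 diverges at zero).
    """

    income: float
    event_probability: float
    cost: float
    risk_aversion: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_probability <= 1.0:
            raise ValueError("event_probability must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")
        if self.risk_aversion <= 0:
            raise ValueError("risk_aversion must be > 0")
        if self.income <= self.cost:
            raise ValueError(
                "utility undefined at nonpositive net income (income must exceed cost)"
            )

    @property
    def expected_income(self) -> float:
        """E(y) = p (y - c) + (1 - p) y."""
        return self.income - self.event_probability * self.cost


def _ce_vec(y: np.ndarray, p: float, c: float, r: float) -> np.ndarray:
    """Vectorized certainty equivalent over an income grid (y > c elementwise)."""
    if p == 0.0 or c == 0.0:
        return y.copy()
    if p == 1.0:
        return y - c
    if r == 1.0:
        return np.exp(p * np.log(y - c) + (1.0 - p) * np.log(y))
    e = 1.0 - r
    return (p * (y - c) ** e + (1.0 - p) * y**e) ** (1.0 / e)


def certainty_equivalent(g: GambleSpec) -> float:
    """The certain income y* with the same CRRA utility as the gamble.

    y* = [p (y - c)^(1-r) + (1 - p) y^(1-r)]^(1/(1-r)) for r != 1; the r = 1
    case uses the logarithmic limit y* = exp(p ln(y - c) + (1 - p) ln y).
    """
    return float(
        _ce_vec(np.array([g.income]), g.event_probability, g.cost, g.risk_aversion)[0]
    )


def risk_premium(g: GambleSpec) -> float:
    """Money-metric value of insurance for one individual: E(y) - y*.

    Non-negative by Jensen's inequality (concave utility); exactly zero when
    the gamble is degenerate (p in {0, 1}) or costless (c = 0).
    """
    if g.cost == 0.0 or g.event_probability in (0.0, 1.0):
        return 0.0
    return g.expected_income - certainty_equivalent(g)


# ---------------------------------------------------------------------------
# counting metrics


def catastrophic_cases(
    incomes, case_weights, cost: float, threshold: float
) -> float:
    """Expected catastrophic-cost cases on an income grid.

    ``case_weights[i]`` paying cases sit at income ``incomes[i]``; a case is
    catastrophic when cost > income * threshold, strictly.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    y = np.asarray(incomes, dtype=float)
    w = np.asarray(case_weights, dtype=float)
    return float(np.sum(w * (cost > y * threshold)))


def poverty_cases(incomes, case_weights, cost: float, poverty_line: float) -> float:
    """Expected poverty cases: payers pushed strictly across the poverty line."""
    if poverty_line <= 0:
        raise ValueError("poverty_line must be > 0")
    y = np.asarray(incomes, dtype=float)
    w = np.asarray(case_weights, dtype=float)
    return float(np.sum(w * ((y > poverty_line) & (y - cost < poverty_line))))


@dataclass
class FrpOutcome:
    """Per-stratum FRP benefit with pre/post-policy diagnostics.

    ``per_stratum`` is the benefit B_FRP,k (cases averted for the counting
    metrics, money for the insurance metric); ``pre``/``post`` hold the
    before/after counts for the counting metrics (zeros for insurance).
    """

    metric: str
    labels: list[str]
    per_stratum: np.ndarray
    pre: np.ndarray
    post: np.ndarray

    @property
    def total(self) -> float:
        return float(np.sum(self.per_stratum))


def _income_grid(stratum: Stratum, frp: FrpConfig) -> np.ndarray:
    if stratum.income_dist is not None:
        return stratum.income_dist.discretize(frp.income_grid_n)
    return np.array([stratum.income])


def _counting_metric(
    strata: Sequence[Stratum],
    policy: Policy,
    frp: FrpConfig,
    metric: str,
    affected_fraction: Optional[float],
) -> FrpOutcome:
    pre = np.empty(len(strata))
    post = np.empty(len(strata))
    for j, s in enumerate(strata):
        grid = _income_grid(s, frp)
        u = affected_fraction if affected_fraction is not None else s.care_seeking
        weights = np.full(grid.size, s.caseload * u / grid.size)
        c_pre = s.oop_cost
        c_post = c_pre * (1.0 - policy.crowd_out)
        if metric == "catastrophic":
            pre[j] = catastrophic_cases(grid, weights, c_pre, frp.threshold)
            post[j] = catastrophic_cases(grid, weights, c_post, frp.threshold)
        else:
            pre[j] = poverty_cases(grid, weights, c_pre, frp.poverty_line)
            post[j] = poverty_cases(grid, weights, c_post, frp.poverty_line)
    return FrpOutcome(
        metric=metric,
        labels=[s.label for s in strata],
        per_stratum=pre - post,
        pre=pre,
        post=post,
    )


def catastrophic_cases_averted(
    strata: Sequence[Stratum], policy: Policy, frp: FrpConfig
) -> FrpOutcome:
    """Catastrophic-cost cases averted: before-vs-after count under crowd-out."""
    return _counting_metric(strata, policy, frp, "catastrophic", None)


def poverty_cases_averted(
    strata: Sequence[Stratum],
    policy: Policy,
    frp: FrpConfig,
    affected_fraction: Optional[float] = None,
) -> FrpOutcome:
    """Poverty cases averted: payers no longer pushed below the poverty line.

    ``affected_fraction`` overrides the fraction of each stratum's caseload
    counted as exposed; the default takes ``frp.poverty_affected_fraction``,
    falling back to each stratum's care-seeking fraction.
    """
    if affected_fraction is None:
        affected_fraction = frp.poverty_affected_fraction
    return _counting_metric(strata, policy, frp, "poverty", affected_fraction)


def insurance_value_population(
    strata: Sequence[Stratum],
    policy: Policy,
    frp: FrpConfig,
    convention: str = "crowd_out",
    prevention: bool = False,
) -> FrpOutcome:
    """Population money-metric value of insurance provided by the policy.

    For every representative income the CRRA risk premium is evaluated before
    and after the policy; the per-stratum benefit is the premium reduction
    times the persons represented, integrated over the stratum's income grid.

    The post-policy gamble has cost c x (1 - crowd_out) under the default
    ``crowd_out`` convention, or c x (1 - crowd_out x cov_policy) under the
    ``coverage`` convention; with ``prevention`` the event probability is
    additionally reduced by the policy's effective coverage gain
    (Eff x dCov).
    """
    n = len(strata)
    cov = policy.cov_policy_vec(n)
    eff_dcov = policy.effectiveness_vec(n) * policy.delta_cov_vec(n)
    r = frp.risk_aversion
    value = np.empty(n)
    for j, s in enumerate(strata):
        grid = _income_grid(s, frp)
        p = s.incidence * s.care_seeking
        c = s.oop_cost
        if convention == "crowd_out":
            c_post = c * (1.0 - policy.crowd_out)
        elif convention == "coverage":
            c_post = c * (1.0 - policy.crowd_out * cov[j])
        else:
            raise ValueError(f"unknown insurance convention {convention!r}")
        p_post = p * (1.0 - eff_dcov[j]) if prevention else p
        if c > 0 and p > 0 and np.any(grid <= c):
            raise ValueError(
                f"stratum {s.label!r}: utility undefined at nonpositive net income "
                f"(grid income <= out-of-pocket cost {c})"
            )
        prem_pre = (grid - p * c) - _ce_vec(grid, p, c, r) if 0 < p < 1 and c > 0 else 0.0
        prem_post = (
            (grid - p_post * c_post) - _ce_vec(grid, p_post, c_post, r)
            if 0 < p_post < 1 and c_post > 0
            else 0.0
        )
        per_person = np.asarray(prem_pre) - np.asarray(prem_post)
        value[j] = s.population * float(np.mean(per_person))
    return FrpOutcome(
        metric="insurance",
        labels=[s.label for s in strata],
        per_stratum=value,
        pre=np.zeros(n),
        post=np.zeros(n),
    )


def compute_frp(scenario: Scenario, policy: Optional[Policy] = None) -> FrpOutcome:
    """Dispatch to the metric configured in the scenario's FrpConfig."""
    pol = policy if policy is not None else scenario.primary_policy
    frp = scenario.frp
    if frp.metric == "catastrophic":
        return catastrophic_cases_averted(scenario.strata, pol, frp)
    if frp.metric == "poverty":
        return poverty_cases_averted(scenario.strata, pol, frp)
    return insurance_value_population(scenario.strata, pol, frp)
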