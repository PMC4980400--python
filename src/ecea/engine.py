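"""Deterministic ECEA arithmetic: health gains, private expenditures, net costs, ratios.

All quantities are expected values carried as exact reals — caseloads,
deaths and money are never rounded inside the engine; rounding happens only
in the reporting layer.  Per-stratum vectors are ordered as the scenario's
strata.

The coverage semantics deliberately distinguish three roles:

* health gains and cases averted scale with the coverage *increment*
  dCov = cov_policy - cov_baseline (default; a ``total`` basis using
  cov_policy alone is exposed for sensitivity analysis);
* implementer costs price the covered caseload, cov_costing x caseload
  (cov_costing defaults to cov_policy);
* private-expenditure aversion follows the crowd-out convention (the public
  payer displaces the out-of-pocket spending of all paying cases,
  PE_av = crowd_out x PE), with a ``coverage`` convention
  (PE_av = cov_policy x PE) selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scenario import Policy, Stratum

__all__ = [
    "health_gains",
    "cases_averted",
    "private_expenditures",
    "private_expenditures_averted",
    "net_costs",
    "Ratio",
    "icers",
    "EceaResult",
    "per_budget_scaling",
]


def _caseloads(strata: Sequence[Stratum]) -> np.ndarray:
    return np.array([s.caseload for s in strata], dtype=float)


def cases_averted(
    strata: Sequence[Stratum], policy: Policy, coverage_basis: str = "incremental"
) -> np.ndarray:
    """Disease cases averted per stratum: Eff x coverage x caseload."""
    n = len(strata)
    if coverage_basis == "incremental":
        cov = policy.delta_cov_vec(n)
    elif coverage_basis == "total":
        cov = policy.cov_policy_vec(n)
    else:
        raise ValueError(f"unknown coverage_basis {coverage_basis!r}")
    return policy.effectiveness_vec(n) * cov * _caseloads(strata)


def health_gains(
    strata: Sequence[Stratum], policy: Policy, coverage_basis: str = "incremental"
) -> np.ndarray:
    """Deaths averted per stratum, B_H,k = Eff x dCov x CFR x caseload.

    A negative coverage increment (disinvestment) yields negative gains with
    a warning rather than an error.
    """
    cfr = np.array([s.case_fatality for s in strata], dtype=float)
    out = cases_averted(strata, policy, coverage_basis) * cfr
    if np.any(out < 0):
        warnings.warn(
            f"policy {policy.name!r}: negative health gains (coverage decreases)",
            stacklevel=2,
        )
    return out


def private_expenditures(
    strata: Sequence[Stratum], include_indirect: bool = False
) -> np.ndarray:
    """Pre-policy out-of-pocket spending per stratum: PE_k = i_k N_k u_k (c_DM + c_DNM).

    Indirect (productivity) costs c_I are excluded by default and added per
    paying case only when ``include_indirect`` is set.
    """
    pe = np.empty(len(strata))
    for j, s in enumerate(strata):
        c = s.oop_cost + (s.c_i if include_indirect else 0.0)
        pe[j] = s.caseload * s.care_seeking * c
    return pe


def private_expenditures_averted(
    strata: Sequence[Stratum],
    policy: Policy,
    convention: str = "crowd_out",
    include_indirect: bool = False,
) -> np.ndarray:
    """Out-of-pocket spending averted per stratum.

    ``crowd_out`` (default): PE_av = crowd_out x PE — public finance displaces
    the private payment of every paying case.  ``coverage``:
    PE_av = cov_policy x PE — only the covered fraction is displaced.
    """
    pe = private_expenditures(strata, include_indirect=include_indirect)
    if convention == "crowd_out":
        return policy.crowd_out * pe
    if convention == "coverage":
        return policy.cov_policy_vec(len(strata)) * pe
    raise ValueError(f"unknown private-expenditure convention {convention!r}")


def net_costs(
    strata: Sequence[Stratum], policy: Policy, coverage_basis: str = "incremental"
) -> np.ndarray:
    """Net implementer cost per stratum.

    C_k = covered_caseload_k x unit_cost_k - cases_averted_k x cost_offsets,
    with covered_caseload = cov_costing x caseload (cov_costing falls back to
    the post-policy coverage).  ``cost_offsets`` credits per-averted-case
    savings of preventive interventions.
    """
    n = len(strata)
    covered = policy.cov_costing_vec(n) * _caseloads(strata)
    c = covered * policy.unit_cost_vec(n)
    if policy.cost_offsets:
        c = c - cases_averted(strata, policy, coverage_basis) * policy.cost_offsets
    return c


@dataclass
class Ratio:
    """An incremental cost-effectiveness ratio with its degeneracy status.

    ``value`` is the unrounded ratio (NaN when undefined); ``rounded`` is the
    nearest currency unit, half away from zero; ``status`` is ``"ok"``,
    ``"undefined"`` (zero denominator) or ``"dominated"`` (negative ratio:
    the policy saves money or loses benefit).
    """

    value: float
    status: str = "ok"

    @property
    def rounded(self) -> Optional[int]:
        if self.status == "undefined" or not math.isfinite(self.value):
            return None
        return int(math.floor(abs(self.value) + 0.5)) * (1 if self.value >= 0 else -1)

    def __str__(self) -> str:
        return f"{self.rounded}" if self.status == "ok" else self.status


def _ratio(cost: float, benefit: float) -> Ratio:
    if benefit == 0:
        return Ratio(value=float("nan"), status="undefined")
    r = cost / benefit
    return Ratio(value=r, status="ok" if r >= 0 else "dominated")


@dataclass
class EceaResult:
    """The four per-stratum ECEA outcome panels plus derived ratios.

    Panels (one entry per stratum, scenario order): deaths averted
    (``health_gains``), disease cases averted, out-of-pocket spending averted
    (``pe_averted``) and its pre-policy level (``pe_baseline``), the FRP
    benefit in the configured metric's units, and the net implementer cost.
    """

    labels: list[str]
    health_gains: np.ndarray
    cases_averted: np.ndarray
    pe_baseline: np.ndarray
    pe_averted: np.ndarray
    frp_benefit: np.ndarray
    net_cost: np.ndarray
    frp_metric: str = "poverty"
    policy_name: str = ""
    currency: str = "USD"

    _panels = (
        "health_gains",
        "cases_averted",
        "pe_baseline",
        "pe_averted",
        "frp_benefit",
        "net_cost",
    )

    # -- totals ------------------------------------------------------------
    @property
    def total_health_gains(self) -> float:
        return float(np.sum(self.health_gains))

    @property
    def total_pe_averted(self) -> float:
        return float(np.sum(self.pe_averted))

    @property
    def total_frp_benefit(self) -> float:
        return float(np.sum(self.frp_benefit))

    @property
    def total_net_cost(self) -> float:
        return float(np.sum(self.net_cost))

    @property
    def icer_health(self) -> Ratio:
        """Net cost per death averted."""
        return _ratio(self.total_net_cost, self.total_health_gains)

    @property
    def icer_frp(self) -> Ratio:
        """Net cost per unit of financial risk protection (ICER_FRP)."""
        return _ratio(self.total_net_cost, self.total_frp_benefit)

    def scaled(self, budget: float) -> "EceaResult":
        """Outcomes renormalized to a budget: each panel x budget / total net cost."""
        return per_budget_scaling(self, budget)

    def summary(self):
        """Per-stratum dashboard as a DataFrame with a TOTAL row."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "deaths_averted": self.health_gains,
                "cases_averted": self.cases_averted,
                "pe_averted": self.pe_averted,
                f"frp_{self.frp_metric}": self.frp_benefit,
                "net_cost": self.net_cost,
            },
            index=pd.Index(self.labels, name="stratum"),
        )
        df.loc["TOTAL"] = df.sum(axis=0)
        return df


def per_budget_scaling(result: EceaResult, budget: float) -> EceaResult:
    """Scale every outcome panel to a stated budget (e.g. per $1 million spent).

    Linear in the budget; requires a strictly positive total net cost.
    """
    total = result.total_net_cost
    if total <= 0:
        raise ValueError("per-budget scaling requires a positive total net cost")
    f = budget / total
    kw = {name: getattr(result, name) * f for name in EceaResult._panels}
    return EceaResult(
        labels=list(result.labels),
        frp_metric=result.frp_metric,
        policy_name=result.policy_name,
        currency=result.currency,
        **kw,
    )


def icers(result: EceaResult) -> tuple[Ratio, Ratio]:
    """(net cost per death averted, net cost per FRP unit) for a result."""
    return result.icer_health, result.icer_frp
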