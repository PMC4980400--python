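"""Dashboard assembly, policy comparison, and machine-readable outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import (
    EceaResult,
    cases_averted,
    health_gains,
    net_costs,
    private_expenditures,
    private_expenditures_averted,
)
from .frp import compute_frp
from .scenario import Policy, Scenario, scenario_to_dict

__all__ = ["DashboardTable", "run_ecea", "compare_policies", "write_outputs"]

logger = logging.getLogger("ecea")

#: fixed column order of the per-stratum CSV
CSV_COLUMNS = [
    "stratum",
    "deaths_averted",
    "cases_averted",
    "pe_baseline",
    "pe_averted",
    "frp_benefit",
    "net_cost",
]


@dataclass
class DashboardTable:
    """The four-panel ECEA dashboard: one row per stratum plus TOTAL.

    Columns: health gains (deaths averted), private expenditures averted,
    the FRP benefit in the configured metric, and the net implementer cost.
    """

    table: pd.DataFrame
    policy_name: str
    frp_metric: str
    currency: str
    budget: Optional[float] = None

    def __str__(self) -> str:
        head = f"ECEA dashboard — policy: {self.policy_name} (FRP metric: {self.frp_metric}, {self.currency})"
        if self.budget is not None:
            head += f"\nscaled to a budget of {self.budget:,.0f} {self.currency}"
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:,.2f}")


def run_ecea(
    scenario: Scenario,
    policy: Optional[Policy] = None,
    budget: Optional[float] = None,
) -> tuple[EceaResult, DashboardTable]:
    """Run the full ECEA pipeline for one policy of a scenario.

    Computes the four outcome panels in order — health gains, private
    expenditures averted, the configured FRP benefit, net implementer costs —
    and assembles the per-stratum dashboard.  Deterministic: no randomness
    anywhere in the pipeline.
    """
    pol = policy if policy is not None else scenario.primary_policy
    strata = scenario.strata

    bh = health_gains(strata, pol)
    ca = cases_averted(strata, pol)
    pe0 = private_expenditures(strata)
    pe_av = private_expenditures_averted(strata, pol)
    frp = compute_frp(scenario, pol)
    cost = net_costs(strata, pol)

    result = EceaResult(
        labels=scenario.labels,
        health_gains=bh,
        cases_averted=ca,
        pe_baseline=pe0,
        pe_averted=pe_av,
        frp_benefit=frp.per_stratum,
        net_cost=cost,
        frp_metric=scenario.frp.metric,
        policy_name=pol.name,
        currency=scenario.currency_label,
    )
    logger.info("health gains total: %.6g deaths averted", result.total_health_gains)
    logger.info("private expenditures averted total: %.6g", result.total_pe_averted)
    logger.info("FRP benefit total (%s): %.6g", result.frp_metric, result.total_frp_benefit)
    logger.info("net cost total: %.6g", result.total_net_cost)

    shown = result if budget is None else result.scaled(budget)
    dashboard = DashboardTable(
        table=shown.summary(),
        policy_name=pol.name,
        frp_metric=scenario.frp.metric,
        currency=scenario.currency_label,
        budget=budget,
    )
    return result, dashboard


def compare_policies(scenarios: Sequence[Scenario], budget: float) -> pd.DataFrame:
    """Per-budget comparison table across policies, one row per policy.

    Every scenario's outcomes are renormalized to the same budget; no ranking
    is imposed — health gains and financial protection are reported side by
    side as separate efficiency criteria.  Requires a shared currency.
    """
    if len(scenarios) < 2:
        raise ValueError("compare_policies needs at least two scenarios")
    currencies = {sc.currency_label for sc in scenarios}
    if len(currencies) > 1:
        raise ValueError(f"inconsistent currencies: {sorted(currencies)}")
    rows = []
    for sc in scenarios:
        result, _ = run_ecea(sc)
        total = result.total_net_cost
        degenerate = total <= 0
        f = np.nan if degenerate else budget / total
        rows.append(
            {
                "policy": result.policy_name,
                "frp_metric": result.frp_metric,
                "deaths_averted_per_budget": result.total_health_gains * f,
                "frp_per_budget": result.total_frp_benefit * f,
                "pe_averted_per_budget": result.total_pe_averted * f,
                "net_cost_total": total,
                "icer_health": result.icer_health.value,
                "icer_frp": result.icer_frp.value,
                "icer_health_status": result.icer_health.status,
                "icer_frp_status": result.icer_frp.status,
            }
        )
    df = pd.DataFrame(rows).set_index("policy")
    df.attrs["budget"] = budget
    return df


def write_outputs(
    result: EceaResult,
    out_dir,
    scenario: Optional[Scenario] = None,
    dashboard: Optional[DashboardTable] = None,
) -> dict[str, Path]:
    """Write the per-stratum CSV, JSON summary, and optional text dashboard.

    Byte-stable for identical inputs: fixed column order, fixed float
    formatting, sorted JSON keys.  Returns the paths written.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    df = pd.DataFrame(
        {
            "stratum": result.labels,
            "deaths_averted": result.health_gains,
            "cases_averted": result.cases_averted,
            "pe_baseline": result.pe_baseline,
            "pe_averted": result.pe_averted,
            "frp_benefit": result.frp_benefit,
            "net_cost": result.net_cost,
        },
        columns=CSV_COLUMNS,
    )
    total_row = {"stratum": "TOTAL", **{c: df[c].sum() for c in CSV_COLUMNS[1:]}}
    df = pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
    csv_path = out / "per_stratum.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")

    summary = {
        "toolkit_version": __version__,
        "policy": result.policy_name,
        "currency": result.currency,
        "frp_metric": result.frp_metric,
        "totals": {
            "deaths_averted": result.total_health_gains,
            "cases_averted": float(np.sum(result.cases_averted)),
            "pe_averted": result.total_pe_averted,
            "frp_benefit": result.total_frp_benefit,
            "net_cost": result.total_net_cost,
        },
        "icer_health": {
            "value": None if result.icer_health.status == "undefined" else result.icer_health.value,
            "rounded": result.icer_health.rounded,
            "status": result.icer_health.status,
        },
        "icer_frp": {
            "value": None if result.icer_frp.status == "undefined" else result.icer_frp.value,
            "rounded": result.icer_frp.rounded,
            "status": result.icer_frp.status,
        },
    }
    if scenario is not None:
        summary["scenario"] = scenario_to_dict(scenario)
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    paths = {"csv": csv_path, "json": json_path}
    if dashboard is not None:
        txt_path = out / "dashboard.txt"
        txt_path.write_text(str(dashboard) + "\n")
        paths["dashboard"] = txt_path
    return paths
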