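"""Publication-style result tables.

Renders the base-case and Monte-Carlo summaries with the row labels of
the published results tables ("Costs for PFS state", "ICER ($ per
QALY)", ...), as a pandas DataFrame exportable to CSV, JSON, or aligned
text.  Currency and QALYs are shown to 2 decimal places, probabilities
to 3.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scenario import ScenarioResult
from .sensitivity import PSASampleSet


def _fmt_money(x: float) -> str:
    return f"{x:,.2f}"


def _fmt_qaly(x: float) -> str:
    return f"{x:.2f}"


def base_case_table(result: ScenarioResult, psa: PSASampleSet | None = None) -> pd.DataFrame:
    """Two-column results table mirroring the published layout."""
    spec = result.spec
    inter, comp = spec.intervention.name, spec.comparator.name
    o_i, o_c = result.outcomes[inter], result.outcomes[comp]
    inc = result.incremental

    rows: list[tuple[str, str, str]] = [
        ("Costs for PFS state", _fmt_money(o_i.cost_by_state["PFS"]), _fmt_money(o_c.cost_by_state["PFS"])),
        ("Costs for PD state", _fmt_money(o_i.cost_by_state["PD"]), _fmt_money(o_c.cost_by_state["PD"])),
        ("Total costs", _fmt_money(o_i.cost_total), _fmt_money(o_c.cost_total)),
        ("Incremental costs", _fmt_money(inc.delta_cost), ""),
        ("Effectiveness for PFS state", _fmt_qaly(o_i.qaly_by_state["PFS"]), _fmt_qaly(o_c.qaly_by_state["PFS"])),
        ("Effectiveness for PD state", _fmt_qaly(o_i.qaly_by_state["PD"]), _fmt_qaly(o_c.qaly_by_state["PD"])),
        ("Total effectiveness", _fmt_qaly(o_i.qaly_total), _fmt_qaly(o_c.qaly_total)),
        ("Incremental effectiveness", _fmt_qaly(inc.delta_qaly), ""),
        (
            "Cost/Effectiveness",
            _fmt_money(o_i.cost_total / o_i.qaly_total),
            _fmt_money(o_c.cost_total / o_c.qaly_total),
        ),
    ]
    if inc.dominance is not None:
        rows.append(("ICER ($ per QALY)", f"dominated by {inc.dominance}", ""))
    elif inc.icer is not None:
        rows.append(("ICER ($ per QALY)", _fmt_money(inc.icer), ""))
    if psa is not None:
        summary = psa.summary()
        rows.extend(
            [
                (
                    f"Monte-Carlo simulation ({psa.n}x)",
                    "",
                    "",
                ),
                ("Mean costs ($)", _fmt_money(summary.loc[inter, "mean_cost"]), _fmt_money(summary.loc[comp, "mean_cost"])),
                ("SD costs ($)", _fmt_money(summary.loc[inter, "sd_cost"]), _fmt_money(summary.loc[comp, "sd_cost"])),
                ("Mean effectiveness (QALYs)", _fmt_qaly(summary.loc[inter, "mean_qaly"]), _fmt_qaly(summary.loc[comp, "mean_qaly"])),
                ("SD effectiveness (QALYs)", _fmt_qaly(summary.loc[inter, "sd_qaly"]), _fmt_qaly(summary.loc[comp, "sd_qaly"])),
            ]
        )
    table = pd.DataFrame(rows, columns=["", inter, comp]).set_index("")
    table.index.name = None
    return table


def arm_outcome_dict(result: ScenarioResult) -> dict:
    """Full-precision JSON-friendly export of a scenario result."""
    inc = result.incremental
    return {
        "label": result.spec.label,
        "population": result.spec.population,
        "arms": {
            name: {
                "cost_total": o.cost_total,
                "qaly_total": o.qaly_total,
                "cost_by_state": o.cost_by_state,
                "qaly_by_state": o.qaly_by_state,
                "undiscounted_cost_total": o.undiscounted_cost_total,
                "undiscounted_qaly_total": o.undiscounted_qaly_total,
            }
            for name, o in result.outcomes.items()
        },
        "incremental": {
            "delta_cost": inc.delta_cost,
            "delta_qaly": inc.delta_qaly,
            "icer": inc.icer,
            "nmb": inc.nmb,
            "wtp": inc.wtp,
            "dominance": inc.dominance,
        },
    }


def render_text(table: pd.DataFrame, title: str | None = None) -> str:
    body = table.to_string()
    return f"{title}\n{'=' * len(title)}\n{body}\n" if title else body + "\n"


def write_table(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path)
    elif fmt == "json":
        path.write_text(json.dumps(json.loads(table.to_json(orient="index")), indent=2))
    elif fmt == "text":
        path.write_text(render_text(table))
    else:
        raise ValueError(f"unknown format {fmt!r}")
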