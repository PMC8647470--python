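"""Tabular and graphical outputs.

All figures are drawn from the exported CSVs rather than in-memory state, so
every plot can be regenerated from the artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .markov import IncrementalResult, StrategyResult
from .parameters import ParameterBundle, get_param, PARAM_ACCESSORS


def results_table(
    res_intervention: StrategyResult,
    res_reference: StrategyResult,
    inc: IncrementalResult,
    display: bool = False,
) -> pd.DataFrame:
    """Two-row incremental results table (strategy, cost, ΔC, QALY, ΔE, C/E, ICER).

    ``display`` rounds to publication granularity: costs and ICER to $1,
    QALYs to 0.01.
    """
    rows = [
        {
            "strategy": res_intervention.strategy,
            "cost": res_intervention.discounted_cost,
            "delta_cost": inc.delta_cost,
            "qaly": res_intervention.discounted_qaly,
            "delta_qaly": inc.delta_qaly,
            "ce_ratio": inc.ce_intervention,
            "icer": inc.icer if inc.icer_defined else None,
            "classification": inc.classification,
        },
        {
            "strategy": res_reference.strategy,
            "cost": res_reference.discounted_cost,
            "delta_cost": None,
            "qaly": res_reference.discounted_qaly,
            "delta_qaly": None,
            "ce_ratio": inc.ce_reference,
            "icer": None,
            "classification": "",
        },
    ]
    df = pd.DataFrame(rows)
    if display:
        for col in ("cost", "delta_cost", "ce_ratio", "icer"):
            df[col] = df[col].round(0)
        for col in ("qaly", "delta_qaly"):
            df[col] = df[col].round(2)
    return df


# --- run manifest -----------------------------------------------------------


def config_hash(bundle: ParameterBundle) -> str:
    """Stable hash of the full parameter set (content-addressed manifest key)."""
    doc = {}
    for name in PARAM_ACCESSORS:
        pr = get_param(bundle, name)
        doc[name] = {"base": pr.base, "low": pr.low, "high": pr.high, "role": pr.role.value}
    doc["settings"] = {
        "wtp": bundle.settings.wtp_per_qaly,
        "cycle_length_weeks": bundle.settings.cycle_length_weeks,
        "cycles_per_year": bundle.settings.cycles_per_year,
        "start_age": bundle.settings.start_age,
        "max_age": bundle.settings.max_age,
        "half_cycle_correction": bundle.settings.half_cycle_correction,
        "hosp_los_days": bundle.costs.hosp_los_days,
        "triple_drug_mix": list(bundle.costs.triple_drug_mix),
    }
    payload = yaml.safe_dump(doc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(
    out_dir: Path,
    bundle: ParameterBundle,
    command: str,
    outputs: list[str],
    seed: int | None = None,
    n_reps: int | None = None,
    defaults_used: dict | None = None,
) -> Path:
    manifest = {
        "command": command,
        "config_hash": config_hash(bundle),
        "seed": seed,
        "n_reps": n_reps,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": sorted(outputs),
        "defaults_used": defaults_used or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


# --- figures (always from CSV artifacts) ------------------------------------


def plot_ce_plane(psa_csv: Path, out_png: Path, wtp: float) -> None:
    df = pd.read_csv(psa_csv)
    df = df.drop_duplicates("replicate")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["delta_qaly"], df["delta_cost"], s=8, alpha=0.4, edgecolors="none")
    lim = max(abs(df["delta_qaly"]).max(), 1e-6) * 1.1
    xs = pd.Series([-lim, lim])
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (US$)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)


def plot_ceac(ceac_csv: Path, out_png: Path) -> None:
    df = pd.read_csv(ceac_csv)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["wtp"], df["prob_cost_effective"], marker="o", ms=3)
    ax.axhline(0.5, color="grey", ls=":", lw=1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (US$/QALY)")
    ax.set_ylabel("P(triple therapy cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)


def plot_tornado(tornado_csv: Path, out_png: Path, base_icer: float) -> None:
    df = pd.read_csv(tornado_csv).dropna(subset=["icer_at_low", "icer_at_high"])
    df = df.sort_values("spread")  # widest bar on top
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    for i, row in enumerate(df.itertuples()):
        lo, hi = sorted((row.icer_at_low, row.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, label=f"base ICER ${base_icer:,.0f}")
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("ICER (US$/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
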