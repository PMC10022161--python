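"""Optional figures: tornado, incremental-plane scatter, CEAC, BIA series.

Matplotlib is imported lazily so headless/batch runs without ``--plots``
never touch a plotting backend.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def tornado_plot(dsa: pd.DataFrame, path: str | Path) -> None:
    """Horizontal-bar tornado of ICER ranges, widest on top."""
    plt = _axes()
    rows = dsa[~dsa["negligible"]].iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    base = dsa["base_icer"].iloc[0]
    for i, (_, r) in enumerate(rows.iterrows()):
        lo, hi = sorted((r["icer_low"], r["icer_high"]))
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    ax.axvline(base, color="black", lw=1, ls="--", label=f"base ICER {base:.2f}")
    ax.set_yticks(range(len(rows)), rows["parameter"])
    ax.set_xlabel("ICER (USD 2020 per DALY averted)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def psa_scatter(samples: pd.DataFrame, path: str | Path, label: str = "") -> None:
    """Incremental plane: cost (USD millions) vs DALYs averted (thousands)."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        samples["dalys_averted"] / 1e3,
        samples["incremental_cost"] / 1e6,
        s=8,
        alpha=0.4,
    )
    ax.set_xlabel("incremental DALYs averted (thousands)")
    ax.set_ylabel("incremental cost (USD millions, 2020)")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Acceptability curves, one line per provider arm."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(
            curve["wtp_usd_2020_per_daly"],
            curve["probability_cost_effective"],
            label=label,
        )
    ax.set_xlabel("willingness to pay (USD 2020 per DALY averted)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bia_plot(trajectory: pd.DataFrame, path: str | Path, label: str = "") -> None:
    """Annual cost (USD millions) and backlog (thousands) over the horizon."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(
        trajectory["year"],
        trajectory["annual_cost_usd_2020"] / 1e6,
        marker="o",
        label="annual cost (USD millions)",
    )
    ax2 = ax.twinx()
    ax2.plot(
        trajectory["year"],
        trajectory["backlog"] / 1e3,
        marker="s",
        color="#a85448",
        label="untreated backlog (thousands)",
    )
    ax.set_xlabel("year")
    ax.set_ylabel("annual cost (USD millions, 2020)")
    ax2.set_ylabel("untreated backlog (thousands)")
    if label:
        ax.set_title(label)
    lines = ax.get_lines() + ax2.get_lines()
    ax.legend(lines, [l.get_label() for l in lines], loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
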