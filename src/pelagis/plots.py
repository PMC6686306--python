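"""Basic diagnostic figures for pipeline outputs (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_STATUS_COLORS = {"successful": "tab:blue", "failed": "tab:red"}


def plot_trend_curves(curves, path) -> None:
    """Fitted group trends (one panel per activity x period) with 95% bands."""
    activities = sorted(curves["activity"].unique())
    periods = sorted(curves["period"].unique())
    fig, axes = plt.subplots(
        len(periods), len(activities), figsize=(4 * len(activities), 3 * len(periods)), squeeze=False
    )
    for i, period in enumerate(periods):
        for j, act in enumerate(activities):
            ax = axes[i][j]
            sub = curves[(curves["activity"] == act) & (curves["period"] == period)]
            for status, grp in sub.groupby("status"):
                color = _STATUS_COLORS.get(status, "tab:gray")
                ax.plot(grp["days_since_laying"], grp["estimate"], color=color, label=status)
                if {"lo", "hi"} <= set(grp.columns):
                    ax.fill_between(grp["days_since_laying"], grp["lo"], grp["hi"], color=color, alpha=0.2)
            ax.set_title(f"{act} / {period}", fontsize=9)
            ax.set_ylim(0, 1)
            ax.set_xlabel("days since laying")
            ax.set_ylabel("proportion of at-sea time")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_moon_curves(moon_curves, path) -> None:
    """Cyclic lunar partial effects on the logit scale."""
    activities = sorted(moon_curves["activity"].unique())
    periods = sorted(moon_curves["period"].unique())
    fig, axes = plt.subplots(
        len(periods), len(activities), figsize=(4 * len(activities), 3 * len(periods)), squeeze=False
    )
    for i, period in enumerate(periods):
        for j, act in enumerate(activities):
            ax = axes[i][j]
            sub = moon_curves[(moon_curves["activity"] == act) & (moon_curves["period"] == period)]
            ax.plot(sub["moon_age"], sub["effect"], color="k")
            if {"lo", "hi"} <= set(sub.columns):
                ax.fill_between(sub["moon_age"], sub["lo"], sub["hi"], color="k", alpha=0.15)
            ax.axvline(29.53 / 2, ls=":", color="gray")  # full moon
            ax.set_title(f"{act} / {period}", fontsize=9)
            ax.set_xlabel("lunar age (days; 0 = new moon)")
            ax.set_ylabel("logit-scale effect")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dry_events(events, records, path, land_threshold_hr: float = 16.0) -> None:
    """Raw dry-event durations over time, coloured by breeding status.

    The horizontal line marks the on-land threshold; for a breeding cohort the
    long dry events should vanish after failure/fledging and reappear at the
    end of the nonbreeding season.
    """
    status = {r.individual_id: r.status for r in records}
    dry = events[events["label"].isin(["flight", "land"])]
    fig, ax = plt.subplots(figsize=(9, 4))
    for st, color in _STATUS_COLORS.items():
        sub = dry[dry["individual_id"].map(status) == st]
        ax.scatter(sub["start"], sub["duration_min"] / 60.0, s=3, alpha=0.4, color=color, label=st)
    ax.axhline(land_threshold_hr, ls="--", color="k")
    ax.set_yscale("log")
    ax.set_ylabel("dry event duration (hr)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
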