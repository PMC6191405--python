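"""Figure helpers for the study reports.

Colour conventions follow the field's habit for multicolour K-edge imaging:
iodine purple, gadolinium green, gold yellow.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

AGENT_COLORS = {
    "iodine": "#7b2d8b",
    "gadolinium": "#2e8b57",
    "gold": "#c8a415",
    "water": "#2060b0",
}


def agent_colormap(agent: str):
    return LinearSegmentedColormap.from_list(
        agent, ["black", AGENT_COLORS.get(agent, "white")]
    )


def regression_panel(report: dict, path=None):
    """Measured-vs-prepared scatter with the OLS fit, one axis per agent."""
    agents = list(report["per_agent"])
    fig, axes = plt.subplots(1, len(agents), figsize=(4.2 * len(agents), 3.6),
                             squeeze=False)
    for ax, agent in zip(axes[0], agents):
        blk = report["per_agent"][agent]
        x = np.asarray(blk["prepared_mg_per_ml"])
        y = np.asarray(blk["measured_mg_per_ml"])
        sd = np.asarray(blk["measured_sd"])
        r = blk["regression"]
        c = AGENT_COLORS[agent]
        ax.errorbar(x, y, yerr=sd, fmt="o", color=c, ms=4, lw=1, capsize=2)
        xx = np.linspace(0, max(x.max(), 1e-9), 2)
        ax.plot(xx, r["slope"] * xx + r["offset"], "-", color=c, lw=1)
        ax.plot(xx, xx, ":", color="grey", lw=1)
        ax.set_xlabel("prepared (mg/mL)")
        ax.set_ylabel("measured (mg/mL)")
        ax.set_title(
            f"{agent}: y={r['slope']:.2f}x{r['offset']:+.2f}, "
            f"$R^2$={r['r_squared']:.3f}"
        )
    fig.suptitle(report["study_id"])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def bland_altman_panel(report: dict, path=None):
    """Difference-vs-mean agreement plot per agent."""
    agents = list(report["per_agent"])
    fig, axes = plt.subplots(1, len(agents), figsize=(4.2 * len(agents), 3.6),
                             squeeze=False)
    for ax, agent in zip(axes[0], agents):
        blk = report["per_agent"][agent]
        x = np.asarray(blk["prepared_mg_per_ml"])
        y = np.asarray(blk["measured_mg_per_ml"])
        ba = blk["bland_altman"]
        c = AGENT_COLORS[agent]
        ax.scatter((x + y) / 2, y - x, color=c, s=18)
        for val, style in ((ba["bias"], "-"), (ba["loa_low"], "--"),
                           (ba["loa_high"], "--")):
            ax.axhline(val, color="grey", ls=style, lw=1)
        ax.set_xlabel("mean of prepared and measured (mg/mL)")
        ax.set_ylabel("measured - prepared (mg/mL)")
        ax.set_title(f"{agent}: bias {ba['bias']:+.2f} mg/mL")
    fig.suptitle(f"{report['study_id']} agreement")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def cnr_bars(report: dict, path=None):
    """CNR per tube and agent, with the per-concentration slope in the label."""
    agents = list(report["per_agent"])
    fig, ax = plt.subplots(figsize=(7, 3.6))
    width = 0.8 / len(agents)
    tubes = np.arange(1, 12)
    for j, agent in enumerate(agents):
        blk = report["per_agent"][agent]
        ax.bar(
            tubes + (j - (len(agents) - 1) / 2) * width,
            blk["cnr"],
            width=width,
            color=AGENT_COLORS[agent],
            label=f"{agent} (slope {blk['cnr_slope']:.2f} /mg/mL)",
        )
    ax.set_xlabel("tube")
    ax.set_ylabel("CNR")
    ax.set_title(f"{report['study_id']} contrast-to-noise")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def image_montage(conventional, images: dict, path=None):
    """Conventional (grey, HU) plus each material map in its agent colour."""
    names = ["conventional"] + list(images)
    fig, axes = plt.subplots(1, len(names), figsize=(3.0 * len(names), 3.2))
    for ax, name in zip(np.atleast_1d(axes), names):
        if name == "conventional":
            im = ax.imshow(conventional.values, cmap="gray", vmin=-200, vmax=500)
            label = "HU"
        else:
            img = images[name]
            vmax = 1100.0 if name == "water" else max(
                np.percentile(img.values, 99.9), 1.0
            )
            im = ax.imshow(img.values, cmap=agent_colormap(name), vmin=0, vmax=vmax)
            label = "mg/mL"
        ax.set_title(name, fontsize=9)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046, label=label)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
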