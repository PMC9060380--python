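"""Figures: per-otolith transects and per-type cohort overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import constants as C


def plot_profile(profile, smoothed, path: str | Path,
                 title: str | None = None) -> None:
    """One otolith: raw ratios, spline fit with 95% band, GMV line, annuli."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.fill_between(smoothed.positions_um, smoothed.lower, smoothed.upper,
                    color="0.8", label="95% band")
    ax.plot(profile.positions_um, profile.ratio, ".", ms=2, color="k",
            alpha=0.4, label="raw")
    ax.plot(smoothed.positions_um, smoothed.fit, color="tab:red", lw=1.5,
            label="fit")
    ax.axhline(C.GMV, color="tab:blue", lw=1, label="GMV")
    for a in profile.annuli_um[:4]:
        ax.axvline(a, color="k", ls="--", lw=0.6)
    ax.set_xlabel("distance from core (µm)")
    ax.set_ylabel("$^{87}$Sr/$^{86}$Sr")
    ax.set_title(title or profile.otolith_id)
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_cohort(smootheds: dict[int, list], path: str | Path) -> None:
    """Per-type overlay of fitted transects (types 1–6 in panels)."""
    fig, axes = plt.subplots(2, 3, figsize=(11, 5.5), sharey=True)
    for type_id, ax in zip(range(1, 7), axes.ravel()):
        for sm in smootheds.get(type_id, []):
            ax.plot(sm.positions_um, sm.fit, lw=0.8, alpha=0.7)
        ax.axhline(C.GMV, color="tab:blue", lw=1)
        ax.set_title(f"type {type_id}", fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("distance from core (µm)")
    for ax in axes[:, 0]:
        ax.set_ylabel("$^{87}$Sr/$^{86}$Sr")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
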