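"""Presentation charts (bar plots of DP profiles and subsite affinities).

Purely cosmetic output; nothing here is part of the numerical contract.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .compare import ComparisonReport
from .subsites import SubsiteProfile


def plot_dp_profiles(report: ComparisonReport, path: str) -> None:
    """Grouped bars of (kcat/KM)_n / (kcat/KM)_2 per enzyme."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(report.specificity_profiles)
    width = 0.8 / len(labels)
    for j, label in enumerate(labels):
        prof = report.specificity_profiles[label]
        dps = sorted(prof.ratios)
        ax.bar(
            [dp + (j - (len(labels) - 1) / 2) * width for dp in dps],
            [prof.ratios[dp] for dp in dps],
            width=width,
            label=label,
        )
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("substrate DP")
    ax.set_ylabel(r"$(k_{cat}/K_M)_n\,/\,(k_{cat}/K_M)_2$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_subsite_affinities(profiles: dict[str, SubsiteProfile], path: str) -> None:
    """Bars of subsite affinities: the -1/+1 sum, then +2, +3, ..."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(profiles)
    all_plus = sorted({i for p in profiles.values() for i in p.plus_affinities})
    positions = ["-1/+1"] + [f"+{i}" for i in all_plus]
    width = 0.8 / len(labels)
    for j, label in enumerate(labels):
        p = profiles[label]
        heights = [p.active_center_affinity] + [
            p.plus_affinities.get(i, 0.0) for i in all_plus
        ]
        ax.bar(
            [k + (j - (len(labels) - 1) / 2) * width for k in range(len(positions))],
            heights,
            width=width,
            label=label,
        )
    ax.set_xticks(range(len(positions)), positions)
    ax.set_xlabel("subsite")
    ax.set_ylabel("affinity (kcal/mol)")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
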