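"""Divergence-binned repeat landscapes.

A repeat landscape stacks, per repeat group, the genome fraction occupied
by copies in each 1%-divergence bin.  Because divergence from the family
consensus proxies insertion age, the landscape reads as activity through
time: mass near K = 0 marks a recent expansion, mass at high K old decayed
families.  A secondary axis converts bin edges to million years through
the neutral clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .divergence import AgeModel, age_mya


@dataclass
class LandscapeBin:
    """One (group, divergence-bin) cell of a repeat landscape."""

    group: str
    bin_lo: int  # bin spans [bin_lo, bin_lo + 1) percent divergence
    bp: int
    pct_genome: float
    age_mya_lo: float


def build_landscape(
    items,
    genome_len: int,
    k_max: int = 50,
    age_model: AgeModel | None = None,
) -> list:
    """Accrue ``(group, K, length_bp)`` items into integer divergence bins.

    Each item's length lands in bin ``floor(K)``; bins ``0..k_max`` are
    emitted per group including empty ones, so bin totals conserve the
    group's annotated bp exactly.  Items beyond ``k_max`` accrue to the
    last bin rather than vanish (conservation before tail resolution).
    Raw landscapes take per-fragment K, final ones per-copy K — the caller
    chooses what to feed.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    model = age_model or AgeModel()
    totals: dict = {}
    for group, K, length in items:
        if length < 0:
            raise ValueError("negative length")
        if K < 0:
            raise ValueError("negative divergence")
        b = min(int(K), k_max)
        key = (group, b)
        totals[key] = totals.get(key, 0) + length
    groups = sorted({g for g, _ in totals})
    bins = []
    for group in groups:
        for b in range(k_max + 1):
            bp = totals.get((group, b), 0)
            bins.append(
                LandscapeBin(
                    group=group,
                    bin_lo=b,
                    bp=bp,
                    pct_genome=100.0 * bp / genome_len,
                    age_mya_lo=age_mya(float(b), model),
                )
            )
    return bins


def landscape_frame(bins) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": b.group,
                "bin_lo": b.bin_lo,
                "bp": b.bp,
                "pct_genome": b.pct_genome,
                "age_mya_lo": b.age_mya_lo,
            }
            for b in bins
        ]
    )


def recent_burst_stat(bins, K_max: float) -> float:
    """Percent of one group's coverage lying in bins at or below ``K_max``.

    Quantifies statements like "elevated coverage at substitution levels
    <= 2".  ``bins`` must come from a single group; returns 0 for an empty
    group.
    """
    groups = {b.group for b in bins}
    if len(groups) > 1:
        raise ValueError("bins from more than one group")
    total = sum(b.bp for b in bins)
    if total == 0:
        return 0.0
    low = sum(b.bp for b in bins if b.bin_lo <= K_max)
    return 100.0 * low / total


def plot_landscape(bins, path, title: str = "Repeat landscape") -> None:
    """Stacked-bar landscape (percent of genome vs divergence bin).

    Secondary top axis shows the age in million years at the bin edges.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = landscape_frame(bins)
    pivot = df.pivot_table(
        index="bin_lo", columns="group", values="pct_genome", fill_value=0.0
    )
    fig, ax = plt.subplots(figsize=(9, 4.5))
    bottom = None
    for group in pivot.columns:
        vals = pivot[group].to_numpy()
        ax.bar(pivot.index, vals, bottom=bottom, width=0.9, label=group)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("Kimura-2 substitution level (CpG adjusted, %)")
    ax.set_ylabel("% of genome")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    mu = AgeModel().mu
    top = ax.secondary_xaxis(
        "top", functions=(lambda k: k / (2 * mu * 1e8), lambda t: t * 2 * mu * 1e8)
    )
    top.set_xlabel("age (My)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
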