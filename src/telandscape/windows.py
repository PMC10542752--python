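"""Fixed-width genomic windows and the per-window feature table.

TE abundance is quantified as percent of window bp covered (unions of
fragment intervals, so a fragmented old element is not counted once per
fragment), alongside gene coverage, CpG-island coverage, GC content and a
distance-weighted mean recombination rate, all in non-overlapping windows
(default 200 kb).  Trailing partial windows are kept but flagged; rank
statistics downstream exclude them by default because their unequal
support would bias the correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .divergence import AgeModel
from .io_formats import CLASS_LABELS, IntervalTrack

DEFAULT_WINDOW = 200_000


def make_windows(chrom_sizes: dict, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Tile every chromosome with non-overlapping ``w``-bp windows.

    ``chrom_sizes`` maps chrom -> {"length", "is_autosome"}.  The trailing
    partial window is kept with ``is_partial=True``.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, meta in chrom_sizes.items():
        length = meta["length"]
        for start in range(0, length, w):
            end = min(start + w, length)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "is_partial": end - start < w,
                    "is_autosome": bool(meta.get("is_autosome", True)),
                }
            )
    return pd.DataFrame(rows)


def _merged(intervals) -> list:
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def coverage_pct(window_start: int, window_end: int, intervals) -> float:
    """Percent of a window covered by the union of (clipped) intervals."""
    width = window_end - window_start
    covered = 0
    for s, e in _merged(intervals):
        lo = max(s, window_start)
        hi = min(e, window_end)
        if hi > lo:
            covered += hi - lo
    return 100.0 * covered / width


def _coverage_column(windows: pd.DataFrame, by_chrom: dict) -> np.ndarray:
    """Vectorised union coverage (%) per window from per-chrom intervals."""
    out = np.zeros(len(windows))
    for chrom, sub in windows.groupby("chrom", sort=False):
        merged = _merged(by_chrom.get(chrom, []))
        if not merged:
            continue
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        for i, row in zip(sub.index, sub.itertuples()):
            lo = np.searchsorted(ends, row.start, side="right")
            hi = np.searchsorted(starts, row.end, side="left")
            if hi <= lo:
                continue
            covered = cum[hi] - cum[lo]
            covered -= max(0, row.start - starts[lo])
            covered -= max(0, ends[hi - 1] - row.end)
            out[i] = 100.0 * covered / (row.end - row.start)
    return out


def gc_pct(sequence: str) -> float:
    """GC percent of the non-N bases of a window slice (NaN if none)."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def rec_rate_window(window_start: int, window_end: int, tracks) -> float:
    """Distance-weighted mean rate over map intervals hitting the window.

    Each interval contributes its rate weighted by its overlap bp; windows
    with no overlapping map interval get NaN.
    """
    wsum = 0.0
    bp = 0
    for t in tracks:
        lo = max(t.start, window_start)
        hi = min(t.end, window_end)
        if hi > lo:
            wsum += t.value * (hi - lo)
            bp += hi - lo
    if bp == 0:
        return float("nan")
    return wsum / bp


def feature_table(
    windows: pd.DataFrame,
    copies,
    genes,
    cpg,
    recmap,
    sequences: dict | None = None,
    age_model: AgeModel | None = None,
) -> pd.DataFrame:
    """Fill every window metric; one row per window.

    ``copies`` carry ``age_class`` (recent/ancient, disjoint); coverage is
    computed from fragment unions per category.  ``genes``/``cpg``/
    ``recmap`` are :class:`IntervalTrack` lists, ``sequences`` maps chrom
    to its full string (GC left NaN when absent).
    """
    table = windows.copy().reset_index(drop=True)
    known = set(table["chrom"])

    def group_tracks(tracks, as_tuples=True):
        by = {}
        for t in tracks:
            if t.chrom not in known:
                raise ValueError(f"unknown chromosome in track: {t.chrom!r}")
            by.setdefault(t.chrom, []).append((t.start, t.end) if as_tuples else t)
        return by

    def frag_intervals(selected):
        by = {}
        for c in selected:
            if c.chrom not in known:
                raise ValueError(f"copy on unknown chromosome {c.chrom!r}")
            by.setdefault(c.chrom, []).extend(c.fragment_intervals)
        return by

    copies = list(copies)
    table["te_cov_all"] = _coverage_column(table, frag_intervals(copies))
    for label in CLASS_LABELS[:4]:
        table[f"te_cov_{label}"] = _coverage_column(
            table, frag_intervals([c for c in copies if c.class_label == label])
        )
    for age in ("recent", "ancient"):
        table[f"te_cov_{age}"] = _coverage_column(
            table, frag_intervals([c for c in copies if c.age_class == age])
        )
    table["gene_cov"] = _coverage_column(table, group_tracks(genes))
    table["cpg_cov"] = _coverage_column(table, group_tracks(cpg))

    gc = np.full(len(table), np.nan)
    if sequences is not None:
        for i, row in enumerate(table.itertuples()):
            seq = sequences.get(row.chrom)
            if seq is not None:
                gc[i] = gc_pct(seq[row.start : row.end])
    table["gc"] = gc

    rec_by = group_tracks(recmap, as_tuples=False)
    rates = np.full(len(table), np.nan)
    for i, row in enumerate(table.itertuples()):
        rates[i] = rec_rate_window(row.start, row.end, rec_by.get(row.chrom, []))
    table["rec_rate"] = rates
    return table
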