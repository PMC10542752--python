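"""Defragmentation of RepeatMasker hits into TE copies and 80-80-80 filtering.

RepeatMasker reports interrupted elements as several fragments: a nested
insertion, an internal deletion or a low-complexity stretch splits one
biological copy into consecutive hits.  This module reassembles copies with
a deterministic greedy left-to-right merge, fuses LTR - internal - LTR
structures into full retrotransposon copies, and applies the classic
80-80-80 retention rule (>= 80 bp, >= 80% identity, >= 80% of the consensus
represented) to produce a final curated annotation.

Two hits join the same copy when either

(a) they share RepeatMasker's per-element run ID (the tool's own statement
    that they are one interrupted element), or
(b) they have the same family, chromosome and strand, their genomic gap is
    at most ``max_gap``, and their consensus coordinates are collinear for
    the strand (the next fragment resumes no more than
    ``cons_overlap_tol`` bp before where the previous one stopped).

The identity leg of 80-80-80 is applied as K < 20 percent divergence — the
divergence value the rule's 80% identity corresponds to in this pipeline —
and the "80% of the reference" leg as consensus-span fraction >= 0.80.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .divergence import copy_kimura
from .io_formats import RepeatHit

logger = logging.getLogger("telandscape")


@dataclass
class MergeParams:
    """Thresholds for merging and for the 80-80-80 filter.

    ``max_gap`` is the largest genomic gap (bp) bridged between fragments
    of one copy; ``cons_overlap_tol`` the consensus-coordinate backtrack
    tolerated when checking collinearity.  ``min_len``, ``min_identity_K``
    and ``min_cons_span`` are the three 80s (length, identity as a
    divergence ceiling, consensus span).  ``strict=False`` drops the
    consensus-span criterion.
    """

    max_gap: int = 2500
    cons_overlap_tol: int = 15
    min_len: int = 80
    min_identity_K: float = 20.0
    min_cons_span: float = 0.80
    strict: bool = True

    def __post_init__(self) -> None:
        if min(self.max_gap, self.cons_overlap_tol, self.min_len) < 0:
            raise ValueError("negative threshold")
        if self.min_identity_K < 0 or not 0 <= self.min_cons_span <= 1:
            raise ValueError("bad filter threshold")


@dataclass
class TECopy:
    """A defragmented TE copy.

    ``start``/``end`` is the 0-based half-open genomic envelope including
    inter-fragment gaps; ``merged_len`` sums only the fragments' own bp so
    nested foreign elements are not counted.  ``K`` is the length-weighted
    mean fragment divergence and ``cons_span_frac`` the fraction of the
    consensus covered by the union of fragment consensus intervals.
    """

    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    class_label: str
    fragments: list = field(default_factory=list)
    merged_len: int = 0
    K: float = 0.0
    cons_span_frac: float = 0.0
    age_class: str = "unset"
    score: int = 0

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("copy has no fragments")
        if self.merged_len > self.end - self.start:
            raise ValueError("merged_len exceeds envelope")
        if not 0 <= self.cons_span_frac <= 1 + 1e-9:
            raise ValueError("cons_span_frac outside [0, 1]")

    @property
    def fragment_intervals(self) -> list:
        """Genomic intervals of the fragments (0-based half-open)."""
        return [(f.start, f.end) for f in self.fragments]


def _union_length(intervals) -> int:
    total = 0
    prev_start = prev_end = None
    for s, e in sorted(intervals):
        if prev_end is None or s > prev_end:
            if prev_end is not None:
                total += prev_end - prev_start
            prev_start, prev_end = s, e
        else:
            prev_end = max(prev_end, e)
    if prev_end is not None:
        total += prev_end - prev_start
    return total


def _collinear(prev: RepeatHit, nxt: RepeatHit, tol: int) -> bool:
    if prev.strand == "+":
        return nxt.cons_start >= prev.cons_end - tol
    return nxt.cons_end <= prev.cons_start + tol


def _build_copy(
    copy_id: str,
    frags: list,
    fragment_K: dict | None,
    cons_len_total: int | None = None,
) -> TECopy:
    first = frags[0]
    start = min(f.start for f in frags)
    end = max(f.end for f in frags)
    merged_len = _union_length((f.start, f.end) for f in frags)
    weights = []
    for f in frags:
        K = fragment_K.get(f.key, f.pct_div) if fragment_K else f.pct_div
        weights.append((K, f.length))
    cons_len = cons_len_total or max(f.consensus_length for f in frags)
    covered = _union_length((f.cons_start - 1, f.cons_end) for f in frags)
    return TECopy(
        copy_id=copy_id,
        chrom=first.chrom,
        start=start,
        end=end,
        strand=first.strand,
        family_name=first.family_name,
        class_label=first.class_label,
        fragments=list(frags),
        merged_len=merged_len,
        K=copy_kimura(weights),
        cons_span_frac=min(1.0, covered / cons_len),
        score=max(f.score for f in frags),
    )


def merge_fragments(
    hits, params: MergeParams | None = None, fragment_K: dict | None = None
) -> list:
    """Greedy left-to-right merge of sorted hits into TE copies.

    ``fragment_K`` optionally maps ``hit.key`` to an alignment-derived
    divergence; hits without an entry fall back to the table's pct_div.
    Every hit lands in exactly one copy.  When several open copies could
    absorb a fragment, the one whose last fragment ends nearest wins
    (run-ID matches always beat proximity).
    """
    params = params or MergeParams()
    hits = list(hits)
    for a, b in zip(hits, hits[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("hits not sorted by (chrom, start)")

    groups: list = []  # list of fragment lists
    open_by_run: dict = {}  # (chrom, run_id) -> group index
    open_recent: list = []  # group indices eligible for rule (b)

    for hit in hits:
        run_key = (hit.chrom, hit.run_id)
        gi = open_by_run.get(run_key)
        if gi is None:
            best = None
            best_dist = None
            for idx in open_recent:
                prev = groups[idx][-1]
                if prev.chrom != hit.chrom:
                    continue
                gap = hit.start - prev.end
                if gap > params.max_gap:
                    continue
                if (
                    prev.family_name == hit.family_name
                    and prev.strand == hit.strand
                    and _collinear(prev, hit, params.cons_overlap_tol)
                ):
                    dist = abs(gap)
                    if best is None or dist < best_dist:
                        best, best_dist = idx, dist
            gi = best
        if gi is not None:
            prev = groups[gi][-1]
            if (
                prev.start == hit.start
                and prev.end == hit.end
                and prev.family_name == hit.family_name
            ):
                logger.warning(
                    "duplicate hit %s:%d-%d (%s) merged",
                    hit.chrom,
                    hit.start,
                    hit.end,
                    hit.family_name,
                )
                continue
            groups[gi].append(hit)
        else:
            gi = len(groups)
            groups.append([hit])
        open_by_run[(hit.chrom, hit.run_id)] = gi
        if gi not in open_recent:
            open_recent.append(gi)
        # prune rule-(b) candidates now unreachable
        open_recent = [
            idx
            for idx in open_recent
            if groups[idx][-1].chrom == hit.chrom
            and groups[idx][-1].end >= hit.start - params.max_gap
        ]

    copies = [
        _build_copy(f"copy_{i:06d}", frags, fragment_K)
        for i, frags in enumerate(groups)
    ]
    copies.sort(key=lambda c: (c.chrom, c.start, c.family_name))
    return copies


def assemble_ltr(copies, library: dict, params: MergeParams | None = None) -> list:
    """Fuse adjacent LTR - internal - LTR copies into full-element copies.

    ``library`` maps consensus names to :class:`ConsensusRecord`; names
    ``X_LTR`` / ``X_I`` share the stem ``X``.  A fusion requires the same
    stem and strand on all three parts and gaps of at most ``max_gap``.
    Ambiguity is resolved leftmost-first; unpaired LTRs stay solo.
    """
    params = params or MergeParams()
    ordered = sorted(copies, key=lambda c: (c.chrom, c.start, c.family_name))
    roles = {name: rec.ltr_role for name, rec in library.items()}
    stems = {name: rec.stem for name, rec in library.items()}
    used = set()
    fused = []
    for j, internal in enumerate(ordered):
        if roles.get(internal.family_name) != "internal_part":
            continue
        stem = stems[internal.family_name]
        left = right = None
        for i in range(j - 1, -1, -1):
            c = ordered[i]
            if i in used or c.chrom != internal.chrom:
                continue
            if (
                roles.get(c.family_name) == "ltr_part"
                and stems[c.family_name] == stem
                and c.strand == internal.strand
                and 0 <= internal.start - c.end <= params.max_gap
            ):
                left = i
                break
        for i in range(j + 1, len(ordered)):
            c = ordered[i]
            if i in used or c.chrom != internal.chrom:
                continue
            if c.start - internal.end > params.max_gap:
                break
            if (
                roles.get(c.family_name) == "ltr_part"
                and stems[c.family_name] == stem
                and c.strand == internal.strand
                and c.start >= internal.end
            ):
                right = i
                break
        if left is not None and right is not None and j not in used:
            used.update((left, j, right))
            fused.append((left, j, right))

    out = []
    consumed = set()
    for left, j, right in fused:
        parts = [ordered[left], ordered[j], ordered[right]]
        consumed.update((left, j, right))
        frags = [f for p in parts for f in p.fragments]
        ltr_name = ordered[left].family_name
        i_name = ordered[j].family_name
        total_cons = 2 * library[ltr_name].length + library[i_name].length
        covered = sum(
            round(p.cons_span_frac * library[p.family_name].length) for p in parts
        )
        copy = TECopy(
            copy_id=ordered[left].copy_id,
            chrom=parts[0].chrom,
            start=parts[0].start,
            end=parts[2].end,
            strand=parts[0].strand,
            family_name=stems[i_name],
            class_label=ordered[j].class_label,
            fragments=frags,
            merged_len=_union_length((f.start, f.end) for f in frags),
            K=copy_kimura([(p.K, p.merged_len) for p in parts]),
            cons_span_frac=min(1.0, covered / total_cons) if total_cons else 0.0,
            score=max(p.score for p in parts),
        )
        out.append(copy)
    for i, c in enumerate(ordered):
        if i not in consumed:
            out.append(c)
    out.sort(key=lambda c: (c.chrom, c.start, c.family_name))
    return out


def filter_808080(copies, params: MergeParams | None = None) -> list:
    """Apply the 80-80-80 retention rule and drop Unclassified copies.

    A copy is retained iff ``merged_len >= min_len`` and
    ``K < min_identity_K`` and (in strict mode) ``cons_span_frac >=
    min_cons_span``.  Counts and coverage can only shrink.
    """
    params = params or MergeParams()
    kept = []
    for c in copies:
        if c.class_label == "Unclassified":
            continue
        if c.merged_len < params.min_len:
            continue
        if c.K >= params.min_identity_K:
            continue
        if params.strict and c.cons_span_frac < params.min_cons_span:
            continue
        kept.append(c)
    return kept


def annotation_summary(copies, genome_len: int) -> pd.DataFrame:
    """Per-class copy counts, summed bp and percent of genome.

    Mirrors the usual annotation-summary table: one row per class label
    plus a ``Total`` row; bp is the fragment-union ``merged_len`` so nested
    foreign elements are not double counted.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    classes = ("SINE", "LINE", "LTR", "DNA", "Unclassified")
    rows = []
    for label in classes:
        sub = [c for c in copies if c.class_label == label]
        bp = sum(c.merged_len for c in sub)
        rows.append(
            {
                "class": label,
                "copies": len(sub),
                "total_bp": bp,
                "pct_genome": 100.0 * bp / genome_len,
            }
        )
    total_bp = sum(r["total_bp"] for r in rows)
    rows.append(
        {
            "class": "Total",
            "copies": sum(r["copies"] for r in rows),
            "total_bp": total_bp,
            "pct_genome": 100.0 * total_bp / genome_len,
        }
    )
    return pd.DataFrame(rows)
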