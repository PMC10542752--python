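"""CpG-adjusted Kimura 2-parameter divergence and insertion-age dating.

A TE copy diverges from its family consensus by neutral substitution after
insertion, so the K2P distance between copy and consensus proxies insertion
age.  Transitions in CpG context are dominated by spontaneous deamination
of methylated cytosine and run roughly an order of magnitude faster than
elsewhere; the CpG adjustment down-weights them so that the distance
reflects the genome-wide clock:

* a transition at a CpG-context column counts 1/10 of a transition;
* when both bases of one consensus CpG dinucleotide carry transitions the
  pair counts as exactly one transition in total;
* transversions are never reweighted.

With transition proportion P and transversion proportion Q the distance is

    K = 100 * ( -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) )   [percent]

and converts to time through T = (K/100) / (2 mu), the factor 2 because
substitutions accrue on the copy while the consensus approximates the
ancestral state sampled from the same clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import AlignmentBlock

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class SubstitutionCounts:
    """Substitution tallies for one alignment.

    ``ts_adj`` is the CpG-adjusted transition count (possibly fractional);
    ``P`` and ``Q`` are the adjusted transition and raw transversion
    proportions that feed :func:`kimura2`.
    """

    n_sites: int
    ts_raw: int
    tv_raw: int
    ts_adj: float

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("empty alignment")
        if self.ts_adj > self.ts_raw + 1e-9:
            raise ValueError("adjusted transitions exceed raw transitions")

    @property
    def P(self) -> float:
        return self.ts_adj / self.n_sites

    @property
    def Q(self) -> float:
        return self.tv_raw / self.n_sites


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def count_substitutions(
    block: AlignmentBlock, cpg_adjusted: bool = True
) -> SubstitutionCounts:
    """Classify alignment columns and tally (CpG-adjusted) substitutions.

    Columns with a gap or non-ACGT symbol in either sequence are excluded
    from ``n_sites``.  With ``cpg_adjusted=False`` the raw transition count
    is used and ``ts_adj == ts_raw``.
    """
    q = block.query_seq.upper()
    c = block.cons_seq.upper()
    usable = []
    for i in range(len(q)):
        if q[i] in _VALID and c[i] in _VALID:
            usable.append(i)
    if not usable:
        raise ValueError("empty alignment")

    is_ts = {}
    tv_raw = 0
    for i in usable:
        if q[i] == c[i]:
            is_ts[i] = False
        elif _is_transition(q[i], c[i]):
            is_ts[i] = True
        else:
            is_ts[i] = False
            tv_raw += 1
    ts_raw = sum(is_ts.values())

    if not cpg_adjusted:
        return SubstitutionCounts(
            n_sites=len(usable), ts_raw=ts_raw, tv_raw=tv_raw, ts_adj=float(ts_raw)
        )

    # CpG dinucleotide pairs: adjacent non-gap consensus columns reading CG.
    # CG occurrences cannot overlap, so every column is in at most one pair.
    nongap = [i for i in range(len(c)) if c[i] != "-"]
    in_pair = set()
    ts_adj = 0.0
    for a, b in zip(nongap, nongap[1:]):
        if c[a] == "C" and c[b] == "G":
            in_pair.update((a, b))
            ts_a = is_ts.get(a, False)
            ts_b = is_ts.get(b, False)
            if ts_a and ts_b:
                ts_adj += 1.0
            elif ts_a or ts_b:
                ts_adj += 0.1
    for i in usable:
        if is_ts[i] and i not in in_pair:
            # lone CpG-context columns (pair partner outside the block)
            ts_adj += 0.1 if block.cpg_mask[i] else 1.0
    return SubstitutionCounts(
        n_sites=len(usable), ts_raw=ts_raw, tv_raw=tv_raw, ts_adj=ts_adj
    )


def kimura2(counts: SubstitutionCounts) -> float:
    """Kimura 2-parameter distance in percent from substitution counts.

    Raises on saturation (either log argument non-positive).
    """
    return kimura2_from_pq(counts.P, counts.Q)


def kimura2_from_pq(P: float, Q: float) -> float:
    """K2P percent distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturated divergence")
    return 100.0 * (-0.5 * math.log(w1) - 0.25 * math.log(w2))


def copy_kimura(fragments) -> float:
    """Length-weighted mean divergence of a copy's fragments.

    ``fragments`` is a sequence of ``(K_i, aligned_len_i)`` pairs.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("copy has no fragments")
    wsum = 0.0
    total = 0
    for K, length in fragments:
        if length <= 0:
            raise ValueError("non-positive fragment length")
        wsum += K * length
        total += length
    return wsum / total


@dataclass
class AgeModel:
    """Neutral clock for converting divergence to insertion age.

    ``mu`` is the per-site per-year substitution rate (default the
    collared-flycatcher estimate 2.3e-9); ``recent_threshold_K`` is the
    percent-divergence boundary between recent and ancient insertions
    (default 7, inclusive, roughly the split from the sister species).
    """

    mu: float = 2.3e-9
    recent_threshold_K: float = 7.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not 0 <= self.recent_threshold_K <= 100:
            raise ValueError("recent_threshold_K outside [0, 100]")


def age_mya(K: float, model: AgeModel | None = None) -> float:
    """Convert percent divergence to insertion age in million years."""
    if K < 0:
        raise ValueError("negative divergence")
    model = model or AgeModel()
    return (K / 100.0) / (2.0 * model.mu) / 1e6


def classify_age(K: float, model: AgeModel | None = None) -> str:
    """Classify a copy as ``recent`` (K <= threshold, inclusive) or ``ancient``."""
    if K < 0:
        raise ValueError("negative divergence")
    model = model or AgeModel()
    return "recent" if K <= model.recent_threshold_K else "ancient"
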