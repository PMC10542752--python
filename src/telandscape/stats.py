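"""Rank-based statistics for windowed genome features.

The centrepiece is the partial Kendall rank correlation: the association
between TE coverage and one genomic feature after removing the rank
association both share with the remaining features (gene coverage, GC,
CpG-island coverage and recombination rate are themselves strongly
inter-correlated).  The partial tau-b is obtained from the inverse of the
pairwise tau-b matrix,

    tau_xy.z = -M_xy / sqrt(M_xx * M_yy),   M = T^-1,

which for a single control reduces to the textbook recursion
(tau_xy - tau_xz tau_yz) / sqrt((1 - tau_xz^2)(1 - tau_yz^2)).  P-values
use the normal approximation with the effective sample size reduced by
the number of controls.  Alongside: tie-corrected Kruskal-Wallis tests,
Bonferroni adjustment per feature family, the macro/micro chromosome
split at 20 Mb, relative per-chromosome TE coverage and a log-scale
coverage-versus-length regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    """A partial Kendall correlation between two window metrics."""

    x_name: str
    y_name: str
    controls: list
    n: int
    tau_partial: float
    z_stat: float
    p_raw: float
    p_adj: float = float("nan")


@dataclass
class GroupTestResult:
    """A tie-corrected Kruskal-Wallis comparison across groups."""

    groups: list
    n_i: list
    H: float
    df: int
    p: float


def kendall_tau_b(x, y) -> float:
    """Kendall tau-b between two equal-length vectors.

    Ties handled by the tau-b denominator; an all-tied vector has no rank
    information and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance")
    tau = sps.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _tau_matrix(columns: np.ndarray) -> np.ndarray:
    k = columns.shape[1]
    T = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            T[i, j] = T[j, i] = kendall_tau_b(columns[:, i], columns[:, j])
    return T


def partial_kendall(table, x_name: str, y_name: str, controls) -> CorrelationResult:
    """Partial Kendall tau-b of x vs y given the control columns.

    ``table`` is a DataFrame; rows with any missing value across the used
    columns are dropped (complete-case).  The statistic comes from the
    inverse pairwise tau-b matrix; the two-sided p-value from the normal
    approximation with z = tau / sqrt(2(2m+5) / (9m(m-1))), m = n - g.
    """
    controls = list(controls)
    if set(controls) & {x_name, y_name}:
        raise ValueError("controls overlap x/y")
    cols = [x_name, y_name] + controls
    sub = table[cols].dropna()
    n = len(sub)
    if n < 10:
        raise ValueError(f"need >= 10 complete rows, have {n}")
    T = _tau_matrix(sub.to_numpy(dtype=float))
    try:
        M = np.linalg.inv(T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate control set") from exc
    if not np.isfinite(M).all() or M[0, 0] * M[1, 1] <= 0:
        raise ValueError("degenerate control set")
    tau = float(-M[0, 1] / math.sqrt(M[0, 0] * M[1, 1]))
    g = len(controls)
    m = n - g
    se = math.sqrt(2.0 * (2.0 * m + 5.0) / (9.0 * m * (m - 1.0)))
    z = tau / se
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        controls=controls,
        n=n,
        tau_partial=tau,
        z_stat=z,
        p_raw=float(p),
    )


def kruskal_wallis(groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H test across value lists.

    Chi-square p with k-1 df; raises on an empty group or when every
    pooled value is identical (tie correction degenerates).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need total N >= 3")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied")
    H, p = sps.kruskal(*groups)
    return GroupTestResult(
        groups=list(range(len(groups))),
        n_i=[len(g) for g in groups],
        H=float(H),
        df=len(groups) - 1,
        p=float(p),
    )


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjust p-values: min(1, m*p) within one test family."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("family size smaller than number of tests")
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


MACRO_THRESHOLD = 20_000_000


def chrom_class(length_bp: int, threshold: int = MACRO_THRESHOLD) -> str:
    """Macro/micro chromosome split: micro iff strictly below the threshold.

    The conventional avian boundary is 20 Mb; exactly-threshold lengths
    are macro because micro is defined strictly as "< 20 Mb".
    """
    if length_bp <= 0:
        raise ValueError("non-positive chromosome length")
    return "micro" if length_bp < threshold else "macro"


def relative_coverage(copies, chrom_sizes: dict, by: str = "all") -> dict:
    """Percent of each chromosome covered by (a class of) TE copies.

    ``by="all"`` pools every copy; ``by="class"`` returns a nested dict
    per class label.  Coverage uses fragment unions.
    """
    from .windows import _merged

    for c in copies:
        if c.chrom not in chrom_sizes:
            raise ValueError(f"copy on unknown chromosome {c.chrom!r}")

    def cov(selected):
        out = {}
        for chrom, meta in chrom_sizes.items():
            ivals = [
                iv
                for c in selected
                if c.chrom == chrom
                for iv in c.fragment_intervals
            ]
            bp = sum(e - s for s, e in _merged(ivals))
            out[chrom] = 100.0 * bp / meta["length"]
        return out

    if by == "all":
        return cov(list(copies))
    if by == "class":
        from .io_formats import CLASS_LABELS

        return {
            label: cov([c for c in copies if c.class_label == label])
            for label in CLASS_LABELS[:4]
        }
    raise ValueError(f"unknown grouping {by!r}")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p: float
    n: int
    dropped: list = field(default_factory=list)


def coverage_length_regression(per_chrom) -> RegressionResult:
    """OLS of log10(relative coverage) on chromosome length.

    ``per_chrom`` is a sequence of (length_bp, rel_cov_percent); zero
    coverage chromosomes cannot be log-transformed and are dropped with a
    warning.  Two-sided t-test p on the slope.
    """
    import logging

    kept = [(L, c) for L, c in per_chrom if c > 0]
    dropped = [(L, c) for L, c in per_chrom if c <= 0]
    if dropped:
        logging.getLogger("telandscape").warning(
            "dropped %d zero-coverage chromosomes from regression", len(dropped)
        )
    if len(kept) < 3:
        raise ValueError("need >= 3 chromosomes with positive coverage")
    x = np.array([L for L, _ in kept], dtype=float)
    y = np.log10([c for _, c in kept])
    if np.ptp(y) == 0:  # flat response: slope exactly 0, no evidence at all
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), p=1.0, n=len(kept), dropped=dropped
        )
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
        n=len(kept),
        dropped=dropped,
    )
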