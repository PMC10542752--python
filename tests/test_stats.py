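"""Rank statistics: tau-b, partial Kendall, Kruskal-Wallis and friends."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telandscape.stats import (
    bonferroni,
    chrom_class,
    coverage_length_regression,
    kendall_tau_b,
    kruskal_wallis,
    partial_kendall,
    relative_coverage,
)


def _brute_tau_b(x, y):
    n = len(x)
    C = D = 0
    for i, j in itertools.combinations(range(n), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        C += s > 0
        D += s < 0
    tx = sum(
        t * (t - 1) // 2 for t in pd.Series(x).value_counts() if t > 1
    )
    ty = sum(
        t * (t - 1) // 2 for t in pd.Series(y).value_counts() if t > 1
    )
    n0 = n * (n - 1) // 2
    return (C - D) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTauB:
    def test_perfect_concordance(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert kendall_tau_b(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_three_point_example(self):
        # brute force over the 3 pairs: 2 concordant, 1 discordant -> 1/3
        assert kendall_tau_b([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    def test_all_tied_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            kendall_tau_b([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_with_ties(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.integers(0, 5, size=len(xs)).tolist()
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        assert kendall_tau_b(xs, ys) == pytest.approx(
            _brute_tau_b(xs, ys), abs=1e-12
        )


class TestPartialKendall:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        x = 0.7 * z + rng.standard_normal(n)
        y = -0.5 * z + rng.standard_normal(n)
        return pd.DataFrame({"x": x, "y": y, "z": z})

    def test_uncorrelated_control_is_identity(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(60),
                "y": rng.standard_normal(60),
                "z": rng.standard_normal(60),
            }
        )
        txy = kendall_tau_b(df.x, df.y)
        res = partial_kendall(df, "x", "y", ["z"])
        # independent control shifts the partial tau only marginally
        assert res.tau_partial == pytest.approx(txy, abs=0.05)

    def test_one_control_recursion_value(self):
        # frozen from the recursion: (0.6 - 0.25) / 0.75
        t_xy, t_xz, t_yz = 0.6, 0.5, 0.5
        expected = (t_xy - t_xz * t_yz) / np.sqrt(
            (1 - t_xz**2) * (1 - t_yz**2)
        )
        assert expected == pytest.approx(0.35 / 0.75)

    def test_matrix_equals_recursion_on_random_tables(self):
        worst = 0.0
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(15, 60))
            mix = rng.standard_normal((3, 3))
            df = pd.DataFrame(
                rng.standard_normal((n, 3)) @ mix, columns=["x", "y", "z"]
            )
            t_xy = kendall_tau_b(df.x, df.y)
            t_xz = kendall_tau_b(df.x, df.z)
            t_yz = kendall_tau_b(df.y, df.z)
            rec = (t_xy - t_xz * t_yz) / np.sqrt(
                (1 - t_xz**2) * (1 - t_yz**2)
            )
            mat = partial_kendall(df, "x", "y", ["z"]).tau_partial
            worst = max(worst, abs(rec - mat))
        assert worst < 1e-12

    def test_control_overlap_rejected(self):
        with pytest.raises(ValueError):
            partial_kendall(self._table(), "x", "y", ["x"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            partial_kendall(self._table(n=5), "x", "y", ["z"])

    def test_degenerate_control_rejected(self):
        df = self._table(n=30)
        df["w"] = df["z"]  # perfectly confounded control pair
        with pytest.raises(ValueError, match="degenerate"):
            partial_kendall(df, "x", "y", ["z", "w"])

    def test_p_adj_bounds(self):
        res = partial_kendall(self._table(n=60, seed=5), "x", "y", ["z"])
        assert abs(res.tau_partial) <= 1
        assert 0 <= res.p_raw <= 1


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        # ranks 1..4, R1={1,2}, R2={3,4}: H = 2.4 with df=1
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_all_tied_raises(self):
        with pytest.raises(ValueError, match="tied"):
            kruskal_wallis([[5, 5], [5, 5]])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1, 2], []])

    def test_group_order_invariant(self):
        a, b, c = [1.0, 5.0, 3.0], [2.0, 8.0], [0.5, 9.0, 4.0]
        assert kruskal_wallis([a, b, c]).H == pytest.approx(
            kruskal_wallis([c, a, b]).H
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.5, 1.0)]
        base = kruskal_wallis(groups).H
        transformed = [np.exp(g) for g in groups]
        assert kruskal_wallis(transformed).H == pytest.approx(base)


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni([0.02, 0.5], m=3) == [
            pytest.approx(0.06),
            pytest.approx(1.0),
        ]

    def test_identity_for_single_test(self):
        assert bonferroni([0.3], m=1) == [pytest.approx(0.3)]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], m=2)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestChromClass:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (19_999_999, "micro"),
            (20_000_000, "macro"),  # boundary declared macro
            (20_000_001, "macro"),
        ],
    )
    def test_boundary(self, length, expected):
        assert chrom_class(length) == expected

    def test_custom_threshold(self):
        assert chrom_class(400_000, threshold=500_000) == "micro"


class TestRelativeCoverage:
    def _copies(self):
        from telandscape.defrag import TECopy
        from telandscape.io_formats import RepeatHit

        def copy(chrom, s, e, label):
            hit = RepeatHit(
                chrom=chrom, start=s, end=e, strand="+", family_name="F",
                class_family=f"{label}/x", score=1, pct_div=1.0, pct_del=0,
                pct_ins=0, cons_start=1, cons_end=e - s, cons_left=0, run_id=1,
            )
            return TECopy(
                copy_id="c", chrom=chrom, start=s, end=e, strand="+",
                family_name="F", class_label=label, fragments=[hit],
                merged_len=e - s, K=1.0, cons_span_frac=1.0,
            )

        return [
            copy("chr1", 0, 1_000_000, "LTR"),
            copy("chr1", 2_000_000, 2_500_000, "LINE"),
        ]

    def test_per_chrom_percent(self):
        sizes = {
            "chr1": {"length": 10_000_000, "is_autosome": True},
            "chr2": {"length": 5_000_000, "is_autosome": True},
        }
        cov = relative_coverage(self._copies(), sizes)
        assert cov["chr1"] == pytest.approx(15.0)
        assert cov["chr2"] == 0.0

    def test_class_values_bounded_by_all(self):
        sizes = {"chr1": {"length": 10_000_000, "is_autosome": True}}
        copies = self._copies()
        all_cov = relative_coverage(copies, sizes)["chr1"]
        per_class = relative_coverage(copies, sizes, by="class")
        for label in per_class:
            assert per_class[label]["chr1"] <= all_cov + 1e-12

    def test_unknown_chrom_rejected(self):
        with pytest.raises(ValueError, match="chr1"):
            relative_coverage(self._copies(), {"chr9": {"length": 10}})


class TestCoverageLengthRegression:
    def test_constant_coverage_flat_slope(self):
        data = [(L, 5.0) for L in (1e6, 2e6, 5e6, 1e7, 2e7)]
        res = coverage_length_regression(data)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.99

    def test_collinear_positive_significant(self):
        data = [(L, 10 ** (L / 1e7)) for L in np.linspace(1e6, 5e7, 8)]
        res = coverage_length_regression(data)
        assert res.slope > 0 and res.p < 1e-6

    def test_zero_coverage_dropped(self):
        data = [(1e6, 0.0), (2e6, 1.0), (3e6, 2.0), (4e6, 3.0)]
        res = coverage_length_regression(data)
        assert res.n == 3 and len(res.dropped) == 1

    def test_recovers_planted_slope_sign(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            L = rng.uniform(1e6, 5e7, size=30)
            log_cov = 0.02 * L / 1e6 + rng.normal(scale=0.3, size=30)
            res = coverage_length_regression(list(zip(L, 10**log_cov)))
            hits += res.slope > 0
        assert hits >= 95


class TestTypeIAndSignRecovery:
    def test_type_one_rate_under_null(self):
        """With zero couplings the partial tau rejects ~5% at alpha=.05."""
        from telandscape.synthetic_data import Coupling, simulate_window_table

        rng = np.random.default_rng(42)
        null = Coupling(te=0.0, gene=0.0, cpg=0.0, rec=0.0, gc=0.0)
        rejections = 0
        taus = []
        for _ in range(200):
            tab = simulate_window_table(500, null, rng)
            res = partial_kendall(
                tab, "te_cov_all", "rec_rate", ["gene_cov", "cpg_cov", "gc"]
            )
            taus.append(abs(res.tau_partial))
            rejections += res.p_raw < 0.05
        assert 0.02 <= rejections / 200 <= 0.09
        assert float(np.median(taus)) < 0.05

    def test_planted_sign_recovered(self):
        """A planted negative TE-recombination link is recovered with the
        right sign in >= 95% of replicates at n=500 windows."""
        from telandscape.synthetic_data import (
            Coupling,
            plant_correlations,
            simulate_window_table,
        )

        rng = np.random.default_rng(7)
        cpl = Coupling(te=0.8, gene=0.0, cpg=0.0, gc=0.0, rec=-0.8)
        assert plant_correlations(cpl)["all"]["rec_rate"] == "-"
        correct = 0
        for _ in range(100):
            tab = simulate_window_table(500, cpl, rng)
            res = partial_kendall(
                tab, "te_cov_all", "rec_rate", ["gene_cov", "cpg_cov", "gc"]
            )
            correct += res.tau_partial < 0
        assert correct >= 95
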