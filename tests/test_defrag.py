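"""Fragment merging, LTR assembly and the 80-80-80 filter."""

import pytest

from telandscape.defrag import (
    MergeParams,
    annotation_summary,
    assemble_ltr,
    filter_808080,
    merge_fragments,
)
from telandscape.io_formats import ConsensusRecord, RepeatHit


def _hit(start, end, family="CR1L1", chrom="chr1", strand="+", cons=(1, 100, 0),
         run_id=1, div=5.0, class_family="LINE/CR1"):
    return RepeatHit(
        chrom=chrom, start=start, end=end, strand=strand, family_name=family,
        class_family=class_family, score=100, pct_div=div, pct_del=0.0,
        pct_ins=0.0, cons_start=cons[0], cons_end=cons[1], cons_left=cons[2],
        run_id=run_id,
    )


class TestMergeFragments:
    def test_collinear_neighbours_merge(self):
        hits = [
            _hit(0, 400, cons=(1, 400, 400), run_id=1),
            _hit(450, 860, cons=(390, 800, 0), run_id=2),
        ]
        copies = merge_fragments(hits, MergeParams(cons_overlap_tol=15))
        assert len(copies) == 1
        c = copies[0]
        assert (c.start, c.end) == (0, 860)
        assert c.merged_len == 810
        assert c.cons_span_frac == pytest.approx(800 / 800)

    def test_distant_different_runs_stay_separate(self):
        hits = [
            _hit(0, 400, cons=(1, 400, 400), run_id=1),
            _hit(10_400, 10_800, cons=(390, 800, 0), run_id=2),
        ]
        assert len(merge_fragments(hits)) == 2

    def test_run_id_bridges_any_gap(self):
        hits = [
            _hit(0, 400, cons=(1, 400, 400), run_id=9),
            _hit(10_400, 10_800, cons=(390, 800, 0), run_id=9),
        ]
        assert len(merge_fragments(hits)) == 1

    def test_non_collinear_consensus_blocks_rule_b(self):
        # second fragment restarts at consensus 1: a new copy, not a join
        hits = [
            _hit(0, 400, cons=(1, 400, 0), run_id=1),
            _hit(450, 850, cons=(1, 400, 0), run_id=2),
        ]
        assert len(merge_fragments(hits)) == 2

    def test_minus_strand_collinearity_mirrored(self):
        # on "-", the genomically later fragment covers earlier consensus
        hits = [
            _hit(0, 400, strand="-", cons=(390, 800, 0), run_id=1),
            _hit(450, 850, strand="-", cons=(1, 400, 400), run_id=2),
        ]
        assert len(merge_fragments(hits)) == 1
        hits_bad = [
            _hit(0, 400, strand="-", cons=(1, 400, 400), run_id=1),
            _hit(450, 850, strand="-", cons=(390, 800, 0), run_id=2),
        ]
        assert len(merge_fragments(hits_bad)) == 2

    def test_unsorted_input_rejected(self):
        hits = [_hit(500, 600), _hit(0, 100)]
        with pytest.raises(ValueError, match="sorted"):
            merge_fragments(hits)

    def test_duplicate_hit_merged_with_warning(self, caplog):
        hits = [_hit(0, 400, run_id=1), _hit(0, 400, run_id=1)]
        with caplog.at_level("WARNING", logger="telandscape"):
            copies = merge_fragments(hits)
        assert len(copies) == 1 and len(copies[0].fragments) == 1
        assert "duplicate" in caplog.text

    def test_partition_no_hit_lost_or_duplicated(self, small_dataset):
        copies = merge_fragments(small_dataset.hits)
        merged_keys = [f.key for c in copies for f in c.fragments]
        assert sorted(merged_keys) == sorted(h.key for h in small_dataset.hits)
        assert len(merged_keys) == len(set(merged_keys))

    def test_nested_fixture_outer_rejoins_inner_separate(self):
        # host CR1 split by a nested SINE: outer fragments share run_id 5
        hits = [
            _hit(0, 1000, cons=(1, 1000, 2000), run_id=5),
            _hit(1000, 1150, family="SINE1", class_family="SINE/tRNA",
                 cons=(1, 150, 0), run_id=6),
            _hit(1150, 3150, cons=(1001, 3000, 0), run_id=5),
        ]
        copies = merge_fragments(hits)
        assert len(copies) == 2
        by_family = {c.family_name: c for c in copies}
        assert len(by_family["CR1L1"].fragments) == 2
        assert by_family["CR1L1"].merged_len == 3000
        assert by_family["SINE1"].merged_len == 150


def _ltr_library(stem="ERVK1", ltr_len=300, i_len=4000):
    return {
        f"{stem}_LTR": ConsensusRecord(f"{stem}_LTR", "LTR/ERVK", "A" * ltr_len),
        f"{stem}_I": ConsensusRecord(f"{stem}_I", "LTR/ERVK", "A" * i_len),
    }


def _ltr_copies(strand="+", stem="ERVK1", gap=50):
    lib = _ltr_library(stem)
    mk = lambda s, e, fam, cons, rid: _hit(
        s, e, family=fam, strand=strand, cons=cons, run_id=rid,
        class_family="LTR/ERVK",
    )
    hits = [
        mk(0, 300, f"{stem}_LTR", (1, 300, 0), 1),
        mk(300 + gap, 4300 + gap, f"{stem}_I", (1, 4000, 0), 2),
        mk(4300 + 2 * gap, 4600 + 2 * gap, f"{stem}_LTR", (1, 300, 0), 3),
    ]
    return merge_fragments(hits), lib


class TestAssembleLtr:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_full_structure_fused_both_strands(self, strand):
        copies, lib = _ltr_copies(strand=strand)
        fused = assemble_ltr(copies, lib)
        assert len(fused) == 1
        c = fused[0]
        assert (c.start, c.end) == (0, 4700)
        assert c.family_name == "ERVK1"
        assert len(c.fragments) == 3
        assert c.cons_span_frac == pytest.approx(1.0)

    def test_solo_ltr_unchanged(self):
        lib = _ltr_library()
        copies = merge_fragments(
            [_hit(0, 300, family="ERVK1_LTR", cons=(1, 300, 0),
                  class_family="LTR/ERVK")]
        )
        fused = assemble_ltr(copies, lib)
        assert len(fused) == 1 and fused[0].family_name == "ERVK1_LTR"

    def test_internal_beyond_max_gap_not_fused(self):
        copies, lib = _ltr_copies(gap=5000)
        fused = assemble_ltr(copies, lib, MergeParams(max_gap=2500))
        assert len(fused) == 3


class TestFilter808080:
    def _copy(self, merged_len=500, K=5.0, span=0.9, label="LINE"):
        hit = _hit(0, merged_len, cons=(1, merged_len, 0))
        from telandscape.defrag import TECopy

        return TECopy(
            copy_id="c", chrom="chr1", start=0, end=merged_len, strand="+",
            family_name="F", class_label=label, fragments=[hit],
            merged_len=merged_len, K=K, cons_span_frac=span,
        )

    def test_short_copy_removed(self):
        assert filter_808080([self._copy(merged_len=79)]) == []

    def test_k20_boundary_removed(self):
        assert filter_808080([self._copy(merged_len=5000, K=20.0)]) == []

    def test_all_boundaries_satisfied_retained(self):
        kept = filter_808080([self._copy(merged_len=80, K=19.99, span=0.80)])
        assert len(kept) == 1

    def test_low_span_removed_only_in_strict_mode(self):
        c = self._copy(span=0.5)
        assert filter_808080([c], MergeParams(strict=True)) == []
        assert len(filter_808080([c], MergeParams(strict=False))) == 1

    def test_unclassified_removed(self):
        assert filter_808080([self._copy(label="Unclassified")]) == []

    def test_filter_never_increases_summary(self, small_dataset):
        copies = assemble_ltr(
            merge_fragments(small_dataset.hits), small_dataset.library
        )
        genome_len = sum(m["length"] for m in small_dataset.chrom_meta.values())
        before = annotation_summary(copies, genome_len).set_index("class")
        after = annotation_summary(filter_808080(copies), genome_len).set_index(
            "class"
        )
        assert (after["copies"] <= before["copies"]).all()
        assert (after["total_bp"] <= before["total_bp"]).all()


class TestAnnotationSummary:
    def test_empty_input_zero_rows(self):
        df = annotation_summary([], 1_000_000)
        assert (df["copies"] == 0).all() and (df["total_bp"] == 0).all()

    def test_percent_of_genome(self):
        from telandscape.defrag import TECopy

        hit = _hit(0, 5000, cons=(1, 5000, 0))
        c = TECopy(
            copy_id="c", chrom="chr1", start=0, end=5000, strand="+",
            family_name="F", class_label="LTR", fragments=[hit],
            merged_len=5000, K=1.0, cons_span_frac=1.0,
        )
        df = annotation_summary([c], 1_000_000).set_index("class")
        assert df.loc["LTR", "pct_genome"] == pytest.approx(0.5)
        assert df.loc["Total", "pct_genome"] == pytest.approx(0.5)

    def test_bad_genome_length(self):
        with pytest.raises(ValueError):
            annotation_summary([], 0)


def test_truth_recovery_on_nested_fixtures():
    """Planted copies (incl. nested splits) recovered >= 95% over seeds."""
    from conftest import small_sim_config

    from telandscape.synthetic_data import plant_genome

    total = recovered = 0
    for seed in range(20):
        ds = plant_genome(small_sim_config(seed, nesting_prob=0.3))
        copies = assemble_ltr(merge_fragments(ds.hits), ds.library)
        found = {tuple(sorted(c.fragment_intervals)) for c in copies}
        for _, row in ds.truth.iterrows():
            total += 1
            ivals = tuple(
                sorted(tuple(map(int, f.split("-"))) for f in row.fragments.split(";"))
            )
            recovered += ivals in found
    assert recovered / total >= 0.95
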