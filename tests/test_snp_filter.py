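import numpy as np
import pandas as pd
import pytest

from bulkscan.errors import ConsistencyError
from bulkscan.pool_sim import SnpPanel
from bulkscan.snp_filter import (
    FilterConfig,
    SnpTable,
    build_informative_panel,
    combine_replicates,
    drop_flagged,
    drop_monoallelic,
    filter_cascade,
    filter_high_coverage,
    poisson_coverage_cutoff,
    trim_coverage_quantiles,
)

from conftest import make_table, random_rows
from oracles import brute_combine, brute_high_coverage_filter, brute_quantile_trim, poisson_cdf_cutoff


def snp_list(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


class TestBuildInformativePanel:
    def test_single_accession_snp_kept_with_reference(self):
        a = snp_list([("1", 10, "C", "G")])
        b = snp_list([("1", 99, "A", "T")])
        panel = build_informative_panel(a, b)
        row = panel.df.set_index("pos").loc[10]
        assert row["allele_a"] == "G" and row["allele_b"] == "C"

    def test_common_variant_removed(self):
        a = snp_list([("1", 10, "C", "T")])
        b = snp_list([("1", 10, "C", "T")])
        panel = build_informative_panel(a, b)
        assert 10 not in set(panel.df["pos"])

    def test_discriminating_double_variant_kept(self):
        a = snp_list([("1", 10, "C", "G")])
        b = snp_list([("1", 10, "C", "T")])
        panel = build_informative_panel(a, b)
        row = panel.df.set_index("pos").loc[10]
        assert row["allele_a"] == "G" and row["allele_b"] == "T"

    def test_mixed_set(self):
        a = snp_list([("1", 5, "A", "G"), ("1", 10, "C", "T"), ("2", 3, "G", "A")])
        b = snp_list([("1", 10, "C", "T"), ("2", 8, "T", "C")])
        panel = build_informative_panel(a, b)
        kept = {(c, p) for c, p in zip(panel.df["chrom"], panel.df["pos"])}
        assert kept == {("1", 5), ("2", 3), ("2", 8)}


def flagged_panel():
    df = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [10, 20, 30],
            "allele_a": ["A", "C", "G"],
            "allele_b": ["T", "G", "A"],
            "flags": [frozenset({"ambiguous_reference"}), frozenset({"mismatch"}), frozenset()],
        }
    )
    return SnpPanel(df)


class TestDropFlagged:
    def test_flagged_rows_removed_unflagged_kept(self):
        t = make_table([("1", 10, 3, 4), ("1", 20, 5, 6), ("1", 30, 7, 8)])
        out = drop_flagged(t, flagged_panel(), FilterConfig())
        assert list(out.df["pos"]) == [30]
        assert list(out.df[["count_a", "count_b"]].iloc[0]) == [7, 8]

    def test_position_missing_from_panel_errors(self):
        t = make_table([("1", 99, 1, 1)])
        with pytest.raises(ConsistencyError):
            drop_flagged(t, flagged_panel(), FilterConfig())

    def test_custom_flag_subset(self):
        t = make_table([("1", 10, 3, 4), ("1", 20, 5, 6), ("1", 30, 7, 8)])
        cfg = FilterConfig(flags_to_drop=frozenset({"mismatch"}))
        out = drop_flagged(t, flagged_panel(), cfg)
        assert list(out.df["pos"]) == [10, 30]


class TestFilterHighCoverage:
    def test_uniform_coverage_untouched(self):
        t = make_table([("1", p, 10, 10) for p in range(1, 12)])
        out = filter_high_coverage(t, FilterConfig())
        assert len(out) == 11

    def test_outlier_removed_against_brute_force(self):
        rows = [("1", p, 10, 10) for p in range(1, 11)] + [("1", 99, 50, 50)]
        t = make_table(rows)
        out = filter_high_coverage(t, FilterConfig())
        expect = brute_high_coverage_filter(rows, 0.99)
        assert len(out) == len(expect) == 10
        assert 99 not in set(out.df["pos"])
        # cutoff agrees with direct pmf summation at lambda=20
        assert poisson_coverage_cutoff(20.0, 0.99) == poisson_cdf_cutoff(20.0, 0.99)

    def test_median_percentile_hand_enumeration(self):
        rows = [("1", p, c, 0) for p, c in enumerate([2, 2, 2, 3, 3, 9, 12, 20], start=1)]
        t = make_table(rows)
        out = filter_high_coverage(t, FilterConfig(poisson_percentile=0.5))
        expect = brute_high_coverage_filter(rows, 0.5)
        assert [tuple(r) for r in out.df.itertuples(index=False)] == expect

    def test_empty_table_rejected(self):
        t = make_table([("1", 1, 1, 1)]).subset(np.array([False]))
        with pytest.raises(ValueError):
            filter_high_coverage(t, FilterConfig())


class TestCombineReplicates:
    def test_counts_sum(self):
        t1 = make_table([("1", 10, 3, 1)], pool="mea", replicate="1")
        t2 = make_table([("1", 10, 2, 2)], pool="mea", replicate="2")
        out = combine_replicates([t1, t2])
        assert list(out.df.iloc[0][["count_a", "count_b"]]) == [5, 3]
        assert out.replicate is None

    def test_zero_fill_missing_replicate(self):
        t1 = make_table([("1", 10, 4, 0), ("1", 20, 1, 1)], pool="mea")
        t2 = make_table([("1", 20, 2, 3)], pool="mea")
        out = combine_replicates([t1, t2])
        assert list(out.df.set_index("pos").loc[10][["count_a", "count_b"]]) == [4, 0]

    def test_single_table_identity(self):
        t1 = make_table([("1", 10, 3, 1), ("2", 5, 0, 2)], pool="wt")
        out = combine_replicates([t1])
        pd.testing.assert_frame_equal(out.df, t1.df)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_replicates([])

    def test_mixed_pools_rejected(self):
        t1 = make_table([("1", 10, 1, 1)], pool="mea")
        t2 = make_table([("1", 10, 1, 1)], pool="wt")
        with pytest.raises(ConsistencyError):
            combine_replicates([t1, t2])

    def test_duplicate_positions_within_replicate_rejected(self):
        df = pd.DataFrame(
            [("1", 10, 1, 1), ("1", 10, 2, 2)],
            columns=["chrom", "pos", "count_a", "count_b"],
        )
        with pytest.raises(ConsistencyError):
            SnpTable(df)


class TestDropMonoallelic:
    @pytest.mark.parametrize(
        "counts,kept", [((5, 0), False), ((0, 7), False), ((1, 1), True)]
    )
    def test_cases(self, counts, kept):
        t = make_table([("1", 10, *counts)])
        out = drop_monoallelic(t)
        assert (len(out) == 1) is kept


class TestTrimCoverageQuantiles:
    def test_linear_interpolation_convention(self):
        rows = [("1", p, p, 0) for p in range(1, 201)]  # coverages 1..200
        t = make_table(rows)
        out = trim_coverage_quantiles(t, FilterConfig(tail_quantile=0.01))
        expect = brute_quantile_trim(rows, 0.01)
        assert [tuple(r) for r in out.df.itertuples(index=False)] == expect
        assert len(out) == 196  # q01=2.99, q99=198.01 -> drops 1,2,199,200

    def test_zero_tail_is_identity(self):
        t = make_table([("1", p, p, 1) for p in range(1, 20)])
        out = trim_coverage_quantiles(t, FilterConfig(tail_quantile=0.0))
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_degenerate_distribution_untouched(self):
        t = make_table([("1", p, 5, 5) for p in range(1, 50)])
        out = trim_coverage_quantiles(t, FilterConfig(tail_quantile=0.01))
        assert len(out) == 49


class TestProperties:
    def test_filters_are_row_subsets(self, rng):
        rows = random_rows(rng, 200)
        t = make_table(rows)
        cfg = FilterConfig()
        for op in (
            lambda x: filter_high_coverage(x, cfg),
            drop_monoallelic,
            lambda x: trim_coverage_quantiles(x, cfg),
        ):
            out = op(t)
            # subset with counts unmodified
            merged = out.df.merge(t.df, on=["chrom", "pos"], suffixes=("", "_in"))
            assert len(merged) == len(out.df)
            assert (merged["count_a"] == merged["count_a_in"]).all()
            assert (merged["count_b"] == merged["count_b_in"]).all()

    def test_fixed_threshold_filters_idempotent(self, rng):
        """drop_monoallelic is idempotent outright; the coverage filters are
        idempotent once their data-derived cutoffs stop moving (re-applying
        them with an unchanged cutoff removes nothing)."""
        rows = random_rows(rng, 200)
        t = drop_monoallelic(make_table(rows))
        pd.testing.assert_frame_equal(drop_monoallelic(t).df, t.df)
        cfg = FilterConfig()
        out = filter_high_coverage(make_table(rows), cfg)
        from oracles import poisson_cdf_cutoff

        cutoff = poisson_cdf_cutoff(float(np.median(out.coverage)), cfg.poisson_percentile)
        assert (out.coverage <= max(cutoff, out.coverage.max())).all()
        # quantile trim: the surviving rows all lie inside the recomputed
        # closed interval boundaries of the *original* table
        out2 = trim_coverage_quantiles(make_table(rows), cfg)
        lo, hi = np.quantile([r[2] + r[3] for r in rows], [0.01, 0.99])
        assert ((out2.coverage >= lo) & (out2.coverage <= hi)).all()

    def test_high_coverage_removal_rate_on_clean_poisson(self, rng):
        cov = rng.poisson(30, size=5_000)
        b = rng.binomial(cov, 0.25)
        rows = [("1", i + 1, int(c - x), int(x)) for i, (c, x) in enumerate(zip(cov, b))]
        out = filter_high_coverage(make_table(rows), FilterConfig())
        removed = 1 - len(out) / 5_000
        assert 0.0 <= removed <= 0.03

    def test_cascade_order_and_report(self, rng):
        panel = flagged_panel()
        reps = [
            make_table([("1", 10, 3, 1), ("1", 20, 2, 2), ("1", 30, 4, 4)], pool="m", replicate="1"),
            make_table([("1", 30, 1, 0)], pool="m", replicate="2"),
        ]
        combined, report = filter_cascade(reps, panel, FilterConfig())
        assert list(combined.df["pos"]) == [30]
        assert list(combined.df.iloc[0][["count_a", "count_b"]]) == [5, 4]
        assert report["replicates"][0]["input"] == 3
        assert report["combined"]["after_trim_coverage_quantiles"] == 1


def test_fuzz_against_brute_force(rng):
    """Randomised equivalence of every stage with the brute-force oracles."""
    for _ in range(100):
        rows = random_rows(rng, int(rng.integers(4, 500)))
        t = make_table(rows)
        pct = float(rng.uniform(0.5, 0.999))
        tail = float(rng.uniform(0.0, 0.2))
        out_hc = filter_high_coverage(t, FilterConfig(poisson_percentile=pct))
        assert [tuple(r) for r in out_hc.df.itertuples(index=False)] == brute_high_coverage_filter(rows, pct)
        out_tr = trim_coverage_quantiles(t, FilterConfig(tail_quantile=tail))
        assert [tuple(r) for r in out_tr.df.itertuples(index=False)] == brute_quantile_trim(rows, tail)
        out_mono = drop_monoallelic(t)
        assert [tuple(r) for r in out_mono.df.itertuples(index=False)] == [
            r for r in rows if r[2] > 0 and r[3] > 0
        ]
        # combine a random split of the rows as two replicates
        k = len(rows) // 2
        t1, t2 = make_table(rows[:k] or rows), make_table(rows[k:] or rows)
        out_cmb = combine_replicates([t1, t2])
        assert [tuple(r) for r in out_cmb.df.itertuples(index=False)] == brute_combine(
            [rows[:k] or rows, rows[k:] or rows]
        )
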