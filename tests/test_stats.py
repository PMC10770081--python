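import numpy as np
import pytest

from tfcrscreen.models import ElementInterval, GeneModel, VariantRecord
from tfcrscreen.stats import (
    assign_decile_bins,
    bin_tfcrs,
    element_overlap_by_bin,
    expression_enrichment_by_bin,
    mutation_rate_by_bin,
    tc_sc_correlation_split,
)

from conftest import make_tfcr


def tfcrs_with_sc(values):
    return [
        make_tfcr(f"t{i}", "chr1", 1000 * i, 1000 * i + 500, tc=1, sc=float(v))
        for i, v in enumerate(values)
    ]


def two_pass_pearson(x, y):
    """Textbook oracle: centered cross-products over centered norms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestDecileBins:
    def test_ten_distinct_values_span_all_bins(self):
        tfcrs = tfcrs_with_sc(range(1, 11))
        assign_decile_bins(tfcrs, "SC")
        assert [t.sc_bin for t in tfcrs] == list(range(10))

    def test_twenty_distinct_values_give_two_per_bin(self):
        tfcrs = tfcrs_with_sc(range(20))
        assignments = assign_decile_bins(tfcrs, "SC")
        counts = np.bincount([a.bin for a in assignments], minlength=10)
        assert list(counts) == [2] * 10

    def test_three_tfcrs_land_in_bins_0_3_6(self):
        tfcrs = tfcrs_with_sc([5.0, 1.0, 9.0])
        assign_decile_bins(tfcrs, "SC")
        assert sorted(t.sc_bin for t in tfcrs) == [0, 3, 6]

    @pytest.mark.parametrize("n", [10, 20, 37, 1000])
    def test_balanced_and_monotone_for_distinct_values(self, n):
        rng = np.random.default_rng(n)
        values = rng.permutation(n).astype(float)
        tfcrs = tfcrs_with_sc(values)
        assign_decile_bins(tfcrs, "SC")
        counts = np.bincount([t.sc_bin for t in tfcrs], minlength=10)
        assert counts.max() - counts.min() <= 1
        ordered = sorted(tfcrs, key=lambda t: t.sc)
        bins = [t.sc_bin for t in ordered]
        assert bins == sorted(bins)

    def test_ties_are_split_deterministically(self):
        tfcrs = tfcrs_with_sc([1.0] * 10)
        assign_decile_bins(tfcrs, "SC")
        again = tfcrs_with_sc([1.0] * 10)
        assign_decile_bins(again, "SC")
        assert [t.sc_bin for t in tfcrs] == [t.sc_bin for t in again]
        assert sorted(t.sc_bin for t in tfcrs) == list(range(10))

    def test_unknown_axis_is_error(self):
        with pytest.raises(ValueError, match="axis"):
            assign_decile_bins(tfcrs_with_sc([1.0]), "XX")


class TestCorrelationSplit:
    def test_perfect_linearity_in_both_strata(self):
        tfcrs = [
            make_tfcr(f"t{i}", "chr1", i * 1000, i * 1000 + 500, tc=i, sc=2.0 * i)
            for i in range(1, 101)
        ]
        split = tc_sc_correlation_split(tfcrs, 50)
        assert split.r_low == pytest.approx(1.0)
        assert split.r_high == pytest.approx(1.0)

    def test_saturating_relation_decorrelates_above_threshold(self):
        # alternating +/-1e-6 perturbation: essentially uncorrelated with TC
        tfcrs = [
            make_tfcr(
                f"t{i}", "chr1", i * 1000, i * 1000 + 500,
                tc=i, sc=min(i, 50) + 1e-6 * (-1) ** i,
            )
            for i in range(1, 101)
        ]
        split = tc_sc_correlation_split(tfcrs, 50)
        assert split.r_low > 0.99
        assert abs(split.r_high) < 0.1

    def test_pearson_matches_two_pass_oracle(self):
        rng = np.random.default_rng(42)
        tc = rng.integers(1, 200, size=500)
        sc = rng.uniform(0, 30, size=500)
        tfcrs = [
            make_tfcr(f"t{i}", "chr1", i * 1000, i * 1000 + 500,
                      tc=int(tc[i]), sc=float(sc[i]))
            for i in range(500)
        ]
        split = tc_sc_correlation_split(tfcrs, 10_000)  # everything in 'low'
        assert split.r_low == pytest.approx(two_pass_pearson(tc, sc), abs=1e-12)

    def test_tiny_stratum_flagged_undefined(self):
        tfcrs = [
            make_tfcr(f"t{i}", "chr1", i * 1000, i * 1000 + 500, tc=i, sc=float(i))
            for i in (1, 2, 100, 101, 102)
        ]
        split = tc_sc_correlation_split(tfcrs, 50)
        assert split.r_low is None
        assert split.low.undefined_reason == "fewer than 3 TFCRs"
        assert split.r_high is not None

    def test_constant_stratum_flagged_not_fabricated(self):
        tfcrs = [
            make_tfcr(f"t{i}", "chr1", i * 1000, i * 1000 + 500, tc=5, sc=float(i))
            for i in range(10)
        ]
        split = tc_sc_correlation_split(tfcrs, 50)
        assert split.r_low is None
        assert split.low.undefined_reason == "constant values"

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            tc_sc_correlation_split([], 50)


def gene(gene_id, chrom, start, end, strand="+"):
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id=gene_id, symbol=gene_id, chrom=chrom,
                     tss=tss, start=start, end=end, strand=strand)


class TestExpressionEnrichment:
    def test_only_top_bin_covers_high_expression_genes(self):
        # ten TFCRs in bins 0..9; a high-FPKM gene under the bin-9 window only
        tfcrs = tfcrs_with_sc(range(10))
        bin_tfcrs(tfcrs)
        top = next(t for t in tfcrs if t.sc_bin == 9)
        genes = [gene("HI", top.chrom, top.window_start, top.window_end)]
        expression = {"HI": 100.0}
        rows = expression_enrichment_by_bin(
            tfcrs, genes, expression, high_expr_cutoff=50.0,
            promoter_upstream=0, axes=("SC",)
        )
        values = {r.bin: r.value for r in rows}
        assert values[9] == 1.0
        assert all(values[b] == 0.0 for b in range(9))

    def test_no_genes_warns_and_gives_zero(self):
        tfcrs = tfcrs_with_sc(range(10))
        bin_tfcrs(tfcrs)
        with pytest.warns(UserWarning, match="no genes"):
            rows = expression_enrichment_by_bin(tfcrs, [], {}, axes=("SC",))
        assert all(r.value == 0.0 for r in rows)

    def test_unbinned_tfcrs_are_rejected(self):
        tfcrs = tfcrs_with_sc(range(10))
        with pytest.raises(ValueError, match="bins not assigned"):
            expression_enrichment_by_bin(tfcrs, [], {}, axes=("SC",))


class TestElementOverlap:
    def test_tiling_elements_give_one_everywhere(self):
        tfcrs = tfcrs_with_sc(range(10))
        bin_tfcrs(tfcrs)
        elements = [ElementInterval("chr1", 0, 10_000, "promoter")]
        rows = element_overlap_by_bin(tfcrs, elements, axes=("SC",))
        assert all(r.value == 1.0 for r in rows)

    def test_no_elements_give_zero_everywhere(self):
        tfcrs = tfcrs_with_sc(range(10))
        bin_tfcrs(tfcrs)
        rows = element_overlap_by_bin(tfcrs, [], axes=("SC",))
        assert all(r.value == 0.0 for r in rows)

    def test_pooled_equals_sum_of_disjoint_class_contributions(self):
        # each window overlaps exactly one element class: inclusion-exclusion
        # reduces to pooled = sum over classes, per bin
        tfcrs = tfcrs_with_sc(range(20))
        bin_tfcrs(tfcrs)
        elements = []
        for i, t in enumerate(tfcrs):
            cls = "promoter" if i % 2 == 0 else "enhancer"
            elements.append(
                ElementInterval(t.chrom, t.window_start, t.window_end, cls)
            )
        rows = element_overlap_by_bin(tfcrs, elements, axes=("SC",))
        by_bin: dict = {}
        for r in rows:
            by_bin.setdefault(r.bin, {})[r.element_class] = r.value
        for b, vals in by_bin.items():
            assert vals["pooled"] == pytest.approx(
                vals["promoter"] + vals["enhancer"]
            )


class TestMutationRate:
    def test_two_variants_in_kilobase_window(self):
        t = make_tfcr("t0", "chr1", 1000, 2000, tc=1, sc=1.0)
        bin_tfcrs([t])
        variants = [VariantRecord("chr1", 1200), VariantRecord("chr1", 1800)]
        rows = mutation_rate_by_bin([t], variants, axes=("SC",))
        assert rows[0].value == pytest.approx(2.0)

    def test_no_variants_gives_zero(self):
        tfcrs = tfcrs_with_sc(range(10))
        bin_tfcrs(tfcrs)
        rows = mutation_rate_by_bin(tfcrs, [], axes=("SC",))
        assert all(r.value == 0.0 for r in rows)

    def test_rate_invariant_to_sharding_variants(self):
        rng = np.random.default_rng(8)
        tfcrs = tfcrs_with_sc(rng.uniform(0, 50, size=40))
        bin_tfcrs(tfcrs)
        variants = [
            VariantRecord("chr1", int(p)) for p in rng.integers(0, 45_000, size=300)
        ]
        whole = mutation_rate_by_bin(tfcrs, variants, axes=("SC",))
        # sharding: counts and lengths add, so rates recombine identically
        shard_a, shard_b = variants[:137], variants[137:]
        counts = {}
        for shard in (shard_a, shard_b):
            for r in mutation_rate_by_bin(tfcrs, shard, axes=("SC",)):
                key = r.bin
                n_var = r.value * sum(
                    t.window_length for t in tfcrs if t.sc_bin == r.bin
                ) / 1000.0
                counts[key] = counts.get(key, 0.0) + n_var
        for r in whole:
            total_len = sum(t.window_length for t in tfcrs if t.sc_bin == r.bin)
            assert r.value == pytest.approx(counts[r.bin] / total_len * 1000.0)
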