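"""RPKM normalization, ratio bins, dimorphism calling and SSR concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboprot.expression import (
    BINS,
    CountsMatrix,
    bin_counts,
    call_dimorphic,
    count_above,
    group_samples,
    group_stats,
    ratio_classify,
    rpkm,
    ssr_concordance,
)


def cm(counts: dict, lib: dict) -> CountsMatrix:
    return CountsMatrix(pd.DataFrame(counts), pd.Series(lib))


def simple_meta(rows):
    return pd.DataFrame(rows).set_index("sample_id")


class TestRPKM:
    def test_hand_arithmetic(self):
        # 100 reads, 1 kb gene, 1e6 mapped reads -> RPKM 100
        m = cm({"s1": [100]}, {"s1": 1_000_000})
        m.counts.index = ["g"]
        out = rpkm(m, pd.Series({"g": 1000}))
        assert out.loc["g", "s1"] == pytest.approx(100.0)

    def test_zero_counts_zero_rpkm(self):
        m = cm({"s1": [0]}, {"s1": 10})
        m.counts.index = ["g"]
        assert rpkm(m, pd.Series({"g": 500})).loc["g", "s1"] == 0.0

    def test_linear_in_counts(self):
        a = cm({"s1": [50]}, {"s1": 1_000_000})
        b = cm({"s1": [100]}, {"s1": 1_000_000})
        a.counts.index = b.counts.index = ["g"]
        L = pd.Series({"g": 2000})
        assert 2 * rpkm(a, L).iloc[0, 0] == pytest.approx(rpkm(b, L).iloc[0, 0])

    @given(st.integers(1, 1000), st.integers(2, 10))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_joint_scaling(self, count, factor):
        base = cm({"s1": [count]}, {"s1": 10_000})
        scaled = cm({"s1": [count * factor]}, {"s1": 10_000 * factor})
        base.counts.index = scaled.counts.index = ["g"]
        L = pd.Series({"g": 1500})
        assert rpkm(base, L).iloc[0, 0] == pytest.approx(rpkm(scaled, L).iloc[0, 0])

    def test_missing_gene_length_named(self):
        m = cm({"s1": [1, 2]}, {"s1": 100})
        m.counts.index = ["g1", "g2"]
        with pytest.raises(ValueError, match="g2"):
            rpkm(m, pd.Series({"g1": 100}))

    def test_library_size_must_cover_counts(self):
        with pytest.raises(ValueError, match="library size"):
            cm({"s1": [80, 30]}, {"s1": 100})


class TestGroupStats:
    def test_all_zero_matrix(self):
        expr = pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"])
        assert group_stats(expr, ["a", "b"]) == (0, 0)

    def test_hand_sum_four_genes(self):
        expr = pd.DataFrame(
            {"a": [10.0, 20.0, 30.0, 40.0], "b": [20.0, 20.0, 30.0, 60.0]}
        )
        # gene means: 15, 20, 30, 50 -> total 115, average 115/4 = 28.75 -> 29
        assert group_stats(expr, ["a", "b"]) == (115, 29)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_stats(pd.DataFrame({"a": [1.0]}), [])

    def test_count_above_matches_loop(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(0, 2000, (30, 3)), columns=list("abc"))
        expected = sum(expr.loc[g, ["a", "b"]].mean() > 700 for g in expr.index)
        assert count_above(expr, ["a", "b"], 700) == expected

    def test_count_above_extremes(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert count_above(expr, ["a"], 1e9) == 0
        assert count_above(expr, ["a"], 0.5) == 3


def two_group_expr(xx_vals, xy_vals, genes=None):
    genes = genes or [f"g{i}" for i in range(len(xx_vals))]
    expr = pd.DataFrame({"xx1": xx_vals, "xy1": xy_vals}, index=genes)
    meta = simple_meta(
        [{"sample_id": "xx1", "stage": 5, "genotype": "XX"},
         {"sample_id": "xy1", "stage": 5, "genotype": "XY"}]
    )
    return expr, meta


class TestRatioClassify:
    def test_bins_and_boundaries(self):
        # ratios (with pseudocount 0): 3.0, 2.0 (boundary), 0.5 (boundary), 0.2
        expr, meta = two_group_expr([100, 100, 100, 500], [300, 200, 50, 100])
        out = ratio_classify(expr, meta, stage=5, pseudocount=0.0)
        assert list(out["bin"]) == ["XY_biased", "unbiased", "unbiased", "XX_biased"]

    def test_pseudocount_keeps_ratio_finite(self):
        expr, meta = two_group_expr([0.0], [10.0])
        out = ratio_classify(expr, meta, stage=5, pseudocount=0.1)
        assert np.isfinite(out["ratio"].iloc[0])
        assert out["bin"].iloc[0] == "XY_biased"

    def test_missing_genotype_rejected(self):
        expr, meta = two_group_expr([1.0], [1.0])
        with pytest.raises(ValueError, match="XX and XY"):
            ratio_classify(expr, meta.drop("xx1"), stage=5)

    def test_bin_counts_partition(self):
        rng = np.random.default_rng(7)
        expr, meta = two_group_expr(rng.uniform(1, 100, 50), rng.uniform(1, 100, 50))
        out = ratio_classify(expr, meta, stage=5)
        counts = bin_counts(out)
        assert sum(counts) == 50
        assert counts == tuple(int((out["bin"] == b).sum()) for b in BINS)


def staged_classifications(bins_by_stage):
    """bins_by_stage: gene -> list of bins over stages (5, 30, 90, 180)."""
    stages = (5, 30, 90, 180)
    return {
        s: pd.DataFrame(
            {"ratio": 1.0, "bin": {g: b[i] for g, b in bins_by_stage.items()}}
        )
        for i, s in enumerate(stages)
    }


class TestCallDimorphic:
    def test_consistent_bias_called(self):
        cls = staged_classifications({
            "up": ["XY_biased"] * 4,
            "down": ["XX_biased"] * 4,
            "mixed": ["XY_biased"] * 3 + ["unbiased"],
            "flat": ["unbiased"] * 4,
        })
        calls = {c.gene: c.direction for c in call_dimorphic(cls)}
        assert calls == {"up": "XY_high", "down": "XX_high"}

    def test_label_swap_swaps_directions(self):
        cls = staged_classifications({"up": ["XY_biased"] * 4, "down": ["XX_biased"] * 4})
        swapped = {
            s: df.assign(bin=df["bin"].map(
                {"XY_biased": "XX_biased", "XX_biased": "XY_biased", "unbiased": "unbiased"}
            ))
            for s, df in cls.items()
        }
        orig = {c.gene: c.direction for c in call_dimorphic(cls)}
        swap = {c.gene: c.direction for c in call_dimorphic(swapped)}
        assert swap == {"up": "XX_high", "down": "XY_high"}
        assert set(orig) == set(swap)


class TestSSRConcordance:
    def setup_method(self):
        genes = ["up", "down"]
        self.expr = pd.DataFrame(
            {
                "xx1": [10.0, 100.0],
                "xy1": [100.0, 10.0],
                "ssr_xy": [100.0, 10.0],   # SSR mirrors XY means
                "ssr_xx": [10.0, 100.0],   # SSR mirrors XX means
            },
            index=genes,
        )
        self.calls = call_dimorphic(staged_classifications({
            "up": ["XY_biased"] * 4, "down": ["XX_biased"] * 4
        }))

    def meta(self, ssr_sample):
        return simple_meta(
            [{"sample_id": "xx1", "stage": 180, "genotype": "XX"},
             {"sample_id": "xy1", "stage": 180, "genotype": "XY"},
             {"sample_id": ssr_sample, "stage": 180, "genotype": "SSR"}]
        )

    def test_ssr_following_xy_is_concordant(self):
        out = ssr_concordance(self.calls, self.expr, self.meta("ssr_xy"))
        assert all(c.ssr_concordant for c in out)

    def test_ssr_following_xx_is_discordant(self):
        out = ssr_concordance(self.calls, self.expr, self.meta("ssr_xx"))
        assert not any(c.ssr_concordant for c in out)

    def test_no_ssr_samples_leaves_flag_unset(self):
        meta = self.meta("ssr_xy").drop("ssr_xy")
        out = ssr_concordance(self.calls, self.expr, meta)
        assert all(c.ssr_concordant is None for c in out)

    def test_group_samples_selects_by_stage_and_genotype(self):
        meta = self.meta("ssr_xy")
        assert group_samples(meta, stage=180, genotype="XX") == ["xx1"]
        assert group_samples(meta, genotype="SSR") == ["ssr_xy"]
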