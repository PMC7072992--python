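"""Duplication-timing verdicts, synteny scoring and retention totals."""

import numpy as np
import pandas as pd
import pytest

from riboprot.catalog import paralog_families
from riboprot.wgd import (
    AnnotatedTree,
    SyntenyBlock,
    classify_duplication,
    retention_table,
    synteny_orientation_agreement,
    synteny_support,
)

from conftest import newick


def annotated(nwk, lineages):
    return AnnotatedTree(newick(nwk), lineages)


# Constructed topologies mirroring the canonical duplicate-pair situations.
TWO_R = (
    "((til_a,human_a)90,(til_b,human_b)85,gar);",
    {"til_a": "teleost", "human_a": "tetrapod", "til_b": "teleost",
     "human_b": "tetrapod", "gar": "non3R_fish"},
    ({"til_a", "human_a"}, {"til_b", "human_b"}),
)
THREE_R = (
    "(((til_a,zeb_a),(til_b,zeb_b)),gar,human);",
    {"til_a": "teleost", "zeb_a": "teleost", "til_b": "teleost",
     "zeb_b": "teleost", "gar": "non3R_fish", "human": "tetrapod"},
    ({"til_a", "zeb_a"}, {"til_b", "zeb_b"}),
)
FOUR_R = (
    "(((sal_a1,sal_a2),(sal_b1,sal_b2)),til,human);",
    {"sal_a1": "salmonid_4R", "sal_a2": "salmonid_4R", "sal_b1": "salmonid_4R",
     "sal_b2": "salmonid_4R", "til": "teleost", "human": "tetrapod"},
    ({"sal_a1", "sal_a2"}, {"sal_b1", "sal_b2"}),
)
LINEAGE = (
    "(((til_a,med_a),(til_b,med_b)),zeb,human);",
    {"til_a": "percomorph", "med_a": "percomorph", "til_b": "percomorph",
     "med_b": "percomorph", "zeb": "teleost", "human": "tetrapod"},
    ({"til_a", "med_a"}, {"til_b", "med_b"}),
)
PARAPHYLETIC = (
    "(((til_a,til_b),zeb_a),med_b,human);",
    {"til_a": "teleost", "til_b": "teleost", "zeb_a": "teleost",
     "med_b": "teleost", "human": "tetrapod"},
    ({"til_a", "zeb_a"}, {"til_b", "med_b"}),
)


class TestClassifyDuplication:
    @pytest.mark.parametrize(
        "case, expected",
        [(TWO_R, "2R"), (THREE_R, "3R"), (FOUR_R, "4R"),
         (LINEAGE, "lineage_specific"), (PARAPHYLETIC, "unresolved")],
        ids=["two-clades-fish-plus-tetrapod", "teleost-only-clades",
             "salmonid-only-clades", "percomorph-only-clades",
             "paraphyletic-duplicates"],
    )
    def test_verdicts(self, case, expected):
        nwk, lin, sets = case
        assert classify_duplication(annotated(nwk, lin), sets).verdict == expected

    @pytest.mark.parametrize("case", [TWO_R, THREE_R, FOUR_R, LINEAGE, PARAPHYLETIC])
    def test_swap_invariance(self, case):
        nwk, lin, (a, b) = case
        t = annotated(nwk, lin)
        assert (classify_duplication(t, (a, b)).verdict
                == classify_duplication(t, (b, a)).verdict)

    def test_overlapping_sets_rejected(self):
        nwk, lin, _ = TWO_R
        with pytest.raises(ValueError, match="overlap"):
            classify_duplication(
                annotated(nwk, lin), ({"til_a", "human_a"}, {"til_a", "til_b"})
            )

    def test_support_is_min_of_clade_edges(self):
        nwk, lin, sets = TWO_R  # newick carries supports 90 and 85
        from riboprot.io import read_tree
        import io as _io, tempfile, os
        with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
            fh.write(nwk)
            path = fh.name
        try:
            tree = read_tree(path)
        finally:
            os.unlink(path)
        call = classify_duplication(AnnotatedTree(tree, lin), sets)
        assert call.verdict == "2R"
        assert call.support == 85.0

    def test_missing_supports_leave_support_unknown(self):
        nwk, lin, sets = THREE_R
        call = classify_duplication(annotated(nwk, lin), sets)
        assert call.support is None


class TestSynteny:
    def block(self, names, focal, strands=None):
        strands = strands or ["+"] * len(names)
        return SyntenyBlock("tilapia", focal, list(zip(names, strands)))

    def test_identical_blocks_window3(self):
        names = list("abcXdef")
        b = self.block(names, "X")
        assert synteny_support(b, b, window=3) == 6

    def test_disjoint_neighbors(self):
        q = self.block(["a", "b", "X", "c", "d"], "X")
        t = self.block(["p", "q", "X", "r", "s"], "X")
        assert synteny_support(q, t, window=2) == 0

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(4)
        pool = [f"g{i}" for i in range(12)]
        for _ in range(20):
            q_names = list(rng.permutation(pool))[:7]
            t_names = list(rng.permutation(pool))[:7]
            q = self.block(q_names[:3] + ["X"] + q_names[3:], "X")
            t = self.block(t_names[:3] + ["X"] + t_names[3:], "X")
            w = int(rng.integers(1, 4))
            expected = len(
                {g for g, _ in q.neighbors(w)} & {g for g, _ in t.neighbors(w)}
            )
            assert synteny_support(q, t, w) == expected

    def test_focal_must_occur_once(self):
        with pytest.raises(ValueError, match="exactly once"):
            SyntenyBlock("sp", "X", [("X", "+"), ("X", "-")])

    def test_orientation_reported_separately(self):
        q = self.block(["a", "b", "X", "c"], "X", ["+", "+", "+", "+"])
        t = self.block(["a", "b", "X", "c"], "X", ["+", "-", "+", "+"])
        assert synteny_support(q, t, window=2) == 3
        assert synteny_orientation_agreement(q, t, window=2) == 2


class TestRetention:
    def test_tilapia_family_sizes_sum_to_catalog(self, tilapia):
        fams = paralog_families(tilapia)
        presence = pd.DataFrame(
            {"tilapia": {f.base_name: f.size for f in fams}}
        ).astype(np.int64)
        assert retention_table(presence)["tilapia"] == 92

    def test_all_zero_matrix(self):
        presence = pd.DataFrame(np.zeros((3, 2), dtype=np.int64),
                                columns=["sp1", "sp2"])
        assert (retention_table(presence) == 0).all()

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 5, (6, 4)))
        expected = [sum(m.iloc[i, j] for i in range(6)) for j in range(4)]
        assert list(retention_table(m)) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            retention_table(pd.DataFrame([[1, -1]]))
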