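"""Guess-table construction, I/O, and transformations."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blindindex.table import (
    BlindingDataError,
    DegenerateDataError,
    GuessTable,
    TableFormatError,
    collapse_likert,
    combine_arms,
    drop_idk,
    read_crosstab,
    read_long,
    write_crosstab,
)

from conftest import make_table


# ---------------------------------------------------------------- strategies

counts_2x3 = st.lists(
    st.lists(st.integers(0, 50), min_size=3, max_size=3), min_size=2, max_size=2
).filter(lambda rows: all(sum(r) >= 1 for r in rows))


@st.composite
def random_tables(draw):
    k = draw(st.integers(2, 4))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, 30), min_size=k + 1, max_size=k + 1),
            min_size=k,
            max_size=k,
        ).filter(lambda rs: all(sum(r) >= 1 for r in rs))
    )
    return make_table(rows, scale="ternary")


# ------------------------------------------------------------- construction


class TestGuessTable:
    def test_build_pads_idk_for_2x2(self):
        t = make_table([[42, 0], [19, 2]])
        assert t.scale == "binary"
        assert t.counts.shape == (2, 3)
        assert not t.has_idk
        assert t.n_total == 63

    def test_build_likert5(self):
        t = make_table([[38, 44, 21, 4, 170], [11, 16, 21, 8, 83]])
        assert t.scale == "likert5"
        assert np.array_equal(t.counts, [[82, 25, 170], [27, 29, 83]])
        assert t.n_total == 416

    @pytest.mark.parametrize(
        "rows,err",
        [
            ([[1, 2, 3]], TableFormatError),               # one arm
            ([[0, 0, 0], [1, 1, 0]], TableFormatError),    # empty arm row
            ([[1, -1, 0], [1, 1, 0]], TableFormatError),   # negative cell
            ([[1.5, 1, 0], [1, 1, 0]], TableFormatError),  # fractional cell
        ],
    )
    def test_invalid_tables_rejected(self, rows, err):
        with pytest.raises(err):
            make_table(rows)

    def test_binary_scale_requires_empty_idk_column(self):
        with pytest.raises(TableFormatError):
            GuessTable(("A", "B"), ("gA", "gB"), np.array([[1, 1, 2], [1, 1, 0]]), "binary")


# ---------------------------------------------------------------------- I/O


class TestReadCrosstab:
    def test_ternary_table(self):
        src = "arm,guessA,guessB,IDK\nA,36,12,19\nB,18,6,9\n"
        t = read_crosstab(src)
        assert t.n_total == 100
        assert t.scale == "ternary"
        assert np.array_equal(t.counts, [[36, 12, 19], [18, 6, 9]])

    def test_2x2_without_idk_column(self):
        t = read_crosstab("arm,guessA,guessB\nA,42,0\nB,19,2\n")
        assert t.scale == "binary"
        assert np.array_equal(t.idk_counts, [0, 0])

    def test_likert_header_collapses(self):
        src = (
            "arm,strongly_A,somewhat_A,somewhat_B,strongly_B,IDK\n"
            "A,38,44,21,4,170\nB,11,16,21,8,83\n"
        )
        t = read_crosstab(src)
        assert t.scale == "likert5"
        assert np.array_equal(t.counts, [[82, 25, 170], [27, 29, 83]])

    def test_negative_cell_names_location(self):
        with pytest.raises(TableFormatError, match="arm 'B'.*'guessB'"):
            read_crosstab("arm,guessA,guessB\nA,1,2\nB,3,-1\n")

    def test_non_integer_cell_rejected(self):
        with pytest.raises(TableFormatError, match="non-integer"):
            read_crosstab("arm,guessA,guessB\nA,1,2\nB,3,x\n")

    def test_duplicate_arm_rejected(self):
        with pytest.raises(TableFormatError, match="duplicate arm"):
            read_crosstab("arm,guessA,guessB\nA,1,2\nA,3,4\n")

    @given(counts_2x3)
    def test_row_order_irrelevant_up_to_relabeling(self, rows):
        head = "arm,guessA,guessB,IDK\n"
        fwd = read_crosstab(head + f"A,{rows[0][0]},{rows[0][1]},{rows[0][2]}\n"
                            + f"B,{rows[1][0]},{rows[1][1]},{rows[1][2]}\n")
        rev = read_crosstab(head + f"B,{rows[1][0]},{rows[1][1]},{rows[1][2]}\n"
                            + f"A,{rows[0][0]},{rows[0][1]},{rows[0][2]}\n")
        a_fwd = fwd.counts[fwd.arm_labels.index("A")]
        a_rev = rev.counts[rev.arm_labels.index("A")]
        assert np.array_equal(a_fwd, a_rev)


class TestReadLong:
    def test_direct_tally(self):
        recs = "arm,guess\n" + "A,guessA\n" * 50 + "B,guessB\n" * 50
        t = read_long(io.StringIO(recs))
        assert np.array_equal(t.counts, [[50, 0, 0], [0, 50, 0]])

    def test_acupuncture_records(self):
        recs = "arm,guess\n" + "A,guessA\n" * 42 + "B,guessA\n" * 19 + "B,guessB\n" * 2
        t = read_long(io.StringIO(recs))
        assert np.array_equal(t.counts, [[42, 0, 0], [19, 2, 0]])
        assert t.scale == "binary"

    def test_unknown_guess_value_rejected(self):
        recs = "arm,guess\nA,guessA\nB,guessB\nA,maybe\nB,guessA\nA,guessB\n"
        with pytest.raises(TableFormatError, match="maybe"):
            read_long(io.StringIO(recs), guess_labels=("guessA", "guessB"))

    def test_missing_arm_column(self):
        with pytest.raises(TableFormatError, match="treatment"):
            read_long(io.StringIO("arm,guess\nA,guessA\nB,guessA\n"), arm_column="treatment")

    @given(counts_2x3)
    def test_long_roundtrip_identical(self, rows):
        t = make_table(rows, scale="ternary")
        recs = "arm,guess\n" + "\n".join(f"{a},{g}" for a, g in t.to_long_records())
        back = read_long(io.StringIO(recs), guess_labels=t.guess_labels)
        again = read_long(
            io.StringIO("arm,guess\n" + "\n".join(f"{a},{g}" for a, g in back.to_long_records())),
            guess_labels=t.guess_labels,
        )
        assert back == again
        assert np.array_equal(back.counts, t.counts)


def test_crosstab_write_read_roundtrip(tmp_path):
    t = make_table([[38, 44, 21, 4, 170], [11, 16, 21, 8, 83]])
    path = tmp_path / "likert.csv"
    write_crosstab(t, path)
    assert read_crosstab(str(path)) == t


# ---------------------------------------------------------- transformations


class TestCollapseLikert:
    def test_statin_collapse(self):
        t = make_table([[38, 44, 21, 4, 170], [11, 16, 21, 8, 83]])
        c = collapse_likert(t)
        assert c.scale == "ternary"
        assert np.array_equal(c.counts, [[82, 25, 170], [27, 29, 83]])
        assert c.n_total == t.n_total

    def test_pairwise_sums(self):
        c = collapse_likert(make_table([[1, 1, 1, 1, 0], [2, 2, 2, 2, 0]]))
        assert np.array_equal(c.counts, [[2, 2, 0], [4, 4, 0]])

    def test_only_idk_rows_propagate(self):
        c = collapse_likert(make_table([[0, 0, 0, 0, 9], [0, 0, 0, 0, 7]]))
        assert np.array_equal(c.counts, [[0, 0, 9], [0, 0, 7]])

    def test_wrong_scale_rejected(self, balanced_random):
        with pytest.raises(BlindingDataError):
            collapse_likert(balanced_random)


class TestCombineArms:
    ARMS = [("active", ["low", "high"]), ("control", ["ribo"])]
    GUESSES = [("g_active", ["g_low", "g_high"]), ("g_control", ["g_ribo"])]

    def three_arm(self):
        return make_table(
            [[41, 66, 30, 44], [27, 72, 24, 51], [22, 36, 64, 52]],
            arm_labels=("low", "high", "ribo"),
            guess_labels=("g_low", "g_high", "g_ribo"),
        )

    def test_two_dose_arms_merge(self):
        c = combine_arms(self.three_arm(), self.ARMS, self.GUESSES)
        assert np.array_equal(c.counts, [[206, 54, 95], [58, 64, 52]])
        assert c.n_total == 529

    def test_identity_partition(self, unbalanced_idk):
        ident_a = [(a, [a]) for a in unbalanced_idk.arm_labels]
        ident_g = [(g, [g]) for g in unbalanced_idk.guess_labels]
        assert combine_arms(unbalanced_idk, ident_a, ident_g) == unbalanced_idk

    def test_partition_must_cover(self):
        with pytest.raises(BlindingDataError, match="partition"):
            combine_arms(self.three_arm(), [("x", ["low"])], self.GUESSES)

    @given(random_tables())
    def test_grand_total_preserved(self, t):
        merged_arms = [("all_but_last", list(t.arm_labels[:-1])), ("last", [t.arm_labels[-1]])]
        merged_guesses = [("g1", list(t.guess_labels[:-1])), ("g2", [t.guess_labels[-1]])]
        c = combine_arms(t, merged_arms, merged_guesses)
        assert c.n_total == t.n_total


class TestDropIdk:
    def test_exclusions_recorded(self):
        t = drop_idk(make_table([[15, 0, 85], [0, 15, 85]]))
        assert np.array_equal(t.treatment_counts, [[15, 0], [0, 15]])
        assert t.idk_excluded == (85, 85)
        assert t.scale == "binary"
        assert t.n_total == 30

    def test_binary_table_unchanged(self, acupuncture):
        assert np.array_equal(drop_idk(acupuncture).counts, acupuncture.counts)

    def test_all_idk_arm_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="only IDK"):
            drop_idk(make_table([[0, 0, 100], [0, 0, 100]]))
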