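"""Ingest: file round-trips, arcsinh transform, subsampling, abundances."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnbpipe import (
    ExpressionMatrix,
    arcsinh_transform,
    cluster_abundance,
    group_ratio,
    read_expression,
    subsample_cells,
    write_expression,
)
from dnbpipe.errors import (
    EmptyGroupError,
    FormatError,
    MissingTimepointError,
    NonNumericError,
    NoPanelOverlapError,
    TransformStateError,
    ZeroDenominatorError,
)
from dnbpipe.fcs import write_fcs
from dnbpipe.ingest import load_sample


class TestReadExpression:
    def test_delimited_round_trip_preserves_values_in_order(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("CD3,CD8\n1.5,2.0\n0.0,4.25\n3.0,5.5\n")
        m = read_expression(path)
        assert m.marker_names == ("CD3", "CD8")
        assert np.array_equal(
            m.values, [[1.5, 2.0], [0.0, 4.25], [3.0, 5.5]]
        )
        assert m.transform_state == "raw"

    def test_fcs_round_trip(self, tmp_path):
        values = np.array([[1.0, 2.5, 0.0], [4.0, 5.5, -1.25]])
        path = tmp_path / "t.fcs"
        write_fcs(path, values, ["CD3", "CD8", "CD27"])
        m = read_expression(path, format="fcs")
        assert m.marker_names == ("CD3", "CD8", "CD27")
        assert np.array_equal(m.values, values)

    def test_no_panel_overlap_is_distinct_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("X,Y\n1,2\n")
        with pytest.raises(NoPanelOverlapError):
            read_expression(path, panel=["CD3", "CD8"])

    def test_non_numeric_cells_are_distinct_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("CD3,CD8\n1,2\nlow,4\n")
        with pytest.raises(NonNumericError):
            read_expression(path)

    def test_unreadable_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_expression(tmp_path / "absent.csv")

    def test_off_panel_channels_dropped(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("CD3,Time,CD8\n1,0,2\n3,1,4\n")
        m = read_expression(path, panel=["CD3", "CD8"])
        assert m.marker_names == ("CD3", "CD8")

    def test_write_read_round_trip_value_identical(self, tmp_path):
        m = ExpressionMatrix(
            np.array([[1.25, -0.5], [2.0, 3.75]]), ("CD3", "CD8")
        )
        path = tmp_path / "rt.csv"
        write_expression(m, path)
        back = read_expression(path)
        assert back.marker_names == m.marker_names
        assert np.array_equal(back.values, m.values)


class TestArcsinh:
    def test_closed_form_values(self, toy_matrix):
        t = arcsinh_transform(toy_matrix, cofactor=5)
        # x=0 is a fixed point; x=5 at cofactor 5 gives asinh(1)=ln(1+sqrt 2)
        assert t.values[0, 0] == 0.0
        assert t.values[0, 3] == pytest.approx(np.log(1 + np.sqrt(2)),
                                               abs=1e-12)
        assert t.transform_state == "arcsinh(5)"

    def test_negative_raw_values_retained_with_sign(self):
        m = ExpressionMatrix(np.array([[-1.0, 1.0]]), ("a", "b"))
        t = arcsinh_transform(m, cofactor=5)
        assert t.values[0, 0] == pytest.approx(np.arcsinh(-0.2))
        assert t.values[0, 0] < 0

    def test_double_transform_is_error(self, toy_matrix):
        once = arcsinh_transform(toy_matrix)
        with pytest.raises(TransformStateError):
            arcsinh_transform(once)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-100, 1e6), min_size=2, max_size=30,
                    unique=True))
    def test_strictly_monotone_rank_preserving(self, xs):
        m = ExpressionMatrix(np.array(xs)[:, None], ("m",))
        t = arcsinh_transform(m)
        assert np.array_equal(np.argsort(m.values[:, 0]),
                              np.argsort(t.values[:, 0]))


class TestSubsample:
    def test_seeded_and_reproducible(self):
        m = ExpressionMatrix(np.arange(4000.0).reshape(2000, 2), ("a", "b"))
        s1 = subsample_cells(m, n=500, seed=1)
        s2 = subsample_cells(m, n=500, seed=1)
        s3 = subsample_cells(m, n=500, seed=2)
        assert s1.n_cells == 500
        assert np.array_equal(s1.values, s2.values)
        assert not np.array_equal(s1.values, s3.values)

    def test_small_matrix_passes_through(self):
        m = ExpressionMatrix(np.ones((300, 2)), ("a", "b"))
        assert subsample_cells(m, n=500) is m

    def test_unstable_target_rejected(self):
        m = ExpressionMatrix(np.ones((300, 2)), ("a", "b"))
        with pytest.raises(ValueError):
            subsample_cells(m, n=49)


class TestClusterAbundance:
    def test_direct_count(self):
        m = ExpressionMatrix(
            np.zeros((10, 2)), ("a", "b"),
            cluster_labels=np.array(["A"] * 7 + ["B"] * 3),
        )
        assert cluster_abundance(m) == {"A": 0.7, "B": 0.3}

    def test_degenerate_single_cluster(self):
        m = ExpressionMatrix(np.zeros((5, 2)), ("a", "b"),
                             cluster_labels=np.array(["X"] * 5))
        assert cluster_abundance(m) == {"X": 1.0}

    def test_reference_list_reports_absent_cluster_as_zero(self):
        m = ExpressionMatrix(np.zeros((4, 2)), ("a", "b"),
                             cluster_labels=np.array(list("AABB")))
        freq = cluster_abundance(m, reference_clusters=["A", "B", "C"])
        assert freq["C"] == 0.0

    def test_no_labels_is_error(self, toy_matrix):
        with pytest.raises(ValueError):
            cluster_abundance(toy_matrix)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=1, max_size=60))
    def test_frequencies_sum_to_one(self, labels):
        m = ExpressionMatrix(np.zeros((len(labels), 2)), ("a", "b"),
                             cluster_labels=np.array(labels))
        assert sum(cluster_abundance(m).values()) == pytest.approx(1, abs=1e-12)


class TestGroupRatio:
    def test_hand_arithmetic(self):
        values = {"p1": 2.0, "p2": 4.0, "q1": 1.0, "q2": 2.0}
        groups = {"p1": "rSLE", "p2": "rSLE", "q1": "HC", "q2": "HC"}
        assert group_ratio(values, groups, "rSLE", "HC") == pytest.approx(2.0)

    def test_identical_groups_give_one(self):
        values = {"a": 3.0, "b": 3.0}
        groups = {"a": "HC", "b": "rSLE"}
        assert group_ratio(values, groups, "HC", "rSLE") == pytest.approx(1.0)

    def test_zero_denominator_and_empty_group_are_distinct(self):
        values = {"a": 3.0, "b": 0.0}
        groups = {"a": "HC", "b": "rSLE"}
        with pytest.raises(ZeroDenominatorError):
            group_ratio(values, groups, "HC", "rSLE")
        with pytest.raises(EmptyGroupError):
            group_ratio(values, groups, "HC", "aSLE")


def test_missing_timepoint_is_hard_error(tmp_path):
    path = tmp_path / "t0.csv"
    path.write_text("a,b\n1,2\n")
    with pytest.raises(MissingTimepointError):
        load_sample({0.0: path}, "P1", "HC")
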