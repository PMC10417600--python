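"""Stream data model, CSV round-trips, windowing and schedule arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chamberpref.streams import (
    BoundingBox,
    Experiment,
    ExperimentDesign,
    MalformedRowError,
    ObservationWindow,
    centroid,
    default_windows,
    downsample,
    expected_frame_count,
    frames_from_dataframe,
    read_detection_csv,
    schedule_hours,
    select_windows,
    total_days,
    write_detection_csv,
)

from conftest import make_stream, box_around


# ---------------------------------------------------------------------------
# boxes and centroids
# ---------------------------------------------------------------------------


class TestBoundingBox:
    def test_centroid_is_midpoint(self):
        assert centroid(BoundingBox(0, 0, 10, 20)) == (5, 10)

    @given(
        a=st.floats(0, 500), b=st.floats(0, 300),
        w=st.floats(1, 200), h=st.floats(1, 150),
    )
    def test_centroid_closed_form(self, a, b, w, h):
        cx, cy = centroid(BoundingBox(a, b, a + w, b + h))
        assert cx == pytest.approx(a + w / 2)
        assert cy == pytest.approx(b + h / 2)

    @pytest.mark.parametrize(
        "coords",
        [(10, 10, 10, 50), (10, 10, 50, 10), (50, 10, 10, 50), (-1, 0, 10, 10),
         (0, 0, 1e-6, 1e-6)],
    )
    def test_invalid_boxes_rejected(self, coords):
        with pytest.raises(ValueError):
            BoundingBox(*coords)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


class TestDetectionCsv:
    def test_single_record_roundtrip(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text(
            "experiment_id,replicate,day,session,compartment,frame_index,"
            "timestamp_s,x_min,y_min,x_max,y_max\n"
            "1,1,1,morning,A,0,0.0,10,10,50,50\n"
        )
        df = read_detection_csv(p)
        assert len(df) == 1
        frames = list(frames_from_dataframe(df))
        assert len(frames) == 1 and frames[0].count == 1

    def test_header_only_is_empty_stream(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(
            "experiment_id,replicate,day,session,compartment,frame_index,"
            "timestamp_s,x_min,y_min,x_max,y_max\n"
        )
        df = read_detection_csv(p)
        assert len(df) == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "experiment_id,replicate,day,session,compartment,frame_index,"
            "timestamp_s,x_min,y_min,x_max,y_max\n"
            "1,1,1,morning,A,0,0.0,10,10,50,50\n"
            "1,1,1,morning,A,oops,0.1,10,10,50,50\n"
        )
        with pytest.raises(MalformedRowError, match="line 3"):
            read_detection_csv(p)

    def test_inverted_box_rejected_with_count(self, tmp_path):
        p = tmp_path / "inv.csv"
        p.write_text(
            "experiment_id,replicate,day,session,compartment,frame_index,"
            "timestamp_s,x_min,y_min,x_max,y_max\n"
            "1,1,1,morning,A,0,0.0,50,10,10,50\n"  # x_min >= x_max
        )
        df = read_detection_csv(p)
        assert df.attrs["n_rejected_boxes"] == 1
        # the frame survives as an explicit empty record
        assert len(df) == 1 and np.isnan(df["x_min"].iloc[0])

    @given(
        records=st.lists(
            st.tuples(
                st.sampled_from("ABC"),
                st.integers(0, 50),
                st.lists(
                    st.tuples(st.floats(0, 600), st.floats(0, 400)).map(
                        lambda p: box_around(p[0] + 50, p[1] + 40)
                    ),
                    max_size=6,
                ),
            ),
            max_size=12,
            unique_by=lambda r: (r[0], r[1]),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_reproduces_records(self, records, tmp_path_factory):
        stream = make_stream(records)
        tmp = tmp_path_factory.mktemp("rt")
        write_detection_csv(stream, tmp / "a.csv")
        back = read_detection_csv(tmp / "a.csv")
        assert len(back) == len(stream)
        # second write is byte-identical to the first (canonical form)
        write_detection_csv(back, tmp / "b.csv")
        assert (tmp / "a.csv").read_bytes() == (tmp / "b.csv").read_bytes()
        a = stream.sort_values(["compartment", "frame_index", "x_min"]).reset_index(drop=True)
        b = back.sort_values(["compartment", "frame_index", "x_min"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False, atol=1e-9)


# ---------------------------------------------------------------------------
# down-sampling and windows
# ---------------------------------------------------------------------------


class TestDownsample:
    def test_keeps_multiples_and_updates_fps(self):
        stream = make_stream([("A", i, [box_around(100, 100)]) for i in range(30)], fps=30)
        out = downsample(stream, 2)
        assert sorted(out["frame_index"]) == list(range(0, 30, 2))
        assert out.attrs["fps"] == 15

    def test_factor_one_is_identity(self):
        stream = make_stream([("A", i, []) for i in range(5)])
        pd.testing.assert_frame_equal(downsample(stream, 1), stream)

    def test_factor_30_gives_one_frame_per_second(self):
        stream = make_stream([("A", i, []) for i in range(90)], fps=30)
        assert len(downsample(stream, 30)) == 3

    @pytest.mark.parametrize("factor", [0, -1, 1.5])
    def test_bad_factor(self, factor):
        with pytest.raises(ValueError):
            downsample(make_stream([]), factor)

    @given(a=st.integers(1, 5), b=st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_composition(self, a, b):
        stream = make_stream([("A", i, []) for i in range(60)])
        lhs = downsample(downsample(stream, a), b)
        rhs = downsample(stream, a * b)
        assert list(lhs["frame_index"]) == list(rhs["frame_index"])


class TestWindows:
    def test_default_windows_select_4h_per_day(self):
        # one frame per minute over 24 h
        rows = [("A", i, []) for i in range(24 * 60)]
        stream = make_stream(rows)
        stream["timestamp_s"] = stream["frame_index"] * 60.0
        out = select_windows(stream, default_windows())
        assert len(out) == 4 * 60
        assert set(out["window"]) == {"morning", "afternoon"}

    def test_empty_window_list_empties_stream(self):
        stream = make_stream([("A", 0, [box_around(50, 50)])])
        assert len(select_windows(stream, [])) == 0

    def test_boundary_frame_excluded(self):
        w = ObservationWindow("morning", 100.0, 200.0)
        stream = make_stream([("A", i, []) for i in range(3)])
        stream["timestamp_s"] = [99.0, 100.0, 200.0]
        out = select_windows(stream, [w])
        assert list(out["timestamp_s"]) == [100.0]  # half-open [start, end)

    def test_overlapping_windows_error(self):
        wins = [ObservationWindow("a", 0, 100), ObservationWindow("b", 50, 150)]
        with pytest.raises(ValueError, match="overlap"):
            select_windows(make_stream([]), wins)

    def test_preserves_order_and_never_fabricates(self):
        rows = [("A", i, []) for i in range(100)]
        stream = make_stream(rows)
        stream["timestamp_s"] = stream["frame_index"] * 120.0
        out = select_windows(stream, default_windows())
        assert list(out["frame_index"]) == sorted(out["frame_index"])
        assert set(out["frame_index"]) <= set(stream["frame_index"])


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------


class TestDesign:
    def test_table_has_54_days_and_648_hours(self, design):
        assert total_days(design) == 54
        assert schedule_hours(design) == 648.0

    def test_35M_frames_at_15fps(self, design):
        assert expected_frame_count(design, fps=15.0) == 34_992_000

    def test_one_day_one_compartment_default_windows(self, design):
        d = ExperimentDesign(
            experiments=design.experiments[:3], days_per_treatment=1, replicates=1
        )
        # 3 experiments x 1 day x 1 replicate x 4 h x 1 compartment
        assert schedule_hours(d, n_compartments=1) == 12.0

    def test_latin_square_enforced(self, design):
        broken = [
            Experiment(1, "hot", {"A": "white", "B": "green", "C": "red"}),
            Experiment(2, "hot", {"A": "white", "B": "red", "C": "green"}),
            Experiment(3, "hot", {"A": "green", "B": "red", "C": "white"}),
        ]
        with pytest.raises(ValueError, match="Latin square"):
            ExperimentDesign(experiments=broken)

    def test_every_light_in_every_compartment_once_per_thermal(self, design):
        for thermal in ("hot", "neutral", "cold"):
            exps = [e for e in design.experiments if e.thermal == thermal]
            for comp in "ABC":
                assert sorted(e.light_map[comp] for e in exps) == ["green", "red", "white"]

    def test_yaml_roundtrip(self, design, tmp_path):
        design.to_yaml(tmp_path / "d.yaml")
        back = ExperimentDesign.from_yaml(tmp_path / "d.yaml")
        assert back.to_dict() == design.to_dict()

    def test_schedule_hours_linear_in_days(self, design):
        double = ExperimentDesign(
            experiments=design.experiments, days_per_treatment=4, replicates=3
        )
        assert schedule_hours(double) == 2 * schedule_hours(design)
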