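"""Record validation, geometry, CSV round trips and effort bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riversurvey as rs
from riversurvey import survey_data as sd


class TestPerpendicularDistance:
    @pytest.mark.parametrize(
        "radial, angle, expected",
        [(100.0, 30.0, 50.0), (200.0, 90.0, 200.0), (0.0, 37.0, 0.0), (100.0, 0.0, 0.0)],
    )
    def test_known_geometry(self, radial, angle, expected):
        assert rs.perpendicular_distance(radial, angle) == pytest.approx(expected)

    @pytest.mark.parametrize("radial, angle", [(-1.0, 30.0), (100.0, -5.0), (100.0, 95.0)])
    def test_out_of_range_rejected(self, radial, angle):
        with pytest.raises(sd.SurveyDataError):
            rs.perpendicular_distance(radial, angle)

    @given(
        r1=st.floats(0, 1e4),
        dr=st.floats(0, 1e4),
        a1=st.floats(0, 90),
        da=st.floats(0, 90),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_both_arguments(self, r1, dr, a1, da):
        a2 = min(a1 + da, 90.0)
        assert rs.perpendicular_distance(r1 + dr, a1) >= rs.perpendicular_distance(r1, a1) - 1e-9
        assert rs.perpendicular_distance(r1, a2) >= rs.perpendicular_distance(r1, a1) - 1e-9


class TestRecordValidation:
    def test_line_transect_with_margin_habitat_rejected(self):
        with pytest.raises(sd.SurveyDataError):
            rs.TransectRecord("t1", "line", 2.0, "downstream", "river_margin")

    def test_strip_transect_with_channel_center_habitat_rejected(self):
        with pytest.raises(sd.SurveyDataError):
            rs.TransectRecord("t1", "strip", 2.0, "downstream", "river_channel")

    def test_nonpositive_length_rejected(self):
        with pytest.raises(sd.SurveyDataError):
            rs.TransectRecord("t1", "line", 0.0, "downstream", "river_channel")

    def test_sighting_derives_perpendicular_distance(self):
        s = rs.SightingRecord("s1", "t1", "bow", 100.0, 30.0, 1, "river_channel", "downstream")
        assert s.perp_distance_m == pytest.approx(50.0)

    def test_bow_sighting_cannot_be_duplicate(self):
        with pytest.raises(sd.SurveyDataError):
            rs.SightingRecord(
                "s1", "t1", "bow", 10.0, 10.0, 1, "river_channel", "downstream", duplicate_of="x"
            )

    def test_area_table_rejects_nonpositive_area(self):
        with pytest.raises(sd.SurveyDataError):
            rs.AreaTable({("river_channel", "downstream"): 0.0})

    def test_config_rejects_p2_above_p1(self):
        with pytest.raises(sd.SurveyDataError):
            rs.AnalysisConfig(p1=0.5, p2=0.9)


class TestReaders:
    def test_minimal_round_trip(self, tmp_path):
        effort = tmp_path / "effort.csv"
        sightings = tmp_path / "sightings.csv"
        effort.write_text(
            "transect_id,kind,length_km,stratum,habitat\n"
            "L1,line,5.0,downstream,river_channel\n"
            "S1,strip,4.0,upstream,river_margin\n"
        )
        sightings.write_text(
            "sighting_id,transect_id,platform,radial_distance_m,radial_angle_deg,"
            "shore_band,group_size,habitat,stratum,duplicate_of\n"
            "a,L1,bow,100,30,,2,river_channel,downstream,\n"
        )
        transects, records = rs.read_survey(effort, sightings)
        assert len(transects) == 2 and len(records) == 1
        assert records[0].perp_distance_m == pytest.approx(50.0)

    def test_unknown_transect_reference_names_the_id(self, tmp_path, tiny_survey):
        transects, _ = tiny_survey
        sightings = tmp_path / "sightings.csv"
        sightings.write_text(
            "sighting_id,transect_id,platform,radial_distance_m,radial_angle_deg,"
            "shore_band,group_size,habitat,stratum,duplicate_of\n"
            "a,GHOST,bow,100,30,,2,river_channel,downstream,\n"
        )
        with pytest.raises(sd.SurveyDataError, match="GHOST"):
            sd.read_sightings(sightings, transects=transects)

    def test_unknown_habitat_label_reports_row_number(self, tmp_path):
        effort = tmp_path / "effort.csv"
        effort.write_text(
            "transect_id,kind,length_km,stratum,habitat\nL1,line,5.0,downstream,swamp\n"
        )
        with pytest.raises(sd.SurveyDataError, match="row 2"):
            sd.read_effort(effort)

    def test_missing_column_rejected(self, tmp_path):
        effort = tmp_path / "effort.csv"
        effort.write_text("transect_id,kind,stratum,habitat\nL1,line,downstream,river_channel\n")
        with pytest.raises(sd.SurveyDataError, match="length_km"):
            sd.read_effort(effort)

    def test_simulated_survey_round_trips_losslessly(self, tmp_path):
        scenario = rs.demo_scenario(seed=7)
        transects, sightings, _ = rs.simulate_survey(scenario)
        rs.write_survey(transects, sightings, tmp_path / "e.csv", tmp_path / "s.csv")
        transects2, sightings2 = rs.read_survey(tmp_path / "e.csv", tmp_path / "s.csv")
        assert transects2 == transects
        for a, b in zip(sightings2, sightings):
            assert a.sighting_id == b.sighting_id
            assert a.duplicate_of == b.duplicate_of
            assert a.shore_band == b.shore_band
            assert a.perp_distance_m == pytest.approx(b.perp_distance_m, rel=1e-9)


class TestEffortSummary:
    def test_survey_scale_totals(self):
        # effort shaped like the 2014 Tocantins survey: 276.6 km of line and
        # 309.3 km of strip effort sum to 585.9 km
        transects = [
            rs.TransectRecord("L1", "line", 276.6, "downstream", "river_channel"),
            rs.TransectRecord("S1", "strip", 309.3, "upstream", "river_margin"),
        ]
        summary = rs.summarize_effort(transects, [])
        total = summary[summary["stratum"] == "TOTAL"].iloc[0]
        assert total["length_km"] == pytest.approx(585.9)
        assert total["n_transects"] == 2

    def test_empty_survey_is_all_zeros(self):
        summary = rs.summarize_effort([], [])
        total = summary.iloc[-1]
        assert total["length_km"] == 0.0 and total["n_sightings"] == 0

    def test_simulator_totals_match_effort_plan(self):
        scenario = rs.demo_scenario(seed=3)
        transects, sightings, truth = rs.simulate_survey(scenario)
        summary = rs.summarize_effort(transects, sightings)
        planned = sum(e.n_transects * e.transect_length_km for e in scenario.effort_plan)
        total = summary[summary["stratum"] == "TOTAL"].iloc[0]
        assert total["length_km"] == pytest.approx(planned, rel=1e-9)
        assert total["n_transects"] == sum(e.n_transects for e in scenario.effort_plan)
        # sightings deduplicate to the detected groups in the truth table
        detected = int((truth["detected_bow"] | truth["detected_stern"]).sum())
        assert total["n_sightings"] == detected

    def test_totals_equal_sum_of_parts(self):
        scenario = rs.demo_scenario(seed=5)
        transects, sightings, _ = rs.simulate_survey(scenario)
        summary = rs.summarize_effort(transects, sightings)
        parts = summary[summary["stratum"] != "TOTAL"]
        total = summary[summary["stratum"] == "TOTAL"].iloc[0]
        assert total["length_km"] == pytest.approx(parts["length_km"].sum(), rel=1e-9)
        assert total["n_sightings"] == parts["n_sightings"].sum()


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = rs.AnalysisConfig(truncation_m=250.0, seed=9)
        path = tmp_path / "config.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert rs.AnalysisConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("truncation_m: 300\nbogus_knob: 1\n")
        with pytest.raises(sd.SurveyDataError, match="bogus_knob"):
            rs.AnalysisConfig.from_yaml(path)
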