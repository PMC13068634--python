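import math

import numpy as np
import pandas as pd
import pytest

from senmorph.errors import ConfigError
from senmorph.gating import classify_frame, fit_gating_model
from senmorph.morphometry import measure_labelmask, records_to_frame
from senmorph.multiphenotype import detect_puncta
from senmorph.synthetic import (
    CONDITION_PRESETS,
    SyntheticScenario,
    generate_condition,
    generate_control_population,
    generate_timelapse,
    render_images,
)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        a = generate_control_population(200, seed=42)
        b = generate_control_population(200, seed=42)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_different_seed_differs(self):
        a = generate_control_population(200, seed=1)
        b = generate_control_population(200, seed=2)
        assert not a.frame["area"].equals(b.frame["area"])

    def test_substreams_isolated(self):
        # the fluorescence stream must not perturb geometry
        s1 = SyntheticScenario(seed=5, n_per_condition=50)
        s2 = SyntheticScenario(seed=5, n_per_condition=50)
        p1 = generate_condition(s1, "day5")
        p2 = generate_condition(s2, "day5")
        assert np.array_equal(p1.frame["area"], p2.frame["area"])

    def test_timelapse_deterministic(self):
        t1 = generate_timelapse(SyntheticScenario(seed=8, n_tracks=10, frames=5))
        t2 = generate_timelapse(SyntheticScenario(seed=8, n_tracks=10, frames=5))
        pd.testing.assert_frame_equal(t1.records, t2.records)
        pd.testing.assert_frame_equal(t1.transition_log, t2.transition_log)


class TestControlPopulation:
    def test_self_gated_controls_mostly_normal(self, control_population, control_model):
        classified = classify_frame(control_population.frame, control_model)
        assert (classified["morpho_class"] == "N").mean() >= 0.90

    def test_mean_area_matches_configured_lognormal_mean(self, control_population):
        scenario = control_population.scenario
        model = scenario.shape_models["N"]
        expected = model.area_mean * scenario.nucleus_area_scale
        sd = expected * math.sqrt(math.exp(model.area_sigma_log**2) - 1)
        se = sd / math.sqrt(len(control_population.frame))
        assert abs(control_population.frame["area"].mean() - expected) < 3 * se

    def test_unimodal_irregularity_is_low(self, control_population):
        assert control_population.frame["irregularity"].median() < 1.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ConfigError):
            generate_control_population(0, seed=1)


class TestGenerateCondition:
    def test_pure_f_mixture_recovered_as_large_regular(self):
        scenario = SyntheticScenario(seed=14, n_per_condition=300)
        pop = generate_condition(scenario, "pure_f",
                                 mixture={"N": 0.0, "E": 0.0, "F": 1.0, "small": 0.0})
        control = generate_control_population(300, seed=15, compartment="cell")
        model = fit_gating_model(
            control.frame,
            all_records=pd.concat([control.frame, pop.frame], ignore_index=True))
        classified = classify_frame(pop.frame, model)
        assert (classified["morpho_class"] == "LR").mean() >= 0.90

    def test_per_state_puncta_means_match_poisson_parameters(self):
        scenario = SyntheticScenario(seed=16, n_per_condition=600)
        pop = generate_condition(scenario, "day5",
                                 mixture={"N": 0.0, "E": 0.5, "F": 0.5, "small": 0.0})
        truth = pop.ground_truth
        for state, lam in (("E", 8.0), ("F", 1.0)):
            counts = truth.loc[truth["state"] == state, "puncta_count"]
            se = math.sqrt(lam / len(counts))
            assert abs(counts.mean() - lam) < 3 * se

    def test_day12_preset_has_small_dividing_subpopulation(self):
        scenario = SyntheticScenario(seed=18, n_per_condition=400)
        pop = generate_condition(scenario, "day12")
        truth = pop.ground_truth
        small = truth[truth["state"] == "small"]
        assert len(small) > 0
        assert (small["divisions"] >= 3).all()
        control_mean = scenario.shape_models["N"].area_mean
        assert (small["true_area"] < control_mean).all()

    def test_exact_composition_matches_mixture(self):
        scenario = SyntheticScenario(seed=19, n_per_condition=200)
        pop = generate_condition(scenario, "day5",
                                 mixture={"N": 0.6, "E": 0.15, "F": 0.25, "small": 0.0})
        counts = pop.ground_truth["state"].value_counts()
        assert counts["N"] == 120 and counts["F"] == 50 and counts["E"] == 30

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticScenario(seed=1, state_mixture={"N": 0.5, "E": 0.2,
                                                     "F": 0.2, "small": 0.0})

    def test_presets_cover_treatment_time_course(self):
        assert set(CONDITION_PRESETS) == {"control", "day5", "day12", "day19"}
        # F-state accumulates over time, E-state declines after its early peak
        assert CONDITION_PRESETS["day19"]["F"] > CONDITION_PRESETS["day5"]["F"]
        assert CONDITION_PRESETS["day5"]["E"] > CONDITION_PRESETS["day19"]["E"]


class TestTimelapse:
    def test_identity_matrix_produces_no_transitions(self):
        scenario = SyntheticScenario(
            seed=20, n_tracks=20, frames=6,
            transition_matrix={
                "N": {"N": 1.0, "E": 0.0, "F": 0.0},
                "E": {"N": 0.0, "E": 1.0, "F": 0.0},
                "F": {"N": 0.0, "E": 0.0, "F": 1.0},
            })
        tl = generate_timelapse(scenario)
        assert tl.transition_log.empty

    def test_logged_frequencies_match_matrix_within_three_se(self):
        scenario = SyntheticScenario(seed=42, n_tracks=100, frames=10)
        tl = generate_timelapse(scenario)
        exposure = tl.state_log[tl.state_log["frame"] < scenario.frames - 1]
        for src, dst, p in (("E", "F", 0.40), ("F", "E", 0.05)):
            n_src = (exposure["state"] == src).sum()
            k = len(tl.transition_log.query("from_state == @src and to_state == @dst"))
            se = math.sqrt(p * (1 - p) / n_src)
            assert abs(k / n_src - p) <= 3 * se

    def test_pure_f_tracks_drift_upward(self):
        scenario = SyntheticScenario(
            seed=23, n_tracks=40, frames=10,
            state_mixture={"N": 0.0, "E": 0.0, "F": 1.0, "small": 0.0},
            transition_matrix={
                "N": {"N": 1.0, "E": 0.0, "F": 0.0},
                "E": {"N": 0.0, "E": 1.0, "F": 0.0},
                "F": {"N": 0.0, "E": 0.0, "F": 1.0},
            })
        tl = generate_timelapse(scenario)
        slopes = []
        for _, grp in tl.records.groupby("track_id"):
            grp = grp.sort_values("timepoint")
            slopes.append(np.polyfit(np.arange(len(grp)), np.log(grp["area"]), 1)[0])
        assert np.mean(np.array(slopes) > 0) >= 0.95

    def test_transition_log_consistent_with_state_log(self):
        scenario = SyntheticScenario(seed=24, n_tracks=30, frames=8)
        tl = generate_timelapse(scenario)
        states = tl.state_log.pivot(index="track_id", columns="frame", values="state")
        n_changes = int((states.iloc[:, 1:].to_numpy() != states.iloc[:, :-1].to_numpy()).sum())
        assert n_changes == len(tl.transition_log)


class TestRenderImages:
    def test_single_disc_area_within_two_percent(self):
        t = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        r = 50.0
        from senmorph.morphometry import Compartment, ShapeObject

        scenario = SyntheticScenario(seed=25, n_per_condition=1)
        pop = generate_condition(scenario, "control",
                                 mixture={"N": 1.0, "E": 0.0, "F": 0.0, "small": 0.0})
        pop.shapes = [ShapeObject(object_id=pop.shapes[0].object_id,
                                  compartment=Compartment.CELL,
                                  polygon=np.column_stack([r * np.cos(t), r * np.sin(t)]))]
        rendered = render_images(pop, channels=())
        (rec,) = measure_labelmask(rendered.mask)
        assert rec.area == pytest.approx(math.pi * r**2, rel=0.02)

    def test_rendered_puncta_recovered_by_detection(self):
        scenario = SyntheticScenario(seed=26, n_per_condition=25)
        pop = generate_condition(scenario, "day5",
                                 mixture={"N": 0.0, "E": 1.0, "F": 0.0, "small": 0.0})
        rendered = render_images(pop, channels=("lc3",))
        from scipy import ndimage

        truth = pop.ground_truth.set_index("object_id")["puncta_count"]
        slices = ndimage.find_objects(rendered.mask)
        matches = 0
        for label, oid in rendered.label_map.items():
            sl = slices[label - 1]
            count, _ = detect_puncta(rendered.channels["lc3"][sl],
                                     rendered.mask[sl] == label,
                                     intensity_threshold=50)
            matches += count == int(truth[oid])
        assert matches >= 0.9 * len(rendered.label_map)

    def test_spot_log_matches_ground_truth_counts(self):
        scenario = SyntheticScenario(seed=27, n_per_condition=20)
        pop = generate_condition(scenario, "day5")
        rendered = render_images(pop, channels=("lc3",))
        logged = rendered.spots.groupby("object_id").size()
        truth = pop.ground_truth.set_index("object_id")["puncta_count"]
        for oid, n in truth.items():
            assert logged.get(oid, 0) == n

    def test_empty_population_yields_background_images(self):
        scenario = SyntheticScenario(seed=28, n_per_condition=1)
        pop = generate_condition(scenario, "control")
        pop.shapes, pop.records = [], []
        pop.ground_truth = pop.ground_truth.iloc[:0]
        rendered = render_images(pop, channels=("lc3",))
        assert rendered.mask.sum() == 0
        assert rendered.channels["lc3"].mean() == pytest.approx(10.0, abs=1.0)

    def test_labels_do_not_touch_borders_or_each_other(self):
        scenario = SyntheticScenario(seed=29, n_per_condition=60)
        pop = generate_condition(scenario, "day5")
        rendered = render_images(pop, channels=())
        records = measure_labelmask(rendered.mask)
        assert len(records) == 60
        assert not any(r.edge_flag for r in records)


def test_scenario_yaml_round_trip(tmp_path):
    scenario = SyntheticScenario(seed=31, n_per_condition=77)
    path = tmp_path / "scenario.yaml"
    scenario.to_yaml(path)
    loaded = SyntheticScenario.from_yaml(path)
    assert loaded.seed == 31
    assert loaded.n_per_condition == 77
    assert loaded.shape_models["E"].n_spikes_range == (3, 6)
    a = generate_condition(scenario, "day5").frame
    b = generate_condition(loaded, "day5").frame
    pd.testing.assert_frame_equal(a, b)
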