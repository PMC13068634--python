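import numpy as np
import pandas as pd
import pytest

from senmorph.errors import InputError, UndefinedStatisticError
from senmorph.multiphenotype import (
    CellCyclePhase,
    background_cutoff,
    cfse_by_state,
    classify_autophagic,
    classify_fucci,
    classify_fucci_frame,
    correlate_marker_morphometry,
    detect_puncta,
    median_split_by_circularity,
    percent_autophagic,
    state_phase_contingency,
)


class TestFucci:
    @pytest.mark.parametrize("red,green,expected", [
        (1000, 10, CellCyclePhase.G1),      # red nuclei
        (500, 500, CellCyclePhase.S),       # yellow (double positive)
        (10, 1000, CellCyclePhase.G2M),     # green nuclei
        (0, 0, CellCyclePhase.UNCLASSIFIED),
        (100, 100, CellCyclePhase.UNCLASSIFIED),  # ties resolve to not-above
    ])
    def test_phase_calls(self, red, green, expected):
        assert classify_fucci(red, green, red_cut=100, green_cut=100) is expected

    def test_negative_intensity_rejected(self):
        with pytest.raises(InputError):
            classify_fucci(-1, 10, 100, 100)

    def test_noise_free_calls_match_generator_labels_exactly(self):
        from senmorph.synthetic import SyntheticScenario, generate_condition

        scenario = SyntheticScenario(seed=9, n_per_condition=400,
                                     intensity_noise_frac=0.0)
        pop = generate_condition(scenario, condition="day5")
        frame = classify_fucci_frame(pop.frame, red_cut=50, green_cut=50)
        truth = pop.ground_truth.set_index("object_id")["phase"]
        assert (frame.set_index("object_id")["phase"] == truth).all()

    def test_ten_percent_noise_accuracy_at_least_95(self):
        from senmorph.synthetic import SyntheticScenario, generate_condition

        scenario = SyntheticScenario(seed=10, n_per_condition=400,
                                     intensity_noise_frac=0.10)
        pop = generate_condition(scenario, condition="day5")
        frame = classify_fucci_frame(pop.frame, red_cut=50, green_cut=50)
        truth = pop.ground_truth.set_index("object_id")["phase"]
        accuracy = (frame.set_index("object_id")["phase"] == truth).mean()
        assert accuracy >= 0.95


class TestPuncta:
    @staticmethod
    def _cell_with_spots(spots, shape=(80, 80), radius=30, amp=200.0, sigma=1.5):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        mask = ((xx - shape[1] / 2) ** 2 + (yy - shape[0] / 2) ** 2) <= radius**2
        img = np.full(shape, 10.0)
        for (r, c) in spots:
            img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
        return img, mask

    def test_seven_rendered_spots_counted(self):
        spots = [(20, 20), (20, 40), (20, 60), (40, 20), (40, 60), (60, 40), (55, 55)]
        img, mask = self._cell_with_spots(spots)
        count, area = detect_puncta(img, mask, intensity_threshold=50)
        assert count == 7
        assert area > 0

    def test_uniform_background_yields_zero(self):
        img, mask = self._cell_with_spots([])
        assert detect_puncta(img, mask, intensity_threshold=50) == (0, 0.0)

    def test_overlapping_spots_merge_to_one_component(self):
        img, mask = self._cell_with_spots([(40, 38), (40, 42)])
        count, _ = detect_puncta(img, mask, intensity_threshold=50)
        assert count == 1

    def test_empty_mask_yields_zero(self):
        img, _ = self._cell_with_spots([(40, 40)])
        assert detect_puncta(img, np.zeros_like(img, dtype=bool), 50) == (0, 0.0)

    def test_total_area_equals_component_pixel_sum(self):
        img, mask = self._cell_with_spots([(30, 30), (50, 50)])
        thr = 50.0
        count, area = detect_puncta(img, mask, thr)
        from scipy import ndimage

        labels, n = ndimage.label((img > thr) & mask)
        brute = sum(int((labels == i).sum()) for i in range(1, n + 1)
                    if 3 <= (labels == i).sum() <= 400)
        assert area == pytest.approx(float(brute))
        assert count == 2

    def test_pixel_size_scales_area(self):
        img, mask = self._cell_with_spots([(40, 40)])
        _, a1 = detect_puncta(img, mask, 50, pixel_size=1.0)
        _, a2 = detect_puncta(img, mask, 50, pixel_size=0.5)
        assert a2 == pytest.approx(a1 * 0.25)


class TestAutophagicCalls:
    @pytest.mark.parametrize("count,expected", [(5, True), (4, False), (0, False), (12, True)])
    def test_five_dot_rule(self, count, expected):
        assert classify_autophagic(count) is expected

    def test_percent_simple_fraction(self):
        frame = pd.DataFrame({"puncta_count": [6] * 3 + [0] * 7, "condition": "tmz"})
        out = percent_autophagic(frame, by=("condition",))
        assert out.loc[0, "percent_autophagic"] == pytest.approx(30.0)

    def test_e_state_more_autophagic_than_f_state(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({
            "puncta_count": np.concatenate([rng.poisson(8, 200), rng.poisson(1, 200)]),
            "condensed_state": ["E"] * 200 + ["F"] * 200,
        })
        out = percent_autophagic(frame, by=("condensed_state",)).set_index("condensed_state")
        assert out.loc["E", "percent_autophagic"] > out.loc["F", "percent_autophagic"]

    def test_all_zero_cohort_is_zero_percent(self):
        frame = pd.DataFrame({"puncta_count": [0] * 10})
        out = percent_autophagic(frame, by=())
        assert out.loc[0, "percent_autophagic"] == 0.0

    def test_empty_groups_are_missing_not_zero(self):
        frame = pd.DataFrame({"puncta_count": [6, 0], "condition": ["a", "a"]})
        out = percent_autophagic(frame, by=("condition",))
        assert set(out["condition"]) == {"a"}


class TestMedianSplit:
    def test_even_split(self):
        frame = pd.DataFrame({"circularity": [0.2, 0.4, 0.6, 0.8],
                              "marker": [1.0, 2.0, 3.0, 4.0]})
        by_circ, _ = median_split_by_circularity(frame, "marker")
        assert sorted(frame.loc[by_circ.groups == "low", "circularity"]) == [0.2, 0.4]
        assert sorted(frame.loc[by_circ.groups == "high", "circularity"]) == [0.6, 0.8]

    def test_low_circularity_group_carries_higher_marker_when_e_enriched(self):
        # p16-like marker twice as high in irregular (low-circularity) cells
        rng = np.random.default_rng(12)
        circ = np.concatenate([rng.uniform(0.2, 0.45, 150), rng.uniform(0.7, 0.95, 150)])
        marker = np.concatenate([rng.lognormal(np.log(400), 0.2, 150),
                                 rng.lognormal(np.log(200), 0.2, 150)])
        frame = pd.DataFrame({"circularity": circ, "marker": marker})
        by_circ, by_marker = median_split_by_circularity(frame, "marker")
        s = by_circ.summary.set_index("circularity_group")
        assert s.loc["low", "mean"] > s.loc["high", "mean"]
        # mirrored split: high-marker cells are less circular
        m = by_marker.summary.set_index("marker_group")
        assert m.loc["high", "mean"] < m.loc["low", "mean"]

    def test_all_ties_go_high_with_warning(self):
        frame = pd.DataFrame({"circularity": [0.5] * 4, "marker": [1, 2, 3, 4.0]})
        with pytest.warns(UserWarning, match="tied"):
            by_circ, _ = median_split_by_circularity(frame, "marker")
        assert (by_circ.groups == "high").all()

    def test_partition_is_exact(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"circularity": rng.uniform(0, 1, 101),
                              "marker": rng.lognormal(0, 1, 101)})
        by_circ, _ = median_split_by_circularity(frame, "marker")
        assert len(by_circ.groups) == len(frame)
        assert set(by_circ.groups.unique()) <= {"low", "high"}
        assert by_circ.summary["n"].sum() == len(frame)

    def test_single_record_rejected(self):
        with pytest.raises(InputError):
            median_split_by_circularity(
                pd.DataFrame({"circularity": [0.5], "marker": [1.0]}), "marker")


class TestCfse:
    def test_nondividing_cells_retain_eightfold_signal_after_three_divisions(self):
        # dye halves each division: 3 divisions -> 1/8 of the initial signal
        frame = pd.DataFrame({
            "sum_cfse": [2.0e5] * 50 + [2.0e5 / 8] * 50,
            "condensed_state": ["F"] * 50 + ["N"] * 50,
        })
        summary, tests = cfse_by_state(frame)
        med = summary.set_index("condensed_state")["median"]
        assert med["F"] / med["N"] == pytest.approx(8.0)
        assert (tests["p"] < 0.001).all()

    def test_single_state_summary_without_comparisons(self):
        frame = pd.DataFrame({"sum_cfse": [1.0, 2.0, 3.0], "condensed_state": "E"})
        summary, tests = cfse_by_state(frame)
        assert len(summary) == 1
        assert tests.empty

    def test_identical_distributions_ratio_near_one(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(10, 0.3, 400)
        frame = pd.DataFrame({"sum_cfse": np.concatenate([vals, vals]),
                              "condensed_state": ["E"] * 400 + ["F"] * 400})
        summary, _ = cfse_by_state(frame)
        med = summary.set_index("condensed_state")["median"]
        assert med["E"] / med["F"] == pytest.approx(1.0, rel=1e-12)


class TestMarkerCorrelation:
    @staticmethod
    def _frame(marker, irregularity, area):
        return pd.DataFrame({"marker": marker, "irregularity": irregularity, "area": area})

    def test_monotone_increasing_marker_positive_coefficient(self):
        irr = np.linspace(0.1, 5, 50)
        frame = self._frame(irr**2, irr, np.linspace(100, 5000, 50))
        out = correlate_marker_morphometry(frame, "marker").set_index("against")
        assert out.loc["irregularity", "coefficient"] > 0
        assert out.loc["irregularity", "sign"] == "positive"

    def test_monotone_decreasing_in_area_negative_coefficient(self):
        area = np.linspace(100, 5000, 50)
        frame = self._frame(1.0 / area, np.linspace(0.1, 5, 50), area)
        out = correlate_marker_morphometry(frame, "marker").set_index("against")
        assert out.loc["area", "coefficient"] < 0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(17)
        frame = self._frame(rng.normal(size=1000),
                            rng.normal(size=1000), rng.normal(size=1000) + 10)
        out = correlate_marker_morphometry(frame, "marker")
        assert (out["coefficient"].abs() < 0.1).all()

    def test_constant_marker_undefined(self):
        frame = self._frame(np.ones(20), np.linspace(0, 1, 20), np.linspace(1, 2, 20))
        with pytest.raises(UndefinedStatisticError):
            correlate_marker_morphometry(frame, "marker")

    def test_too_few_observations_rejected(self):
        frame = self._frame(np.arange(5.0), np.arange(5.0), np.arange(5.0) + 1)
        with pytest.raises(InputError):
            correlate_marker_morphometry(frame, "marker")


def test_background_cutoff_uses_background_pixels_only():
    img = np.full((40, 40), 5.0)
    mask = np.zeros((40, 40), dtype=int)
    mask[10:30, 10:30] = 1
    img[mask == 1] = 1000.0
    assert background_cutoff(img, mask) == pytest.approx(5.0)


def test_state_phase_contingency_counts():
    frame = pd.DataFrame({
        "condensed_state": ["E", "E", "F", "F", "F", "N"],
        "phase": ["G1", "G1", "G1", "G2M", "G1", "S"],
    })
    table = state_phase_contingency(frame)
    assert table.loc["E", "G1"] == 2
    assert table.loc["F", "G2M"] == 1
    assert int(table.to_numpy().sum()) == 6
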