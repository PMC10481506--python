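import itertools

import numpy as np
import pytest

import archlabel as al
from archlabel import fdi, labeling
from conftest import make_random_scene


def E_with(n, assignments):
    """Assignment matrix from {row: fdi_code}."""
    E = labeling.empty_assignment(n)
    for row, code in assignments.items():
        E[row, fdi.CODE_TO_COLUMN[code]] = 1
    return E


def coms_at(xs, z=1.0):
    return np.array([[x, 0.0, z] for x in xs])


class TestPenaltyF1Terms:
    def test_f11_zero_when_codes_unique(self):
        E = E_with(3, {0: 11, 1: 12, 2: 13})
        assert al.penalty_f11(E) == 0

    def test_f11_counts_duplicates(self):
        E = labeling.empty_assignment(2)
        E[:, fdi.CODE_TO_COLUMN[11]] = 1
        assert al.penalty_f11(E) == 1

    def test_f11_three_plus_two_on_two_codes(self):
        E = labeling.empty_assignment(5)
        E[0:3, fdi.CODE_TO_COLUMN[11]] = 1
        E[3:5, fdi.CODE_TO_COLUMN[24]] = 1
        assert al.penalty_f11(E) == 3

    def test_f12_right_side_of_watershed(self):
        E = E_with(1, {0: 11})
        assert al.penalty_f12(E, coms_at([0], z=2.0), watershed_z=1.0) == 0
        assert al.penalty_f12(E, coms_at([0], z=0.5), watershed_z=1.0) == 1

    def test_f12_counts_both_jaws(self):
        E = E_with(2, {0: 11, 1: 41})
        coms = np.array([[0, 0, -1.0], [0, 0, 1.0]])  # both on the wrong side
        assert al.penalty_f12(E, coms, watershed_z=0.0) == 2

    def test_f12_jaw_hint_overrides_watershed(self):
        E = E_with(1, {0: 11})
        coms = coms_at([0], z=-5.0)  # below watershed, but hinted upper
        assert (
            al.penalty_f12(E, coms, 0.0, jaws=np.array(["upper"])) == 0
        )
        assert (
            al.penalty_f12(E, coms, 0.0, jaws=np.array(["lower"])) == 1
        )

    def test_f13_counts_unassigned_rows(self):
        assert al.penalty_f13(E_with(3, {0: 11, 1: 12, 2: 13})) == 0
        assert al.penalty_f13(labeling.empty_assignment(3)) == 3
        assert al.penalty_f13(E_with(5, {0: 11, 1: 12, 2: 13})) == 2

    def test_f1_weighted_sum(self):
        # f11=1 (duplicate), f12=1 (wrong jaw), f13=1 (unassigned row)
        E = labeling.empty_assignment(3)
        E[0, fdi.CODE_TO_COLUMN[11]] = 1
        E[1, fdi.CODE_TO_COLUMN[11]] = 1
        coms = np.array([[0, 0, 2.0], [0, 0, -2.0], [0, 0, 2.0]])
        assert al.penalty_f1(E, coms, 0.0) == pytest.approx(1.11)

    def test_f1_zero_for_clean_assignment(self):
        E = E_with(1, {0: 11})
        assert al.penalty_f1(E, coms_at([0], z=1.0), 0.0) == 0.0

    def test_f1_custom_arithmetic(self):
        # f11=0, f12=2, f13=3 with default weights -> 0.23
        E = labeling.empty_assignment(5)
        E[0, fdi.CODE_TO_COLUMN[11]] = 1
        E[1, fdi.CODE_TO_COLUMN[41]] = 1
        coms = np.array(
            [[0, 0, -1.0], [0, 0, 1.0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]
        )
        assert al.penalty_f1(E, coms, 0.0) == pytest.approx(0.23)


class TestPenaltyF2:
    def test_consistent_order_has_no_inversions(self):
        E = E_with(3, {0: 18, 1: 17, 2: 16})  # arch indices 0,1,2
        assert al.penalty_f2(E, coms_at([0, 1, 2])) == 0

    def test_one_swapped_pair_counts_twice(self):
        E = E_with(2, {0: 17, 1: 18})  # arch order says 18 before 17
        assert al.penalty_f2(E, coms_at([0, 1])) == 2

    def test_full_reversal_counts_all_pairs(self):
        k = 5
        codes = [fdi.ARCH_ORDER["upper"][i] for i in range(k)]
        E = E_with(k, {i: codes[k - 1 - i] for i in range(k)})
        assert al.penalty_f2(E, coms_at(range(k))) == k * (k - 1)

    def test_quadrant_one_numbering_runs_against_the_arch(self):
        # 18 precedes 17 along the arch though 18 > 17 numerically
        E = E_with(2, {0: 18, 1: 17})
        assert al.penalty_f2(E, coms_at([0, 1])) == 0
        # raw-numeral comparison wrongly flags the pair as inverted
        assert al.penalty_f2(E, coms_at([0, 1]), order_by_arch_index=False) == 2


class TestPenaltyF3:
    def _prior(self, full_prior):
        return full_prior

    def test_exact_distance_contributes_zero(self, full_prior):
        d = full_prior.distance(11, 21)
        E = E_with(2, {0: 11, 1: 21})
        coms = np.array([[0, 0, 0], [d, 0, 0]])
        assert al.penalty_f3(E, coms, full_prior) == pytest.approx(0.0)

    def test_single_tooth_has_no_pairs(self, full_prior):
        E = E_with(1, {0: 14})
        assert al.penalty_f3(E, coms_at([0]), full_prior) == 0.0

    def test_one_mm_error_counted_on_ordered_pairs(self, full_prior):
        d = full_prior.distance(11, 21)
        E = E_with(2, {0: 11, 1: 21})
        coms = np.array([[0, 0, 0], [d + 1.0, 0, 0]])
        assert al.penalty_f3(E, coms, full_prior) == pytest.approx(2.0)

    def test_abs_metric_option(self, full_prior):
        d = full_prior.distance(11, 21)
        E = E_with(2, {0: 11, 1: 21})
        coms = np.array([[0, 0, 0], [d + 2.0, 0, 0]])
        assert al.penalty_f3(E, coms, full_prior, metric="abs") == pytest.approx(4.0)

    def test_missing_entry_skipped_with_warning(self, upper_template):
        prior = al.template_prior(upper_template)
        prior.d[fdi.CODE_TO_COLUMN[11], fdi.CODE_TO_COLUMN[21]] = np.nan
        prior.d[fdi.CODE_TO_COLUMN[21], fdi.CODE_TO_COLUMN[11]] = np.nan
        E = E_with(2, {0: 11, 1: 21})
        coms = coms_at([0, 50])
        with pytest.warns(UserWarning, match="missing prior"):
            assert al.penalty_f3(E, coms, prior) == 0.0
        with pytest.raises(al.PriorMissingError):
            al.penalty_f3(E, coms, prior, strict=True)


class TestStage1:
    def _hinted_scene(self, n, jaw="upper"):
        rng = np.random.default_rng(n)
        dets = [
            al.ToothDetection(
                i,
                np.array([i * 5.0, rng.uniform(0, 5), rng.uniform(0, 2)]),
                al.Box3([i * 5.0 - 1, -1, -1], [i * 5.0 + 1, 6, 3]),
            )
            for i in range(n)
        ]
        return al.build_scene(dets, jaw_hint=jaw)

    def test_single_detection_gets_valid_upper_code(self):
        scene = self._hinted_scene(1)
        E1 = al.stage1_greedy(scene)
        codes = labeling.assignment_codes(E1)
        assert codes[0] is not None and fdi.jaw_of(codes[0]) == "upper"
        assert al.penalty_f1(E1, scene.coms(), scene.watershed_z) <= 0.0 + 1e-12

    def test_sixteen_detections_fill_the_jaw(self):
        scene = self._hinted_scene(16)
        E1 = al.stage1_greedy(scene)
        assert al.penalty_f11(E1) == 0
        assert al.penalty_f13(E1) == 0
        codes = labeling.assignment_codes(E1)
        assert len({c for c in codes}) == 16

    def test_seventeenth_detection_left_unassigned(self):
        scene = self._hinted_scene(17)
        E1 = al.stage1_greedy(scene)
        assert al.penalty_f13(E1) == 1
        assert al.penalty_f11(E1) == 0
        jaws = np.array(["upper"] * 17)
        f1 = al.penalty_f1(E1, scene.coms(), scene.watershed_z, jaws=jaws)
        assert f1 == pytest.approx(0.01)

    def test_local_optimality_under_single_changes(self):
        rng = np.random.default_rng(42)
        scene = make_random_scene(rng, 4, 3)
        weights = al.PenaltyWeights()
        E1 = al.stage1_greedy(scene, weights)
        jaws = labeling._detection_jaws(scene, labeling.DEFAULT_CONFIG)
        base = al.penalty_f1(E1, scene.coms(), scene.watershed_z, weights, jaws)
        for row in range(len(E1)):
            for col in range(32):
                mod = E1.copy()
                mod[row] = 0
                if not E1[row, col]:
                    mod[row, col] = 1
                if (mod.sum(axis=1) > 1).any():
                    continue
                f1 = al.penalty_f1(
                    mod, scene.coms(), scene.watershed_z, weights, jaws
                )
                assert f1 >= base - 1e-12


class TestStage2:
    def test_sorted_input_unchanged(self):
        dets = [
            al.ToothDetection(
                i, np.array([x, 0, 1.0]), al.Box3([x - 1, -1, 0], [x + 1, 1, 2])
            )
            for i, x in enumerate([0.0, 5.0])
        ]
        scene = al.build_scene(dets, jaw_hint="upper")
        E1 = E_with(2, {0: 18, 1: 17})
        E2 = al.stage2_sort(E1, scene)
        assert np.array_equal(E1, E2)

    def test_swapped_pair_restored(self):
        dets = [
            al.ToothDetection(
                i, np.array([x, 0, 1.0]), al.Box3([x - 1, -1, 0], [x + 1, 1, 2])
            )
            for i, x in enumerate([0.0, 5.0])
        ]
        scene = al.build_scene(dets, jaw_hint="upper")
        E1 = E_with(2, {0: 17, 1: 18})
        E2 = al.stage2_sort(E1, scene)
        assert labeling.assignment_codes(E2) == [18, 17]
        assert al.penalty_f2(E2, scene.coms()) == 0

    def test_code_multiset_preserved_per_jaw(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            scene = make_random_scene(rng, rng.integers(1, 7), rng.integers(1, 7))
            E1 = al.stage1_greedy(scene)
            E2 = al.stage2_sort(E1, scene)
            for jaw in ("upper", "lower"):
                cols = fdi.JAW_COLUMNS[jaw]
                assert np.array_equal(
                    np.sort(np.nonzero(E1[:, cols])[0]),
                    np.sort(np.nonzero(E2[:, cols])[0]),
                )
                assert np.array_equal(
                    np.sort(np.nonzero(E1[:, cols])[1]),
                    np.sort(np.nonzero(E2[:, cols])[1]),
                )


class TestStage3:
    def test_full_jaw_is_forced_identity(self, upper_template, full_prior):
        scene = al.generate_scene(upper_template, al.SimulationConfig(seed=0))
        E1 = al.stage1_greedy(scene)
        E2 = al.stage2_sort(E1, scene)
        E3 = al.stage3_slots(E2, scene, full_prior)
        assert np.array_equal(E2, E3)

    def test_missing_tooth_slot_is_skipped(self, upper_template, full_prior):
        config = al.SimulationConfig(seed=1, missing_codes={16})
        scene = al.generate_scene(upper_template, config)
        result = al.label_teeth(scene, full_prior)
        assert 16 not in result.labels.values()
        assert all(
            result.labels[i] == scene.fdi_labels[i] for i in scene.fdi_labels
        )

    def test_f2_still_zero_and_f3_not_worse(self, full_prior):
        rng = np.random.default_rng(5)
        for trial in range(10):
            scene = make_random_scene(rng, rng.integers(1, 7), rng.integers(1, 7))
            E2 = al.stage2_sort(al.stage1_greedy(scene), scene)
            E3 = al.stage3_slots(E2, scene, full_prior)
            coms = scene.coms()
            assert al.penalty_f2(E3, coms) == 0
            assert al.penalty_f3(E3, coms, full_prior) <= al.penalty_f3(
                E2, coms, full_prior
            ) + 1e-9


class TestBruteForceOracle:
    def test_single_detection_matches_pipeline(self, full_prior):
        rng = np.random.default_rng(1)
        scene = make_random_scene(rng, 1, 0)
        E = al.brute_force_label(scene, full_prior)
        result = al.label_teeth(scene, full_prior)
        assert labeling.assignment_codes(E) == list(result.labels.values())

    def test_two_detections_snap_to_matching_pair(self, upper_template, full_prior):
        # two COMs exactly at the canine/first-molar slots of the template
        i1 = upper_template.slot_of(13)
        i2 = upper_template.slot_of(16)
        dets = [
            al.ToothDetection(
                n,
                upper_template.slot_positions[i].copy(),
                al.Box3(
                    upper_template.slot_positions[i] - 1,
                    upper_template.slot_positions[i] + 1,
                ),
            )
            for n, i in enumerate((i2, i1))
        ]
        scene = al.build_scene(dets, jaw_hint="upper")
        E = al.brute_force_label(scene, full_prior)
        assert set(labeling.assignment_codes(E)) == {13, 16}

    def test_oracle_equals_pipeline_on_small_scenes(self, full_prior):
        rng = np.random.default_rng(77)
        agree = 0
        for trial in range(15):
            scene = make_random_scene(rng, rng.integers(1, 4), rng.integers(1, 4))
            E = al.brute_force_label(scene, full_prior, max_n=4)
            result = al.label_teeth(scene, full_prior)
            coms = scene.coms()
            assert al.penalty_f3(E, coms, full_prior) == pytest.approx(
                result.penalties["f3"], rel=1e-9, abs=1e-9
            )
            agree += labeling.assignment_codes(E) == list(result.labels.values())
        assert agree >= 13  # ties may diverge; optima mostly unique

    def test_refuses_large_jaws(self, full_prior):
        rng = np.random.default_rng(2)
        scene = make_random_scene(rng, 5, 5)
        with pytest.raises(ValueError):
            al.brute_force_label(scene, full_prior, max_n=4)


class TestLabelTeeth:
    def test_noiseless_full_arch_fully_recovered(
        self, lower_template, full_prior
    ):
        scene = al.generate_scene(lower_template, al.SimulationConfig(seed=9))
        result = al.label_teeth(scene, full_prior)
        assert result.labels == scene.fdi_labels
        assert result.penalties == {"f1": 0.0, "f2": 0.0, "f3": pytest.approx(0.0)}

    def test_single_canine_scene(self, upper_template, full_prior):
        i = upper_template.slot_of(13)
        com = upper_template.slot_positions[i].copy()
        scene = al.build_scene(
            [al.ToothDetection(0, com, al.Box3(com - 1, com + 1))],
            jaw_hint="upper",
        )
        result = al.label_teeth(scene, full_prior)
        assert result.penalties["f3"] == 0.0
        assert sum(c is not None for c in result.labels.values()) == 1

    def test_deterministic_across_calls(self, upper_template, full_prior):
        config = al.SimulationConfig(seed=3, com_jitter_sigma=0.3)
        truth = al.generate_scene(upper_template, config)
        pred, _ = al.simulate_detector(truth, config)
        r1 = al.label_teeth(pred, full_prior)
        r2 = al.label_teeth(pred, full_prior)
        assert r1.labels == r2.labels
        assert np.array_equal(r1.E3, r2.E3)
        assert r1.penalties == r2.penalties

    def test_invariant_under_detection_permutation(
        self, upper_template, full_prior
    ):
        config = al.SimulationConfig(seed=6, com_jitter_sigma=0.5, missing_codes=2)
        scene = al.generate_scene(upper_template, config)
        result = al.label_teeth(scene, full_prior)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(scene))
        shuffled = al.build_scene(
            [scene.detections[i] for i in perm], jaw_hint=scene.jaw_hint
        )
        result2 = al.label_teeth(shuffled, full_prior)
        assert result2.labels == result.labels

    def test_bimaxillary_scene_uses_watershed(
        self, upper_template, lower_template, full_prior
    ):
        cfg = al.SimulationConfig(seed=8)
        upper = al.generate_scene(upper_template, cfg)
        lower = al.generate_scene(lower_template, cfg)
        merged = al.merge_scenes(upper, lower)
        assert merged.jaw_hint == "both"
        result = al.label_teeth(merged, full_prior)
        assert result.labels == merged.fdi_labels

    def test_empty_scene_rejected(self, full_prior):
        empty = al.ArchScene([], np.full(3, np.nan), float("nan"))
        with pytest.raises(ValueError):
            al.label_teeth(empty, full_prior)


class TestDistancePrior:
    def test_mean_of_one_observation(self):
        com = {11: np.array([0.0, 0, 0]), 21: np.array([5.0, 0, 0])}
        dets = [
            al.ToothDetection(i, c, al.Box3(c - 1, c + 1))
            for i, c in enumerate(com.values())
        ]
        scene = al.build_scene(
            dets, jaw_hint="upper", fdi_labels={0: 11, 1: 21}
        )
        prior = al.estimate_distance_prior([scene])
        assert prior.distance(11, 21) == pytest.approx(5.0)
        assert prior.distance(21, 11) == pytest.approx(5.0)
        assert prior.support[fdi.CODE_TO_COLUMN[11], fdi.CODE_TO_COLUMN[21]] == 1

    def test_mean_of_two_scenes(self):
        scenes = []
        for d in (4.0, 6.0):
            coms = [np.array([0.0, 0, 0]), np.array([d, 0, 0])]
            dets = [
                al.ToothDetection(i, c, al.Box3(c - 1, c + 1))
                for i, c in enumerate(coms)
            ]
            scenes.append(
                al.build_scene(dets, jaw_hint="upper", fdi_labels={0: 11, 1: 21})
            )
        prior = al.estimate_distance_prior(scenes)
        assert prior.distance(11, 21) == pytest.approx(5.0)
        assert prior.support[fdi.CODE_TO_COLUMN[11], fdi.CODE_TO_COLUMN[21]] == 2

    def test_noiseless_scenes_reproduce_template(self, upper_template):
        scenes = [
            al.generate_scene(upper_template, al.SimulationConfig(seed=s))
            for s in range(5)
        ]
        est = al.estimate_distance_prior(scenes)
        ref = al.template_prior(upper_template)
        cols = [fdi.CODE_TO_COLUMN[c] for c in upper_template.codes]
        assert np.allclose(
            est.d[np.ix_(cols, cols)], ref.d[np.ix_(cols, cols)], atol=1e-9
        )

    def test_unobserved_pairs_flagged_missing(self):
        com = {11: np.array([0.0, 0, 0]), 12: np.array([7.0, 0, 0])}
        dets = [
            al.ToothDetection(i, c, al.Box3(c - 1, c + 1))
            for i, c in enumerate(com.values())
        ]
        scene = al.build_scene(dets, jaw_hint="upper", fdi_labels={0: 11, 1: 12})
        prior = al.estimate_distance_prior([scene])
        assert prior.is_missing(11, 18)
        assert not prior.is_missing(11, 12)
        assert prior.distance(11, 11) == 0.0

    def test_symmetry_and_zero_diagonal(self, full_prior):
        d = full_prior.d
        assert np.allclose(d, d.T, equal_nan=True)
        assert np.all(np.diag(d) == 0.0)

    def test_csv_round_trip(self, tmp_path, full_prior):
        path = tmp_path / "prior.csv"
        full_prior.to_csv(path)
        back = al.DistancePrior.from_csv(path)
        assert np.allclose(back.d, full_prior.d, equal_nan=True)

    def test_csv_missing_entries_are_empty_cells(self, tmp_path, upper_template):
        prior = al.template_prior(upper_template)  # lower jaw all missing
        path = tmp_path / "prior.csv"
        prior.to_csv(path)
        text = path.read_text()
        assert ",," in text  # NaN serialized as empty cell
        back = al.DistancePrior.from_csv(path)
        assert back.is_missing(31, 32)
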