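"""Concept assignment: IOU, activation boxes, hit-rate aggregation."""

import numpy as np
import pytest

import _oracles
from convrules.adapter import ActivationSet
from convrules.concepts import (
    UNINTERPRETABLE,
    activation_box,
    assign_concepts,
    filter_interpretable,
)
from convrules.geometry import RegionBox, iou
from convrules.rules import induce_tree, tree_to_rules


class TestIou:
    def test_identical_and_disjoint(self):
        a = RegionBox("a", 0, 0, 4, 4)
        assert iou(a, RegionBox("b", 0, 0, 4, 4)) == 1.0
        assert iou(a, RegionBox("b", 10, 10, 14, 14)) == 0.0

    def test_hand_example_one_third(self):
        a = RegionBox("a", 0, 0, 4, 4)
        b = RegionBox("b", 2, 0, 6, 4)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_matches_pixel_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x0, y0 = rng.integers(0, 60, 2)
            a = RegionBox("a", x0, y0, x0 + int(rng.integers(1, 20)), y0 + int(rng.integers(1, 20)))
            x0, y0 = rng.integers(0, 60, 2)
            b = RegionBox("b", x0, y0, x0 + int(rng.integers(1, 20)), y0 + int(rng.integers(1, 20)))
            val = iou(a, b)
            assert val == pytest.approx(_oracles.pixel_iou(a, b), abs=0)
            assert val == iou(b, a)
            assert 0.0 <= val <= 1.0


class TestActivationBox:
    def test_all_zero_map_is_none(self):
        assert activation_box(np.zeros((4, 4)), 64) is None

    def test_single_cell_footprint_nearest(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        box = activation_box(m, 64, interpolation="nearest", level=0.5)
        assert (box.x0, box.y0, box.x1, box.y1) == (32, 16, 48, 32)

    def test_hot_corner_confined_to_quadrant(self):
        m = np.zeros((4, 4))
        m[:2, :2] = 1.0
        box = activation_box(m, 64, percentile=95)
        assert box.x1 <= 32 and box.y1 <= 32

    def test_secondary_blob_ignored(self):
        m = np.zeros((8, 8))
        m[1, 1] = 1.0  # primary peak
        m[6, 6] = 0.9  # secondary, above percentile but a separate component
        box = activation_box(m, 64, percentile=97, interpolation="nearest")
        assert box.x1 <= 24 and box.y1 <= 24

    def test_min_size_growth_shifts_inward_at_corner(self):
        m = np.zeros((16, 16))
        m[0, 15] = 1.0  # top-right corner unit
        box = activation_box(m, 64, interpolation="nearest", level=0.5, min_size=16)
        assert box.x1 - box.x0 >= 16 and box.y1 - box.y0 >= 16
        assert box.within(64)

    def test_non_finite_rejected(self):
        m = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            activation_box(m, 64)


def synthetic_activations(region_box, n_images=10, grid=16, image_size=64, silent_kernel=True):
    """Kernel 0 activates exactly on region_box's downscaled footprint;
    kernel 1 (optional) is silent."""
    scale = image_size // grid
    maps = np.zeros((n_images, 2 if silent_kernel else 1, grid, grid))
    maps[:, 0, region_box.y0 // scale : region_box.y1 // scale,
         region_box.x0 // scale : region_box.x1 // scale] = 1.0
    return ActivationSet(activations=maps, image_ids=np.arange(n_images))


class TestAssignConcepts:
    def setup_method(self):
        self.regions = {
            "R1": RegionBox("R1", 4, 4, 24, 24),
            "R2": RegionBox("R2", 40, 8, 60, 28),
            "R3": RegionBox("R3", 8, 40, 28, 60),
        }

    def test_always_matching_kernel_assigned_its_region(self):
        acts = synthetic_activations(self.regions["R1"])
        boxes = [self.regions] * 10
        cmap = assign_concepts(acts, boxes, image_size=64)
        assert cmap.assignments[0] == "R1"
        assert cmap.hit_rates.loc[0, "R1"] == 1.0

    def test_silent_kernel_uninterpretable(self):
        acts = synthetic_activations(self.regions["R2"])
        cmap = assign_concepts(acts, [self.regions] * 10, image_size=64)
        assert cmap.assignments[1] == UNINTERPRETABLE
        assert cmap.hit_rates.loc[1].max() == 0.0

    def test_too_many_highly_hit_regions_is_uninterpretable(self):
        # a kernel rotating over three regions hits each in a third of images
        scale = 4
        maps = np.zeros((9, 1, 16, 16))
        for i, name in enumerate(["R1", "R2", "R3"] * 3):
            b = self.regions[name]
            maps[i, 0, b.y0 // scale : b.y1 // scale, b.x0 // scale : b.x1 // scale] = 1.0
        acts = ActivationSet(activations=maps, image_ids=np.arange(9))
        boxes = [self.regions] * 9
        strict = assign_concepts(acts, boxes, image_size=64, hit_frac=0.2, max_regions=2)
        assert strict.assignments[0] == UNINTERPRETABLE
        assert len(strict.highly_hit[0]) == 3
        relaxed = assign_concepts(acts, boxes, image_size=64, hit_frac=0.2, max_regions=3)
        assert relaxed.assignments[0] in self.regions

    def test_raising_iou_min_never_raises_hit_rates(self):
        acts = synthetic_activations(self.regions["R3"], n_images=6)
        boxes = [self.regions] * 6
        low = assign_concepts(acts, boxes, image_size=64, iou_min=0.3)
        high = assign_concepts(acts, boxes, image_size=64, iou_min=0.6)
        assert (high.hit_rates.to_numpy() <= low.hit_rates.to_numpy() + 1e-12).all()

    def test_missing_boxes_reported(self):
        acts = synthetic_activations(self.regions["R1"], n_images=5)
        with pytest.raises(ValueError, match="missing region boxes"):
            assign_concepts(acts, [self.regions] * 3, image_size=64)


class TestFilterInterpretable:
    def test_identity_when_all_interpretable(self, literal_table, concept_map):
        interp = concept_map.interpretable_kernels()
        filtered = filter_interpretable(literal_table, concept_map)
        assert filtered.kernel_ids.tolist() == interp
        assert filtered.n_kernels == len(interp)

    def test_error_when_none_interpretable(self, literal_table):
        from convrules.concepts import ConceptMap
        import pandas as pd

        empty = ConceptMap(
            assignments={k: UNINTERPRETABLE for k in range(literal_table.n_kernels)},
            hit_rates=pd.DataFrame(np.zeros((literal_table.n_kernels, 1)), columns=["R"]),
            highly_hit={k: () for k in range(literal_table.n_kernels)},
        )
        with pytest.raises(ValueError, match="no interpretable"):
            filter_interpretable(literal_table, empty)

    def test_rules_on_filtered_table_avoid_uninterpretable(
        self, literal_table, concept_map, cnn_predictions
    ):
        filtered = filter_interpretable(literal_table, concept_map)
        tree = induce_tree(filtered, cnn_predictions, max_depth=3)
        used = tree_to_rules(tree).kernels_used()
        assert used <= set(concept_map.interpretable_kernels())
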