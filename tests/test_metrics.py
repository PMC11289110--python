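"""Pixel-wise and cyst-wise metrics, matching rules, size zones."""

import math

import numpy as np
import pytest

from cystseg.io import connected_components
from cystseg.metrics import (
    CystConfusion,
    MatchConfig,
    PixelConfusion,
    ZoneConfig,
    assign_zone,
    compute_metrics,
    compute_zone_boundaries,
    cyst_metrics,
    dt_iou_distribution,
    match_cysts,
    pixel_confusion,
    pixel_metrics,
    zone_attribution,
)
from oracles import max_matching_dt


def _mask_from_boxes(shape, boxes):
    mask = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1 in boxes:
        mask[r0:r1, c0:c1] = True
    return mask


class TestPixelConfusion:
    def test_identical_masks(self, rng):
        gt = rng.random((20, 20)) < 0.25
        pc = pixel_confusion(gt, gt)
        assert (pc.tp, pc.fp, pc.fn) == (gt.sum(), 0, 0)

    def test_three_labeled_pixels_hand_enumeration(self):
        gt = np.zeros((2, 2), dtype=bool)
        pred = np.zeros((2, 2), dtype=bool)
        gt[0, 0] = gt[0, 1] = True     # gt = {a, b}
        pred[0, 1] = pred[1, 0] = True  # pred = {b, c}
        pc = pixel_confusion(pred, gt)
        assert (pc.tp, pc.fp, pc.fn) == (1, 1, 1)
        iou, pr, re = pixel_metrics(pc)
        assert (iou, pr, re) == (1 / 3, 1 / 2, 1 / 2)

    def test_empty_masks_undefined_metrics(self):
        pc = pixel_confusion(np.zeros((4, 4), bool), np.zeros((4, 4), bool))
        assert all(math.isnan(m) for m in pixel_metrics(pc))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pixel_confusion(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_iou_identity_from_precision_recall(self, seed):
        rng = np.random.default_rng(seed)
        pc = pixel_confusion(rng.random((30, 30)) < 0.4, rng.random((30, 30)) < 0.4)
        iou, pr, re = pixel_metrics(pc)
        assert iou == pytest.approx(pr * re / (pr + re - pr * re), abs=1e-12)


class TestMatchingCases:
    """The canonical overlap configurations and their DT/MS/WR resolution."""

    def _counts(self, pred, gt, tau=0.0):
        cc = match_cysts(connected_components(pred), connected_components(gt),
                         MatchConfig(tau=tau))
        return cc.dt, cc.ms, cc.wr

    def test_exact_match(self):
        gt = _mask_from_boxes((20, 20), [(2, 8, 2, 8)])
        assert self._counts(gt.copy(), gt) == (1, 0, 0)

    def test_partial_overlap_is_detected(self):
        gt = _mask_from_boxes((20, 20), [(2, 8, 2, 8)])
        pred = _mask_from_boxes((20, 20), [(5, 11, 5, 11)])
        assert self._counts(pred, gt) == (1, 0, 0)

    def test_two_predictions_one_gt_is_one_dt_one_wr(self):
        gt = _mask_from_boxes((20, 20), [(5, 15, 3, 17)])
        pred = _mask_from_boxes((20, 20), [(6, 14, 4, 9), (6, 14, 11, 16)])
        assert self._counts(pred, gt) == (1, 0, 1)

    def test_one_prediction_two_gt_is_one_dt_one_ms(self):
        gt = _mask_from_boxes((20, 20), [(6, 14, 4, 9), (6, 14, 11, 16)])
        pred = _mask_from_boxes((20, 20), [(5, 15, 3, 17)])
        assert self._counts(pred, gt) == (1, 1, 0)

    def test_disjoint_prediction_and_gt(self):
        gt = _mask_from_boxes((20, 20), [(2, 6, 2, 6)])
        pred = _mask_from_boxes((20, 20), [(12, 16, 12, 16)])
        assert self._counts(pred, gt) == (0, 1, 1)

    def test_no_predictions_three_gt(self):
        gt = _mask_from_boxes((30, 30), [(2, 6, 2, 6), (10, 14, 10, 14), (20, 24, 20, 24)])
        assert self._counts(np.zeros((30, 30), bool), gt) == (0, 3, 0)

    def test_single_shared_pixel_counts_as_detection(self):
        gt = _mask_from_boxes((12, 12), [(2, 6, 2, 6)])
        pred = _mask_from_boxes((12, 12), [(5, 9, 5, 9)])  # overlap = 1 px
        assert self._counts(pred, gt) == (1, 0, 0)
        # but not under a stricter IoU rule
        assert self._counts(pred, gt, tau=0.5) == (0, 1, 1)


class TestMatchingProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((48, 48)) < 0.35
        gt = rng.random((48, 48)) < 0.35
        plc, glc = connected_components(pred), connected_components(gt)
        cc = match_cysts(plc, glc)
        assert cc.dt + cc.ms == glc.n_components
        assert cc.dt + cc.wr == plc.n_components
        assert cc.dt == len(cc.pairs)
        assert cc.dt <= min(plc.n_components, glc.n_components)

    def test_dt_non_increasing_in_tau(self, rng):
        pred = rng.random((48, 48)) < 0.35
        gt = rng.random((48, 48)) < 0.35
        plc, glc = connected_components(pred), connected_components(gt)
        taus = [0.0, 0.1, 0.3, 0.5, 0.7]
        dts = [match_cysts(plc, glc, MatchConfig(tau=t)).dt for t in taus]
        assert all(a >= b for a, b in zip(dts, dts[1:]))

    def _star_instance(self, rng):
        """Random instance whose overlap graph is a union of stars."""
        shape = (60, 60)
        pred = np.zeros(shape, bool)
        gt = np.zeros(shape, bool)
        cells = [(r, c) for r in range(3) for c in range(3)]
        rng.shuffle(cells)
        for cell in cells[:int(rng.integers(1, 6))]:
            r0, c0 = cell[0] * 20, cell[1] * 20
            center_on_gt = rng.random() < 0.5
            hub = gt if center_on_gt else pred
            leaves = pred if center_on_gt else gt
            hub[r0 + 4:r0 + 16, c0 + 4:c0 + 16] = True
            for i in range(int(rng.integers(0, 4))):
                rr = r0 + 2 + 4 * i
                leaves[rr:rr + 3, c0 + 2 + (i % 2) * 10: c0 + 8 + (i % 2) * 10] = True
        return pred, gt

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_optimal_on_star_overlap_graphs(self, seed):
        rng = np.random.default_rng(seed)
        while True:  # resample until within the exhaustive oracle bound
            pred, gt = self._star_instance(rng)
            plc, glc = connected_components(pred), connected_components(gt)
            if plc.n_components <= 6 and glc.n_components <= 6:
                break
        cc = match_cysts(plc, glc)
        overlap = np.zeros((plc.n_components, glc.n_components), dtype=bool)
        for pi in range(1, plc.n_components + 1):
            for gi in range(1, glc.n_components + 1):
                overlap[pi - 1, gi - 1] = ((plc.labels == pi) & (glc.labels == gi)).any()
        assert cc.dt == max_matching_dt(overlap)

    def test_perfect_prediction_gives_all_ones(self, five_cyst_scene):
        m = compute_metrics(five_cyst_scene.gt_mask, five_cyst_scene.gt_mask)
        assert all(v == 1.0 for v in m.as_dict().values())


class TestCystMetrics:
    def test_one_dt_one_ms(self):
        assert cyst_metrics(CystConfusion(1, 1, 0)) == (0.5, 1.0, 0.5)

    def test_all_zero_counts_undefined(self):
        assert all(math.isnan(v) for v in cyst_metrics(CystConfusion(0, 0, 0)))

    def test_perturber_counts(self):
        assert cyst_metrics(CystConfusion(3, 0, 3)) == (0.5, 0.5, 1.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CystConfusion(-1, 0, 0)
        with pytest.raises(ValueError):
            PixelConfusion(1, -2, 0)


class TestZones:
    def test_published_boundary_assignments(self):
        config = ZoneConfig()
        assert assign_zone(30.0, config) == 1
        assert assign_zone(1900.0, config) == 6
        assert assign_zone(34.7, config) == 2  # boundaries are left-closed
        assert assign_zone(100.0, config) == 4

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            assign_zone(0.0)

    def test_quantile_boundaries_give_equal_cardinality(self):
        areas = list(range(1, 13))
        bounds = compute_zone_boundaries(areas, 6)
        config = ZoneConfig(boundaries=bounds, microns_per_pixel=1.0)
        zones = [assign_zone(a, config) for a in areas]
        counts = np.bincount(zones, minlength=7)[1:]
        assert (counts == 2).all()

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_quantile_boundaries_balanced_within_one(self, n, rng):
        areas = rng.lognormal(4.0, 0.9, 97)
        bounds = compute_zone_boundaries(areas, n)
        config = ZoneConfig(boundaries=bounds, microns_per_pixel=1.0)
        counts = np.bincount([assign_zone(a, config) for a in areas], minlength=n + 1)[1:]
        assert counts.max() - counts.min() <= 1

    def test_degenerate_equal_areas_warn(self):
        with pytest.warns(UserWarning, match="collapse"):
            compute_zone_boundaries([5.0] * 12, 6)

    def test_single_zone_has_no_boundaries(self):
        assert compute_zone_boundaries([1, 2, 3], 1) == ()

    def test_fewer_areas_than_zones_rejected(self):
        with pytest.raises(ValueError):
            compute_zone_boundaries([1.0, 2.0], 6)


class TestZoneAttribution:
    def test_dt_counted_in_gt_zone_wr_in_predicted_zone(self):
        # gt component: 10x10 = 100 px; pred overlaps with 20x20 = 400 px
        shape = (64, 64)
        gt = _mask_from_boxes(shape, [(4, 14, 4, 14)])
        pred = _mask_from_boxes(shape, [(4, 24, 4, 24), (40, 44, 40, 44)])  # + 16 px WR
        plc, glc = connected_components(pred), connected_components(gt)
        cc = match_cysts(plc, glc)
        zones = ZoneConfig(boundaries=(50.0, 150.0, 500.0), microns_per_pixel=1.0)
        per_zone = zone_attribution(cc, plc, glc, zones)
        # DT sits in the gt-area zone (100 um2 -> zone 2), not the pred zone (400 -> 3)
        assert per_zone[2].dt == 1 and per_zone[3].dt == 0
        # WR sits in its predicted-area zone (16 um2 -> zone 1)
        assert per_zone[1].wr == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_zone_counts_conserve_global_counts(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((48, 48)) < 0.3
        gt = rng.random((48, 48)) < 0.3
        plc, glc = connected_components(pred), connected_components(gt)
        cc = match_cysts(plc, glc)
        per_zone = zone_attribution(cc, plc, glc, ZoneConfig(microns_per_pixel=1.0))
        assert sum(z.dt for z in per_zone.values()) == cc.dt
        assert sum(z.ms for z in per_zone.values()) == cc.ms
        assert sum(z.wr for z in per_zone.values()) == cc.wr


class TestDtIouDistribution:
    def test_fraction_above_threshold(self):
        class _C:
            def __init__(self, ious):
                from cystseg.metrics import MatchedPair
                self.pairs = tuple(MatchedPair(i + 1, i + 1, v, 1)
                                   for i, v in enumerate(ious))
        dist = dt_iou_distribution([_C([0.1, 0.5]), _C([0.9])])
        assert dist.fraction_above(0.2) == pytest.approx(2 / 3)
        assert dist.ious == (0.1, 0.5, 0.9)

    def test_identical_masks_give_unit_ious(self, five_cyst_scene):
        m = compute_metrics(five_cyst_scene.gt_mask, five_cyst_scene.gt_mask)
        dist = dt_iou_distribution([m.cyst])
        assert all(v == 1.0 for v in dist.ious)

    def test_empty_distribution(self):
        dist = dt_iou_distribution([])
        assert dist.ious == ()
        assert math.isnan(dist.fraction_above(0.5))
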