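"""CondOT paths, endpoint loss, and the unbalanced apo-holo coupling filter."""

import numpy as np
import pytest

from holoflow import cfm, synthetic
from holoflow.cfm import (
    CouplingThresholds,
    RejectReason,
    apo_holo_filter,
    cfm_endpoint_loss,
    condot_interpolate,
    sample_training_batch,
)
from holoflow.structures import InvalidInputError


class TestCondOT:
    def test_endpoints_exact(self):
        rng = np.random.default_rng(0)
        x0, x1 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert np.array_equal(condot_interpolate(x0, x1, 0.0), x0)
        assert np.array_equal(condot_interpolate(x0, x1, 1.0), x1)

    def test_quarter_point(self):
        out = condot_interpolate(
            np.array([[0.0, 0, 0]]), np.array([[2.0, 4, 6]]), 0.25
        )
        assert np.allclose(out, [[0.5, 1.0, 1.5]])

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            condot_interpolate(np.zeros((3, 3)), np.zeros((4, 3)), 0.5)

    def test_t_out_of_range(self):
        with pytest.raises(InvalidInputError):
            condot_interpolate(np.zeros((2, 3)), np.zeros((2, 3)), 1.5)


class TestEndpointLoss:
    def test_zero_when_exact(self):
        x = np.random.default_rng(1).normal(size=(5, 3))
        assert cfm_endpoint_loss(x, x) == 0.0

    def test_unit_offset_gives_one(self):
        x1 = np.random.default_rng(2).normal(size=(7, 3))
        pred = x1 + np.array([1.0, 0, 0])
        assert cfm_endpoint_loss(pred, x1) == pytest.approx(1.0)

    def test_mask_removes_contribution(self):
        x1 = np.zeros((4, 3))
        pred = np.zeros((4, 3))
        pred[0] = 1e6  # huge error on a masked-out atom
        mask = np.array([False, True, True, True])
        assert cfm_endpoint_loss(pred, x1, mask) == 0.0
        assert cfm_endpoint_loss(pred, x1, mask) == cfm_endpoint_loss(pred[1:], x1[1:])

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            cfm_endpoint_loss(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros(2, bool))

    def test_frame_dependence_contract(self):
        # translating both arguments together leaves the loss unchanged;
        # translating only one does not (the plain endpoint loss is
        # deliberately frame-dependent)
        rng = np.random.default_rng(3)
        pred, x1 = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        shift = np.array([2.0, -1.0, 0.5])
        both = cfm_endpoint_loss(pred + shift, x1 + shift)
        assert both == pytest.approx(cfm_endpoint_loss(pred, x1), rel=1e-12)
        assert cfm_endpoint_loss(pred + shift, x1) != pytest.approx(
            cfm_endpoint_loss(pred, x1), rel=1e-6
        )


class TestApoHoloFilter:
    def test_identical_pair_accepted(self, small_system):
        apo, holo, _ = small_system
        d = apo_holo_filter(holo, holo)
        assert d.accepted and d.reject_reason is RejectReason.NONE
        assert d.alignment.tm_score == pytest.approx(1.0)
        assert d.alignment.rmsd < 1e-9

    def test_heavy_deformation_rejected_for_tm(self):
        # shorter chain (smaller d0) so TM 0.6 is reachable at 3 A RMSD
        apo, holo = synthetic.make_pair_with_similarity(0.6, 3.0, n_residues=80, seed=9)
        d = apo_holo_filter(apo, holo)
        assert not d.accepted
        assert d.reject_reason is RejectReason.TM_BELOW

    def test_rmsd_exactly_at_bound_rejected(self):
        # the rejection rule is strict: c(x0,x1) >= c_RMSD rejects
        apo, holo = synthetic.make_pair_with_similarity(
            0.9, 5.0, seed=9, rmsd_band=(5.0, 5.0 + 1e-6)
        )
        d = apo_holo_filter(apo, holo)
        assert not d.accepted
        assert d.reject_reason is RejectReason.RMSD_ABOVE

    def test_length_criteria(self, small_system):
        apo, holo, _ = small_system
        thr = CouplingThresholds(min_residues=100)
        d = apo_holo_filter(holo, holo, thr)
        assert d.reject_reason is RejectReason.LENGTH

    def test_residue_mismatch_rejected(self, small_system, small_pair_pool):
        apo, holo, _ = small_system
        other_apo, _ = small_pair_pool[0]
        with pytest.raises(InvalidInputError):
            apo_holo_filter(other_apo, holo)

    def test_monotone_in_thresholds(self):
        # lowering tm_min or raising rmsd_max never converts accept->reject
        apo, holo = synthetic.make_pair_with_similarity(0.75, 4.0, seed=13)
        grid = [
            CouplingThresholds(tm_min=tm, rmsd_max=r)
            for tm in (0.9, 0.8, 0.7, 0.6, 0.5)
            for r in (3.0, 4.5, 6.0, 10.0)
        ]
        verdicts = {
            (t.tm_min, t.rmsd_max): apo_holo_filter(apo, holo, t).accepted for t in grid
        }
        for (tm1, r1), v1 in verdicts.items():
            for (tm2, r2), v2 in verdicts.items():
                if tm2 <= tm1 and r2 >= r1 and v1:
                    assert v2, f"relaxing ({tm1},{r1})->({tm2},{r2}) flipped accept"

    def test_invalid_thresholds(self):
        with pytest.raises(InvalidInputError):
            CouplingThresholds(tm_min=0.0)
        with pytest.raises(InvalidInputError):
            CouplingThresholds(rmsd_max=-1.0)


class TestTrainingBatch:
    def test_single_pair_batch(self, small_pair_pool):
        batch = sample_training_batch(small_pair_pool[:1], 4, seed=3)
        assert len(batch) == 4
        assert all(s.pair_index == 0 for s in batch)
        assert len({s.t for s in batch}) == 4

    def test_interpolation_invariant_bit_exact(self, small_pair_pool):
        for s in sample_training_batch(small_pair_pool, 8, seed=4):
            assert np.array_equal(s.xt, (1.0 - s.t) * s.x0 + s.t * s.x1)
            assert s.x0.shape == s.x1.shape == s.xt.shape
            assert np.array_equal(s.target, s.x1)

    def test_t_uniform_mean(self, small_pair_pool):
        batch = sample_training_batch(small_pair_pool[:1], 10_000, seed=5)
        assert 0.49 <= np.mean([s.t for s in batch]) <= 0.51

    def test_empty_pool_error(self):
        with pytest.raises(InvalidInputError, match="empty pair pool"):
            sample_training_batch([], 4, seed=0)

    def test_seeded_reproducibility(self, small_pair_pool):
        b1 = sample_training_batch(small_pair_pool, 6, seed=11)
        b2 = sample_training_batch(small_pair_pool, 6, seed=11)
        for s1, s2 in zip(b1, b2):
            assert s1.t == s2.t
            assert np.array_equal(s1.xt, s2.xt)

    def test_training_noise_applied_to_endpoint(self, small_pair_pool):
        apo, holo = small_pair_pool[0]
        batch = sample_training_batch(
            [(apo, holo)], 3, seed=6, config=cfm.BatchConfig(noise_sigma=1e-4)
        )
        for s in batch:
            dev = np.abs(s.x1 - holo.all_coords())
            assert 0 < dev.max() < 1e-2
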