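"""Upsampling counts, geometric transforms and class weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drpipe import balance, synth
from drpipe.balance import (
    class_weights,
    compute_balance_plan,
    flip_lr,
    flip_ud,
    remove_unnecessary_area,
    rotate_by_angle,
    rotate_random,
    upsample_class,
)
from drpipe.errors import InvalidCounts, MissingClass, NotSquare
from drpipe.imaging import inscribe_circle_mask


class TestBalancePlan:
    def test_reference_study_counts(self):
        plan = compute_balance_plan(15472, [1445, 3183, 553, 421])
        assert plan.add_per_image == (9, 3, 26, 35)
        assert plan.resulting_totals == (14450, 12732, 14931, 15156)

    def test_already_balanced_class_adds_nothing(self):
        plan = compute_balance_plan(100, [100])
        assert plan.add_per_image == (0,)
        assert plan.resulting_totals == (100,)

    def test_floor_division(self):
        plan = compute_balance_plan(100, [33])
        assert plan.add_per_image == (2,)
        assert plan.resulting_totals == (99,)

    @pytest.mark.parametrize("counts", [[0], [101]])
    def test_invalid_counts_raise(self, counts):
        with pytest.raises(InvalidCounts):
            compute_balance_plan(100, counts)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        n0=st.integers(1, 10**6),
        counts=st.lists(st.integers(1, 10**6), min_size=1, max_size=6),
    )
    def test_floor_correctness_property(self, n0, counts):
        counts = [min(c, n0) for c in counts]
        plan = compute_balance_plan(n0, counts)
        for c, add, total in zip(plan.class_counts, plan.add_per_image, plan.resulting_totals):
            assert total == c * (add + 1) <= n0
            assert 0 <= n0 - total < c


class TestFlips:
    def test_row_reversal(self):
        img = np.zeros((1, 3, 3), np.uint8)
        img[0, :, 0] = [10, 20, 30]
        assert list(flip_lr(img)[0, :, 0]) == [30, 20, 10]

    def test_involutions(self, fundus_image):
        assert np.array_equal(flip_lr(flip_lr(fundus_image)), fundus_image)
        assert np.array_equal(flip_ud(flip_ud(fundus_image)), fundus_image)

    def test_symmetric_image_unchanged(self):
        img = np.full((5, 5, 3), 42, np.uint8)
        assert np.array_equal(flip_lr(img), img)
        assert np.array_equal(flip_ud(img), img)

    def test_flip_lr_then_ud_is_half_turn(self, fundus_image):
        half_turn = fundus_image[::-1, ::-1]
        assert np.array_equal(flip_ud(flip_lr(fundus_image)), half_turn)


class TestRotation:
    def test_deterministic_under_seed(self, fundus_image):
        assert np.array_equal(rotate_random(fundus_image, 11), rotate_random(fundus_image, 11))

    def test_zero_image_stays_zero(self):
        img = np.zeros((8, 8, 3), np.uint8)
        assert np.all(rotate_random(img, 0) == 0)

    def test_centered_disc_preserved_up_to_interpolation(self):
        # a uniform centred disc is rotation-invariant; interior pixels
        # must survive within interpolation tolerance
        s = 41
        yy, xx = np.ogrid[:s, :s]
        c = (s - 1) / 2
        disc = ((yy - c) ** 2 + (xx - c) ** 2 <= (s / 4) ** 2)
        img = (np.broadcast_to(disc[:, :, None], (s, s, 3)) * 180).astype(np.uint8)
        rot = rotate_by_angle(img, 77.3)
        interior = ((yy - c) ** 2 + (xx - c) ** 2 <= (s / 4 - 2) ** 2)
        assert np.all(np.abs(rot[interior].astype(int) - 180) <= 2)

    def test_same_dimensions(self, fundus_image):
        assert rotate_random(fundus_image, 3).shape == fundus_image.shape


class TestRemoveUnnecessaryArea:
    def test_equals_circle_mask_on_squares(self, rng):
        img = rng.integers(0, 256, size=(9, 9, 3)).astype(np.uint8)
        assert np.array_equal(remove_unnecessary_area(img), inscribe_circle_mask(img))

    def test_rejects_non_square(self):
        with pytest.raises(NotSquare):
            remove_unnecessary_area(np.zeros((4, 6, 3), np.uint8))

    def test_idempotent(self, rng):
        img = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
        once = remove_unnecessary_area(img)
        assert np.array_equal(remove_unnecessary_area(once), once)

    def test_survivor_count_on_uniform_image(self):
        img = np.full((299, 299, 3), 10, np.uint8)
        out = remove_unnecessary_area(img)
        yy, xx = np.ogrid[:299, :299]
        inside = ((yy - 149) ** 2 + (xx - 149) ** 2 <= 149.5**2).sum()
        assert (out[:, :, 0] > 0).sum() == inside


class TestUpsampleClass:
    def test_output_count_matches_plan(self, rng, fundus_params):
        imgs = [synth.make_fundus(fundus_params, rng=rng) for _ in range(3)]
        out = upsample_class(imgs, 4, rng_seed=0, label=2)
        assert len(out) == 3 * (4 + 1)
        assert set(out.labels) == {2}

    def test_add_zero_returns_originals_only(self, fundus_image):
        out = upsample_class([fundus_image], 0)
        assert len(out) == 1
        assert np.array_equal(out.images[0], fundus_image)

    def test_transform_allocation_order(self, fundus_image):
        out = upsample_class([fundus_image], 5, rng_seed=1)
        tags = [p.transform for p in out.provenance]
        assert tags == ["source", "flip_lr", "flip_ud", "rotate", "rotate", "rotate"]
        angles = [p.angle_deg for p in out.provenance if p.transform == "rotate"]
        assert len(set(angles)) == 3  # independent draws

    def test_generated_images_are_remasked(self, fundus_image):
        masked = inscribe_circle_mask(fundus_image)
        out = upsample_class([masked], 3, rng_seed=5)
        for img in out.images[1:]:
            assert np.array_equal(remove_unnecessary_area(img), img)

    def test_provenance_traces_every_output(self, rng, fundus_params):
        imgs = [synth.make_fundus(fundus_params, rng=rng) for _ in range(4)]
        out = upsample_class(imgs, 3, rng_seed=2)
        sources = [p.source_index for p in out.provenance]
        assert sorted(set(sources)) == [0, 1, 2, 3]
        assert all(sources.count(i) == 4 for i in range(4))


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        labels = [0, 1, 2, 3, 4] * 10
        assert np.allclose(class_weights(labels).as_array(), 1.0)

    def test_study_proportions(self):
        counts = [15472, 1445, 3183, 553, 421]
        labels = np.repeat(np.arange(5), counts)
        w = class_weights(labels).as_array()
        # direct evaluation: 21074 / (5 * count_c)
        assert np.allclose(w, [0.2724, 2.9168, 1.3242, 7.6217, 10.0114], atol=5e-5)

    def test_missing_class_raises(self):
        with pytest.raises(MissingClass):
            class_weights([0, 1, 2, 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(counts=st.lists(st.integers(1, 500), min_size=5, max_size=5))
    def test_weighted_mean_is_one(self, counts):
        labels = np.repeat(np.arange(5), counts)
        w = class_weights(labels).as_array()
        assert np.isclose((w * np.bincount(labels)).sum(), labels.size)
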