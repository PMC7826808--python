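import math

import numpy as np
import pytest

from sitmap import (DEFAULT_ANGLES, GeometryParams, TemplateValues, build_bank,
                    build_variant, equalize_reward_sums, rotate_template)


class TestVariantConstruction:
    def test_default_geometry_offsets(self, geom, vals):
        tpl = build_variant(geom, vals, 1)
        sep = math.dist(tpl.left_hip_offset, tpl.right_hip_offset)
        assert abs(sep - 12.0) < 1e-9
        # caudal sits h px behind the hip midpoint
        mid = ((tpl.left_hip_offset[0] + tpl.right_hip_offset[0]) / 2,
               (tpl.left_hip_offset[1] + tpl.right_hip_offset[1]) / 2)
        assert abs(tpl.caudal_offset[0] - mid[0] - 3.0) < 1e-9
        assert abs(tpl.caudal_offset[1] - mid[1]) < 1e-9

    def test_penalty_values_bounded_by_slope_and_thickness(self, geom, vals):
        for variant in (1, 2, 3, 4):
            tpl = build_variant(geom, vals, variant)
            pen = tpl.values[tpl.values < 0]
            assert pen.size > 0
            assert np.all(pen >= vals.k * geom.c - 1e-12)
            assert np.all(pen < 0)

    def test_sign_partition_exhaustive(self, geom, vals):
        tpl = build_variant(geom, vals, 2)
        v = tpl.values
        reward, penalty, neutral = v > 0, v < 0, v == 0
        assert (reward.sum() + penalty.sum() + neutral.sum()) == v.size
        assert reward.any() and penalty.any() and neutral.any()

    def test_variant_strong_site_placement(self, geom, vals):
        # strong tier pixels sit where each variant expects the pressure peak
        def value_at(tpl, offset):
            r = int(round(tpl.anchor[0] + offset[0]))
            c = int(round(tpl.anchor[1] + offset[1]))
            return tpl.values[r, c]

        t1, t2, t3, t4 = (build_variant(geom, vals, v) for v in (1, 2, 3, 4))
        for t in (t1, t2):
            assert value_at(t, t.left_hip_offset) == vals.v_strong
        assert value_at(t2, t2.right_hip_offset) == vals.v_medium
        assert value_at(t3, t3.right_hip_offset) == vals.v_strong
        assert value_at(t3, t3.left_hip_offset) == vals.v_medium
        assert value_at(t4, t4.caudal_offset) == vals.v_strong
        assert value_at(t4, t4.left_hip_offset) == vals.v_medium

    def test_unknown_variant_rejected(self, geom, vals):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant(geom, vals, 5)

    @pytest.mark.parametrize("bad", [
        dict(r1=3, r2=3), dict(d=0), dict(c=-1),
    ])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            GeometryParams(**{**dict(r1=7, r2=3, d=12, c=4, h=3, l=9), **bad})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TemplateValues(v_weak=1, v_medium=5, v_strong=2)
        with pytest.raises(ValueError):
            TemplateValues(k=0.3)


class TestEqualization:
    def test_reward_sums_equal_after_equalization(self, geom, vals):
        eq = equalize_reward_sums([build_variant(geom, vals, v) for v in (1, 2, 3, 4)])
        sums = [t.reward_sum() for t in eq]
        assert max(abs(s - sums[0]) for s in sums) < 1e-9

    def test_identical_variant_gets_unit_scale(self, geom, vals):
        t1 = build_variant(geom, vals, 1)
        eq = equalize_reward_sums([t1, build_variant(geom, vals, 1)])
        np.testing.assert_array_equal(eq[1].values, t1.values)

    def test_scalars_match_independent_sums(self, geom, vals):
        raw = [build_variant(geom, vals, v) for v in (1, 2, 3, 4)]
        eq = equalize_reward_sums(raw)
        ref = float(sum(x for x in raw[0].values.ravel() if x > 0))
        for before, after in zip(raw, eq):
            s = float(sum(x for x in before.values.ravel() if x > 0))
            np.testing.assert_allclose(after.reward_scale, ref / s, atol=1e-12)

    def test_penalty_pixels_untouched(self, geom, vals):
        raw = [build_variant(geom, vals, v) for v in (1, 2, 3, 4)]
        eq = equalize_reward_sums(raw)
        for b, a in zip(raw, eq):
            np.testing.assert_array_equal(b.values[b.values < 0], a.values[a.values < 0])

    def test_degenerate_template_rejected(self, geom, vals):
        t = build_variant(geom, vals, 1)
        t.values = np.where(t.values > 0, 0.0, t.values)
        with pytest.raises(ValueError, match="degenerate template"):
            equalize_reward_sums([t])


class TestRotation:
    def test_zero_rotation_is_identity(self, geom, vals):
        t = build_variant(geom, vals, 2)
        r = rotate_template(t, 0.0)
        np.testing.assert_array_equal(r.values, t.values)
        assert r.anchor == t.anchor

    def test_offsets_match_rotation_matrix(self, geom, vals):
        t = build_variant(geom, vals, 1)
        for angle in (10.0, -25.0, 40.0):
            r = rotate_template(t, angle)
            th = math.radians(angle)
            for off, roff in ((t.left_hip_offset, r.left_hip_offset),
                              (t.right_hip_offset, r.right_hip_offset),
                              (t.caudal_offset, r.caudal_offset)):
                expect = (off[0] * math.cos(th) - off[1] * math.sin(th),
                          off[0] * math.sin(th) + off[1] * math.cos(th))
                assert math.dist(roff, expect) < 1e-9

    def test_separation_invariant_under_rotation(self, bank):
        for t in bank.templates:
            assert abs(math.dist(t.left_hip_offset, t.right_hip_offset) - 12.0) < 1e-6

    def test_sign_partition_preserved_at_every_angle(self, bank):
        for t in bank.templates:
            assert np.all((t.values > 0) | (t.values < 0) | (t.values == 0))
            assert (t.values > 0).any() and (t.values < 0).any()


class TestBank:
    def test_default_bank_has_36_templates(self, bank):
        assert len(bank) == 36
        assert len(bank.angles) == 9

    def test_single_angle_bank_has_4(self, geom, vals):
        assert len(build_bank(geom, vals, (0.0,))) == 4

    def test_reward_sums_equal_across_whole_bank(self, bank):
        sums = [t.reward_sum() for t in bank.templates]
        assert max(sums) - min(sums) < 1e-9

    def test_variant_major_angle_minor_ordering(self, bank):
        variants = [t.variant_id for t in bank.templates]
        assert variants == [v for v in (1, 2, 3, 4) for _ in range(9)]
        angles = [t.angle_deg for t in bank.templates[:9]]
        assert angles == list(DEFAULT_ANGLES)

    def test_rebuild_is_deterministic(self, geom, vals, bank):
        again = build_bank(geom, vals)
        for a, b in zip(bank.templates, again.templates):
            np.testing.assert_array_equal(a.values, b.values)

    def test_empty_angle_list_rejected(self, geom, vals):
        with pytest.raises(ValueError, match="no angles"):
            build_bank(geom, vals, ())
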