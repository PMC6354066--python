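"""Label propagation, locally-ranked fusion, and parcellation utilities."""

import warnings

import numpy as np
import pytest

from murivol.images import AffineTransform, LabeledImage, LabelInfo, LabelMap
from murivol.parcellation import (correct_bias, extract_volumes, fuse_labels,
                                  local_ncc, propagate_labels, qa_correct_mask,
                                  resample_image, split_hemispheres,
                                  total_brain_volume)


def tiny_map(data, spacing=0.3, labels=None):
    data = np.asarray(data)
    if labels is None:
        labels = {int(v): LabelInfo(f"s{v}", "GM") for v in np.unique(data) if v}
    return LabelMap(data, (spacing,) * 3, labels)


# ---------------------------------------------------------------------------
# bias correction


class TestCorrectBias:
    def test_flat_image_unchanged(self):
        img = LabeledImage(np.full((12, 12, 12), 50.0), (1, 1, 1))
        out = correct_bias(img, order=2)
        assert np.abs(out.data / img.data - 1).max() < 1e-6

    def test_linear_ramp_removed(self, rng):
        """A multiplicative linear ramp is estimated and divided out."""
        shape = (16, 16, 16)
        base = np.full(shape, 80.0)
        ramp = 1.0 + 0.2 * np.linspace(-0.5, 0.5, shape[0])[:, None, None]
        img = LabeledImage(base * ramp, (1, 1, 1))
        out = correct_bias(img, order=1)
        rel = out.data / base
        assert np.abs(rel - rel.mean()).max() < 0.01

    def test_order_zero_is_mean_preserving_identity(self):
        img = LabeledImage(np.random.default_rng(0).uniform(50, 100, (10, 10, 10)),
                           (1, 1, 1))
        out = correct_bias(img, order=0)
        assert np.allclose(out.data, img.data)

    def test_all_zero_image_raises(self):
        with pytest.raises(ValueError):
            correct_bias(LabeledImage(np.zeros((8, 8, 8)), (1, 1, 1)))


# ---------------------------------------------------------------------------
# propagation


class TestPropagateLabels:
    def test_identity_transform_is_noop(self):
        data = np.zeros((10, 10, 10), dtype=int)
        data[3:6, 3:6, 3:6] = 2
        lm = tiny_map(data)
        target = LabeledImage(np.zeros((10, 10, 10)), lm.spacing)
        out = propagate_labels(lm, AffineTransform.identity(), target)
        assert np.array_equal(out.data, data)

    def test_integer_translation_shifts_exactly(self):
        """A one-voxel pull-back shift moves labels by exactly one voxel."""
        data = np.zeros((10, 10, 10), dtype=int)
        data[3:6, 3:6, 3:6] = 1
        lm = tiny_map(data)
        target = LabeledImage(np.zeros((10, 10, 10)), lm.spacing)
        mat = np.eye(4)
        mat[0, 3] = lm.spacing[0]  # target voxel i samples atlas voxel i+1
        out = propagate_labels(lm, AffineTransform(mat), target)
        assert np.array_equal(out.data, np.roll(data, -1, axis=0))

    def test_out_of_field_gives_background_with_warning(self):
        data = np.ones((6, 6, 6), dtype=int)
        lm = tiny_map(data)
        target = LabeledImage(np.zeros((6, 6, 6)), lm.spacing)
        mat = np.eye(4)
        mat[:3, 3] = 100.0  # far outside the atlas extent
        with pytest.warns(UserWarning, match="background"):
            out = propagate_labels(lm, AffineTransform(mat), target)
        assert not out.data.any()

    def test_never_invents_label_ids(self, rng):
        data = rng.integers(0, 4, size=(9, 9, 9))
        lm = tiny_map(data)
        target = LabeledImage(np.zeros((12, 12, 12)), (0.21,) * 3)
        out = propagate_labels(lm, AffineTransform.identity(), target)
        assert set(np.unique(out.data)) <= set(np.unique(data))


# ---------------------------------------------------------------------------
# local NCC


def ncc_oracle(f, w, window):
    """Brute-force windowed Pearson correlation, borders clipped."""
    half = window // 2
    out = np.zeros(f.shape)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            for k in range(f.shape[2]):
                sl = tuple(slice(max(0, c - half), min(n, c + half + 1))
                           for c, n in zip((i, j, k), f.shape))
                a = f[sl].ravel()
                b = w[sl].ravel()
                va = a.var()
                vb = b.var()
                if va <= 0 or vb <= 0:
                    continue
                out[i, j, k] = np.clip(
                    ((a - a.mean()) * (b - b.mean())).mean() / np.sqrt(va * vb),
                    -1, 1)
    return out


class TestLocalNCC:
    def test_self_correlation_is_one(self, rng):
        f = LabeledImage(rng.normal(size=(9, 9, 9)), (1, 1, 1))
        r = local_ncc(f, f, window=3)
        assert np.allclose(r, 1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        f = LabeledImage(rng.normal(size=(9, 9, 9)), (1, 1, 1))
        g = LabeledImage(-f.data, f.spacing)
        assert np.allclose(local_ncc(f, g, window=3), -1.0)

    def test_matches_bruteforce_oracle(self, rng):
        f = rng.normal(size=(7, 7, 7))
        w = rng.normal(size=(7, 7, 7))
        got = local_ncc(LabeledImage(f, (1, 1, 1)), LabeledImage(w, (1, 1, 1)), 3)
        expect = ncc_oracle(f, w, 3)
        assert np.abs(got - expect).max() < 1e-10

    def test_constant_windows_score_zero(self):
        f = LabeledImage(np.zeros((8, 8, 8)), (1, 1, 1))
        w = LabeledImage(np.random.default_rng(1).normal(size=(8, 8, 8)), (1, 1, 1))
        assert np.all(local_ncc(f, w, 3) == 0.0)

    def test_bounded_and_symmetric(self, rng):
        f = rng.normal(size=(8, 8, 8))
        w = rng.normal(size=(8, 8, 8))
        a = local_ncc(LabeledImage(f, (1, 1, 1)), LabeledImage(w, (1, 1, 1)), 5)
        b = local_ncc(LabeledImage(w, (1, 1, 1)), LabeledImage(f, (1, 1, 1)), 5)
        assert np.all(np.abs(a) <= 1.0)
        assert np.allclose(a, b)

    def test_window_validation(self, rng):
        f = LabeledImage(rng.normal(size=(6, 6, 6)), (1, 1, 1))
        with pytest.raises(ValueError):
            local_ncc(f, f, window=4)
        with pytest.raises(ValueError):
            local_ncc(f, f, window=9)


# ---------------------------------------------------------------------------
# fusion


def fuse_oracle(labs, sims, top_k):
    """Independent per-voxel rank-then-mode with the documented tie rules."""
    shape = labs[0].shape
    out = np.zeros(shape, dtype=int)
    A = len(labs)
    for idx in np.ndindex(shape):
        ranked = sorted(range(A), key=lambda a: (-sims[a][idx], a))[:top_k]
        votes = {}
        for a in ranked:
            lab = labs[a][idx]
            cnt, ssum = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, ssum + sims[a][idx])
        best = sorted(votes.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
        out[idx] = best[0][0]
    return out


class TestFuseLabels:
    def test_unanimous_candidates(self, rng):
        data = rng.integers(0, 5, size=(8, 8, 8))
        maps = [tiny_map(data, labels={i: LabelInfo(f"s{i}", "GM") for i in range(1, 5)})
                for _ in range(4)]
        sims = [rng.random((8, 8, 8)) for _ in range(4)]
        out = fuse_labels(maps, sims, top_k=3)
        assert np.array_equal(out.data, data)

    @pytest.mark.parametrize("top_k", [1, 3, 5])
    def test_matches_rank_then_mode_oracle(self, rng, top_k):
        shape = (6, 6, 6)
        labs = [rng.integers(0, 4, size=shape) for _ in range(5)]
        sims = [rng.random(shape) for _ in range(5)]
        labels = {i: LabelInfo(f"s{i}", "GM") for i in range(1, 4)}
        maps = [tiny_map(l, labels=labels) for l in labs]
        out = fuse_labels(maps, sims, top_k=top_k)
        assert np.array_equal(out.data, fuse_oracle(labs, sims, top_k))

    def test_top_one_follows_best_similarity(self, rng):
        shape = (5, 5, 5)
        labs = [np.full(shape, 1), np.full(shape, 2)]
        sims = [rng.random(shape), rng.random(shape)]
        labels = {1: LabelInfo("a", "GM"), 2: LabelInfo("b", "GM")}
        out = fuse_labels([tiny_map(l, labels=labels) for l in labs], sims, top_k=1)
        expect = np.where(sims[0] >= sims[1], 1, 2)  # ties favor the first atlas
        assert np.array_equal(out.data, expect)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            fuse_labels([], [], 1)
        m = tiny_map(np.ones((4, 4, 4), dtype=int))
        with pytest.raises(ValueError):
            fuse_labels([m], [np.ones((5, 5, 5))], 1)
        with pytest.raises(ValueError):
            fuse_labels([m], [np.ones((4, 4, 4))], 2)


# ---------------------------------------------------------------------------
# QA, hemispheres, volumes, resampling


class TestQACorrectMask:
    def test_empty_mask_is_noop(self):
        lm = tiny_map(np.ones((5, 5, 5), dtype=int))
        out, removed = qa_correct_mask(lm, np.zeros((5, 5, 5), dtype=bool))
        assert np.array_equal(out.data, lm.data)
        assert removed == {}

    def test_removal_count_exact(self):
        data = np.zeros((6, 6, 6), dtype=int)
        data[0:3, 0:3, 0:3] = 1
        lm = tiny_map(data)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0, 0:2, 0:5] = True  # 6 voxels of label 1, 4 of background
        out, removed = qa_correct_mask(lm, mask)
        assert removed == {1: 6}
        assert (out.data == 1).sum() == 27 - 6

    def test_background_only_mask(self):
        data = np.zeros((5, 5, 5), dtype=int)
        data[2, 2, 2] = 1
        lm = tiny_map(data)
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        out, removed = qa_correct_mask(lm, mask)
        assert removed == {}
        assert np.array_equal(out.data, data)

    def test_grid_mismatch_raises(self):
        lm = tiny_map(np.ones((5, 5, 5), dtype=int))
        with pytest.raises(ValueError):
            qa_correct_mask(lm, np.zeros((6, 6, 6), dtype=bool))


class TestSplitHemispheres:
    def test_mirror_symmetric_split_is_balanced(self, rendered_subject):
        _, _, lab = rendered_subject
        split = split_hemispheres(lab)
        df = extract_volumes(split)
        for name in {i.name.rsplit("_", 1)[0] for i in split.labels.values()
                     if i.hemisphere in ("L", "R")}:
            vl = df.loc[df.structure == f"{name}_L", "volume_mm3"].iloc[0]
            vr = df.loc[df.structure == f"{name}_R", "volume_mm3"].iloc[0]
            # mirror layout: halves agree to within one voxel layer
            assert abs(vl - vr) / max(vl, vr) < 0.12

    def test_35_structures_30_bilateral_give_65_labels(self):
        data = np.zeros((8, 8, 8), dtype=int)
        labels = {}
        ids = list(range(1, 36))
        for n, lid in enumerate(ids):
            labels[lid] = LabelInfo(f"s{lid}", "GM",
                                    "unsplit" if n < 30 else "midline",
                                    bilateral=n < 30)
            data.flat[n] = lid  # all voxels on the left side
        lm = tiny_map(data, labels=labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out = split_hemispheres(lm)
        assert len(out.labels) == 30 * 2 + 5

    def test_one_sided_bilateral_warns(self):
        data = np.zeros((6, 6, 6), dtype=int)
        data[0, 0, 0] = 1  # entirely left of the midplane
        lm = tiny_map(data, labels={1: LabelInfo("s1", "GM", bilateral=True)})
        with pytest.warns(UserWarning, match="no R voxels"):
            out = split_hemispheres(lm)
        df = extract_volumes(out)
        assert df.loc[df.structure == "s1_R", "volume_mm3"].iloc[0] == 0.0

    def test_already_split_raises(self):
        lm = tiny_map(np.zeros((4, 4, 4), dtype=int),
                      labels={1: LabelInfo("s1_L", "GM", "L", bilateral=True)})
        with pytest.raises(ValueError, match="already"):
            split_hemispheres(lm)


class TestExtractVolumes:
    def test_100_voxels_at_150_micron(self):
        data = np.zeros((10, 10, 10), dtype=int)
        data.flat[:100] = 1
        lm = tiny_map(data, spacing=0.15)
        df = extract_volumes(lm)
        assert df.loc[df.structure == "s1", "volume_mm3"].iloc[0] == pytest.approx(0.3375)

    def test_conservation_sum_equals_mask_volume(self, rendered_subject):
        """Voxel counts conserve exactly; volumes to float round-off."""
        _, _, lab = rendered_subject
        df = extract_volumes(lab)
        assert df["n_voxels"].sum() == (lab.data > 0).sum()
        mask_volume = (lab.data > 0).sum() * lab.voxel_volume
        assert total_brain_volume(df) == pytest.approx(mask_volume, rel=1e-12)

    def test_absent_label_flagged_empty(self):
        lm = tiny_map(np.zeros((4, 4, 4), dtype=int),
                      labels={3: LabelInfo("ghost", "GM")})
        df = extract_volumes(lm)
        row = df[df.structure == "ghost"].iloc[0]
        assert row["volume_mm3"] == 0.0 and row["empty"]


class TestResampleImage:
    def test_identity_spacing_preserves_image(self, rendered_subject):
        _, img, _ = rendered_subject
        out = resample_image(img, img.spacing[0], order=3)
        assert out.shape == img.shape
        assert np.abs(out.data - img.data).max() < 1e-6

    def test_constant_image_stays_constant(self):
        img = LabeledImage(np.full((20, 20, 20), 7.0), (0.1, 0.1, 0.1))
        out = resample_image(img, 0.37, order=3)
        assert np.allclose(out.data, 7.0)

    def test_invalid_order(self, rendered_subject):
        _, img, _ = rendered_subject
        with pytest.raises(ValueError):
            resample_image(img, 0.2, order=6)
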