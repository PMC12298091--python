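"""Windowed-attention backbone: shapes, attention, freezing, pretraining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iopscreen.backbone import (
    BackboneConfig,
    SwinBackbone,
    SwinBackboneClassifier,
    apply_freeze_policy,
    patch_partition,
    window_attention,
)


class TestPatchPartition:
    def test_token_counts(self):
        assert patch_partition(np.zeros((224, 224)), 4).shape[:2] == (56, 56)
        assert patch_partition(np.zeros((8, 8)), 4).shape[:2] == (2, 2)

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            patch_partition(np.zeros((10, 10)), 4)

    def test_projection_applied(self, rng):
        w = rng.normal(size=(16, 5))
        tok = patch_partition(rng.random((8, 8)), 4, weight=w)
        assert tok.shape == (2, 2, 5)


class TestWindowAttention:
    def test_attention_rows_normalized(self, rng):
        for shift in (0, 2):
            _, attn = window_attention(
                rng.random((2, 8, 8, 12)), 4, 3, shift=shift, return_attn=True
            )
            assert np.abs(attn.sum(axis=-1) - 1).max() < 1e-6

    def test_output_shape_preserved_with_shift(self, rng):
        x = rng.random((1, 8, 8, 6))
        out = window_attention(x, 4, 2, shift=2, seed=1)
        assert out.shape == x.shape
        assert np.isfinite(out).all()

    def test_oversized_window_falls_back_to_global(self, rng):
        x = rng.random((1, 2, 2, 6))
        out = window_attention(x, 4, 2, shift=2, seed=1)
        assert out.shape == x.shape

    def test_zero_shift_matches_plain_windowed(self, rng):
        x = rng.random((1, 8, 8, 6))
        a = window_attention(x, 4, 2, shift=0, seed=3)
        b = window_attention(x, 4, 2, seed=3)
        assert np.array_equal(a, b)


class TestShapeLaw:
    @settings(max_examples=10, deadline=None)
    @given(
        embed=st.sampled_from([8, 16, 24]),
        input_size=st.sampled_from([32, 64]),
        window=st.sampled_from([2, 4]),
    )
    def test_stage_sides_halve_and_channels_double(self, embed, input_size, window):
        cfg = BackboneConfig(
            input_size=input_size, patch_size=4, depths=(1, 1, 1, 1),
            heads=(2, 2, 2, 2), window_size=window, embed_dim=embed, mlp_ratio=1.0,
        )
        model = SwinBackbone(cfg, seed=0)
        _, feats = model.forward_stages(np.zeros((1, input_size, input_size)))
        for s, f in enumerate(feats):
            side = input_size // (4 * 2**s)
            assert f.shape == (1, side, side, embed * 2**s)

    def test_tiny_preset_stage_sides(self):
        model = SwinBackbone(BackboneConfig.tiny(), seed=0)
        _, feats = model.forward_stages(np.zeros((2, 64, 64)))
        assert [f.shape[1] for f in feats] == [16, 8, 4, 2]

    def test_outputs_finite_and_deterministic(self, rng):
        model = SwinBackbone(BackboneConfig.tiny(), seed=1)
        x = rng.random((3, 64, 64))
        a, feats = model.forward_stages(x)
        b, _ = model.forward_stages(x)
        assert np.isfinite(a.data).all()
        assert all(np.isfinite(f.data).all() for f in feats)
        assert np.array_equal(a.data, b.data)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(input_size=63)
        with pytest.raises(ValueError):
            BackboneConfig(input_size=64, embed_dim=10, heads=(3, 3, 3, 3))
        with pytest.raises(ValueError):
            SwinBackbone(BackboneConfig.tiny(), seed=0).forward_stages(
                np.zeros((1, 32, 32))
            )


class TestFreezePolicy:
    @pytest.fixture()
    def trained(self, small_cohort):
        X = np.stack([s.image for s in small_cohort[:48]])
        y = np.array([s.label for s in small_cohort[:48]])
        return SwinBackboneClassifier(epochs=1, random_state=0).fit(X, y), X, y

    def test_freeze_all_pins_every_parameter(self, trained):
        clf, X, y = trained
        names = sorted({n.split(".")[0] for n, _ in clf.model_.named_parameters()})
        before = clf.model_.state_dict()
        clf2 = SwinBackboneClassifier(
            epochs=1, init="pretrained", pretrained_model=clf,
            freeze=tuple(names), random_state=1,
        ).fit(X, y)
        after = clf2.model_.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_partial_freeze_leaves_late_stages_trainable(self, trained):
        clf, X, y = trained
        before = clf.model_.state_dict()
        clf2 = SwinBackboneClassifier(
            epochs=1, init="pretrained", pretrained_model=clf,
            freeze=("patch_embed", "stage0", "stage1"), random_state=1,
        ).fit(X, y)
        after = clf2.model_.state_dict()
        frozen = [k for k in before if k.startswith(("patch_embed", "stage0", "stage1"))]
        stage3 = [k for k in before if k.startswith("stage3")]
        assert all(np.array_equal(before[k], after[k]) for k in frozen)
        assert any(not np.array_equal(before[k], after[k]) for k in stage3)

    def test_unknown_layer_name_rejected(self):
        model = SwinBackbone(BackboneConfig.tiny(), seed=0)
        with pytest.raises(ValueError):
            apply_freeze_policy(model, ["stage9"])


class TestPretraining:
    def test_loss_decreases_and_reproducible(self, small_cohort):
        X = np.stack([s.image for s in small_cohort[:40]])
        y = np.array([s.label for s in small_cohort[:40]])
        a = SwinBackboneClassifier(epochs=5, random_state=7).fit(X, y)
        assert a.loss_history_[-1] < a.loss_history_[0]
        b = SwinBackboneClassifier(epochs=5, random_state=7).fit(X, y)
        assert a.loss_history_ == b.loss_history_

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            SwinBackboneClassifier(epochs=1).fit(np.zeros((0, 64, 64)), np.array([]))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = SwinBackbone(BackboneConfig.tiny(), seed=3)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = SwinBackbone.load(path)
        x = rng.random((2, 64, 64))
        assert np.array_equal(model.forward(x).data, loaded.forward(x).data)

    def test_transform_concatenates_selected_stage_features(self, small_cohort):
        X = np.stack([s.image for s in small_cohort[:16]])
        y = np.array([s.label for s in small_cohort[:16]])
        clf = SwinBackboneClassifier(epochs=1, random_state=0).fit(X, y)
        f = clf.transform(X, stages=(2, 3))
        assert f.shape == (16, 96 + 192)
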