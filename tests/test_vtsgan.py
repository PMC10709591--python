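import numpy as np
import pytest

from vtsct.grid import VolumeGrid, empty_like_template
from vtsct.phantom import NoduleSpec, NoduleType, generate_phantom
from vtsct.slabsim import SliceCondition, degrade
from vtsct.vtsgan import (
    ModelConfig,
    TrainConfig,
    baseline_interp,
    evaluate_l1,
    infer,
    load_model,
    make_training_pairs,
    save_model,
    train,
    zero_residual_model,
)
from vtsct.vtsgan.model import dc_upsample

TINY = ModelConfig(
    patch_shape=(10, 10, 12), base_channels=4, depth=2, disc_channels=3, disc_depth=1
)


@pytest.fixture(scope="module")
def small_volumes():
    vols = []
    for i, (total, solid) in enumerate([(22.0, 12.0), (18.0, 18.0), (24.0, 10.0)]):
        grid = empty_like_template((30, 30, 30), (1.0, 1.0, 1.0), (-14.5, -14.5, -14.5))
        ntype = NoduleType.SOLID if total == solid else NoduleType.PART_SOLID
        spec = NoduleSpec(ntype, total, solid, (0.0, 0.0, 0.0))
        vols.append(generate_phantom(spec, grid, seed=50 + i)[0])
    return vols


@pytest.fixture(scope="module")
def tiny_pairs(small_volumes):
    return make_training_pairs(
        small_volumes, 3, seed=2, patch_shape=TINY.patch_shape
    )


@pytest.fixture(scope="module")
def thick_volume(small_volumes):
    return degrade(small_volumes[0], SliceCondition(5.0, 5.0, 1.0))


COND55 = SliceCondition(5.0, 5.0, 1.0)


class TestMakeTrainingPairs:
    def test_pair_count_and_condition_range(self, small_volumes):
        pairs = make_training_pairs(small_volumes[:1], 4, seed=0, patch_shape=(10, 10, 12))
        assert len(pairs) == 4
        for thick, thin, cond in pairs:
            assert 3.0 <= cond.thickness_mm <= 8.0
            assert 3.0 <= cond.interval_mm <= 8.0
            assert thick.spacing_mm[2] == cond.interval_mm

    def test_zero_per_volume(self, small_volumes):
        assert make_training_pairs(small_volumes, 0, seed=0, patch_shape=(10, 10, 12)) == []

    def test_seeded_reproducibility(self, small_volumes):
        p1 = make_training_pairs(small_volumes, 3, seed=9, patch_shape=(10, 10, 12))
        p2 = make_training_pairs(small_volumes, 3, seed=9, patch_shape=(10, 10, 12))
        for (t1, n1, c1), (t2, n2, c2) in zip(p1, p2):
            assert c1 == c2
            assert np.array_equal(t1.voxels, t2.voxels)
            assert np.array_equal(n1.voxels, n2.voxels)

    def test_oversized_patch_rejected(self, small_volumes):
        with pytest.raises(ValueError, match="patch"):
            make_training_pairs(small_volumes, 1, seed=0, patch_shape=(64, 64, 64))


class TestTrain:
    def test_smoke_losses_finite(self, tiny_pairs):
        state = train(tiny_pairs, TINY, TrainConfig(epochs=2, batch_size=4), seed=0)
        assert len(state.history) == 2
        for h in state.history:
            assert all(np.isfinite(v) for v in h.values())

    def test_smoke_reconstruction_improves(self, tiny_pairs):
        cfg = ModelConfig(
            patch_shape=TINY.patch_shape, base_channels=4, depth=2, lambda_adv=0.0
        )
        state = train(
            tiny_pairs, cfg, TrainConfig(epochs=4, batch_size=4, lr_g=5e-4), seed=0
        )
        assert state.history[-1]["g_rec"] <= state.history[0]["g_rec"] + 1e-6

    def test_pure_regression_beats_linear_baseline(self, tiny_pairs):
        cfg = ModelConfig(
            patch_shape=TINY.patch_shape,
            base_channels=6,
            depth=3,
            lambda_adv=0.0,
            dc_iters=0,
        )
        state = train(
            tiny_pairs, cfg, TrainConfig(epochs=40, batch_size=4, lr_g=1e-3), seed=1
        )
        l1_model, l1_baseline = evaluate_l1(state, tiny_pairs)
        assert l1_model <= l1_baseline

    def test_training_determinism(self, tiny_pairs):
        s1 = train(tiny_pairs, TINY, TrainConfig(epochs=2, batch_size=4), seed=5)
        s2 = train(tiny_pairs, TINY, TrainConfig(epochs=2, batch_size=4), seed=5)
        assert s1.history == s2.history

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY, TrainConfig(epochs=1), seed=0)


class TestInfer:
    def test_repeated_inference_bitwise_identical(self, tiny_pairs, thick_volume):
        state = train(tiny_pairs, TINY, TrainConfig(epochs=1, batch_size=4), seed=0)
        v1 = infer(state, thick_volume, COND55, 1.0)
        v2 = infer(state, thick_volume, COND55, 1.0)
        assert np.array_equal(v1.voxels, v2.voxels)

    def test_output_grid_contract(self, tiny_pairs, thick_volume):
        state = train(tiny_pairs, TINY, TrainConfig(epochs=1, batch_size=4), seed=0)
        out = infer(state, thick_volume, COND55, 1.0)
        assert out.spacing_mm[2] == 1.0
        assert out.spacing_mm[:2] == thick_volume.spacing_mm[:2]
        assert out.shape[:2] == thick_volume.shape[:2]

    def test_zero_residual_equals_linear_interp(self, thick_volume):
        cfg = ModelConfig(
            patch_shape=TINY.patch_shape, base_channels=4, depth=2, dc_iters=0
        )
        model = zero_residual_model(cfg, seed=3)
        out = infer(model, thick_volume, COND55, 1.0)
        base = baseline_interp(thick_volume, COND55, 1.0, method="linear")
        lo, hi = cfg.hu_clip
        assert np.array_equal(out.voxels, np.clip(base.voxels, lo, hi))

    def test_inconsistent_condition_rejected(self, thick_volume):
        model = zero_residual_model(TINY, seed=0)
        with pytest.raises(ValueError, match="inconsistent"):
            infer(model, thick_volume, SliceCondition(5.0, 4.0, 1.0), 1.0)

    def test_invalid_target_rejected(self, thick_volume):
        model = zero_residual_model(TINY, seed=0)
        with pytest.raises(ValueError):
            infer(model, thick_volume, COND55, 2.0)

    def test_chunked_inference_matches_single_pass(self, tiny_pairs):
        state = train(tiny_pairs, TINY, TrainConfig(epochs=1, batch_size=4), seed=0)
        grid = empty_like_template((16, 16, 90), (1.0, 1.0, 1.0), (-7.5, -7.5, -44.5))
        spec = NoduleSpec(NoduleType.SOLID, 12.0, 12.0, (0.0, 0.0, 0.0))
        thin, _ = generate_phantom(spec, grid, seed=1)
        thick = degrade(thin, COND55)
        full = infer(state, thick, COND55, 1.0, max_chunk_z=200)
        chunked = infer(state, thick, COND55, 1.0, max_chunk_z=32, overlap_z=8)
        # blended overlap agrees with the single pass away from ramps
        assert np.allclose(full.voxels, chunked.voxels, atol=1.0)

    def test_serialization_round_trip_bitwise(self, tiny_pairs, thick_volume, tmp_path):
        state = train(tiny_pairs, TINY, TrainConfig(epochs=2, batch_size=4), seed=0)
        before = infer(state, thick_volume, COND55, 1.0)
        path = tmp_path / "model.npz"
        save_model(state, path)
        loaded = load_model(path)
        after = infer(loaded, thick_volume, COND55, 1.0)
        assert np.array_equal(before.voxels, after.voxels)
        assert loaded.history == state.history
        assert loaded.config == state.config


class TestBaselineInterp:
    def test_constant_volume(self):
        vol = VolumeGrid(np.full((4, 4, 8), -600.0), (1.0, 1.0, 5.0))
        for method in ("nearest", "linear", "cubic"):
            out = baseline_interp(vol, SliceCondition(5.0, 5.0, 1.0), 1.0, method)
            assert np.allclose(out.voxels, -600.0)

    def test_linear_reproduces_ramp(self, ramp_volume):
        thick = degrade(ramp_volume, COND55)
        out = baseline_interp(thick, COND55, 1.0, "linear")
        prof = out.voxels[0, 0, :]
        slopes = np.diff(prof)
        assert np.allclose(slopes, slopes[0], atol=1e-4)

    def test_nearest_copies_input_slices(self, thick_volume):
        out = baseline_interp(thick_volume, COND55, 1.0, "nearest")
        in_slices = {thick_volume.voxels[:, :, k].tobytes() for k in range(thick_volume.shape[2])}
        for k in range(out.shape[2]):
            assert out.voxels[:, :, k].tobytes() in in_slices

    def test_unknown_method_rejected(self, thick_volume):
        with pytest.raises(ValueError):
            baseline_interp(thick_volume, COND55, 1.0, "sinc")


class TestDataConsistency:
    def test_dc_zero_iters_is_linear(self, thick_volume):
        z = np.arange(-10.0, 10.0, 1.0)
        from vtsct.vtsgan.model import resample_z_to

        a = dc_upsample(thick_volume, z, 5.0, iters=0)
        b = resample_z_to(thick_volume, z, method="linear")
        assert np.allclose(a, b)

    def test_dc_improves_slab_consistency(self, small_volumes):
        thin = small_volumes[0]
        thick = degrade(thin, COND55)
        z = thin.z_centers_mm()
        from vtsct.vtsgan.model import _slab_average_at

        def slab_err(up):
            redeg = _slab_average_at(
                up, float(z[0]), 1.0, thick.z_centers_mm(), 5.0
            )
            return np.abs(redeg - thick.voxels).mean()

        up0 = dc_upsample(thick, z, 5.0, iters=0)
        up3 = dc_upsample(thick, z, 5.0, iters=3)
        assert slab_err(up3) < slab_err(up0)


class TestScaledDownEfficacy:
    def test_z_profile_error_not_worse_than_baseline(self, small_volumes):
        # part-solid phantoms, 5 mm -> 1 mm: trained model's mean
        # absolute error across nodule regions vs the linear baseline,
        # majority over 3 seeds
        pairs = make_training_pairs(
            small_volumes, 6, seed=0, patch_shape=(14, 14, 14), focus_fraction=0.7
        )
        wins = 0
        for seed in range(3):
            cfg = ModelConfig(
                patch_shape=(14, 14, 14),
                base_channels=6,
                depth=3,
                lambda_adv=0.1,
            )
            state = train(
                pairs, cfg, TrainConfig(epochs=15, batch_size=6, adv_every=4), seed=seed
            )
            errs_m, errs_b = [], []
            for thin in small_volumes:
                thick = degrade(thin, COND55)
                virt = infer(state, thick, COND55, 1.0)
                base = baseline_interp(thick, COND55, 1.0)
                # align reconstructed z-grid with the source grid
                off = int(round(virt.origin_mm[2] - thin.origin_mm[2]))
                n = min(virt.shape[2], thin.shape[2] - off)
                ref = thin.voxels[..., off : off + n]
                errs_m.append(np.abs(virt.voxels[..., :n] - ref).mean())
                errs_b.append(np.abs(base.voxels[..., :n] - ref).mean())
            wins += np.mean(errs_m) <= np.mean(errs_b)
        assert wins >= 2
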