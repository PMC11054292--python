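"""Architecture contracts, losses, and learning sanity for the network."""

import numpy as np
import pytest

from widefield_track3d import nn
from widefield_track3d.codec import decode_detections, encode_targets
from widefield_track3d.compose import compose_scene
from widefield_track3d.config import OpticalConfig, default_bead_classes
from widefield_track3d.net import (
    BACKBONES,
    ELAN,
    SPPCSP,
    CenterXFNet,
    LossWeights,
    batch_targets,
    build_backbone,
    load_checkpoint,
    save_checkpoint,
    shape_audit,
    total_loss,
)
from widefield_track3d.nn import Adam, Tensor
from widefield_track3d.util import substream

# neck geometry of the full-scale model at 1024 px input
SPP_CSP_TABLE = [
    ("SPP+CSP 1", 2048, 256, 32, 32, 2048, 256),
    ("SPP+CSP 2", 1024, 256, 64, 64, 1024, 256),
    ("SPP+CSP 3", 512, 128, 128, 128, 512, 128),
]
ELAN_TABLE = [
    ("ELAN 1", 256, 512, 64, 64, 256, 256),
    ("ELAN 2", 128, 256, 128, 128, 128, 128),
    ("ELAN 3", 64, 128, 256, 256, 64, 64),
]


class TestArchitecture:
    def test_resnet50_neck_shape_chain(self):
        rows = {r["idx"]: r for r in shape_audit("resnet50", 1024)}
        for idx, c1, c2, si, so, ci, co in SPP_CSP_TABLE + ELAN_TABLE:
            r = rows[idx]
            assert (r["c1"], r["c2"], r["in_size"], r["out_size"], r["in_channel"], r["out_channel"]) == (
                c1, c2, si, so, ci, co
            ), idx
        assert rows["maps"]["out_size"] == 256

    def test_backbone_channel_counts(self):
        for name, spec in BACKBONES.items():
            bb = build_backbone(name)
            exp = 4 if spec["block"] == "bottleneck" else 1
            assert bb.out_channels == [w * exp for w in spec["widths"]]
        assert build_backbone("resnet50").out_channels == [256, 512, 1024, 2048]

    def test_tiny_backbone_forward_strides(self, rng):
        bb = build_backbone("tiny", rng=rng)
        feats = bb(Tensor(rng.normal(size=(1, 1, 256, 256)).astype(np.float32)))
        assert [f.data.shape for f in feats] == [
            (1, 16, 64, 64), (1, 32, 32, 32), (1, 64, 16, 16), (1, 128, 8, 8),
        ]

    def test_indivisible_input_rejected(self, rng):
        bb = build_backbone("tiny", rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            bb(Tensor(rng.normal(size=(1, 1, 100, 100)).astype(np.float32)))
        model = CenterXFNet(2, "tiny", rng)
        with pytest.raises(ValueError, match="square"):
            model(rng.normal(size=(1, 1, 128, 96)).astype(np.float32))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_backbone("resnet101")

    @pytest.mark.parametrize("c1,c2,size", [(128, 32, 8), (64, 32, 16)])
    def test_spp_csp_shape_contract(self, c1, c2, size, rng):
        blk = SPPCSP(c1, c2, rng)
        out = blk(Tensor(rng.normal(size=(2, c1, size, size)).astype(np.float32)))
        assert out.data.shape == (2, c2, size, size)
        assert np.all(np.isfinite(out.data))
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(np.zeros((1, c1 + 1, size, size), np.float32)))

    def test_spp_csp_zeros_input_finite(self, rng):
        blk = SPPCSP(32, 16, rng)
        out = blk(Tensor(np.zeros((1, 32, 8, 8), np.float32)))
        assert out.data.shape == (1, 16, 8, 8)
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("c1,c2,c_out,size", [(32, 64, 32, 16), (16, 32, 16, 64)])
    def test_elan_shape_contract(self, c1, c2, c_out, size, rng):
        blk = ELAN(c1, c2, c_out, rng)
        out = blk(Tensor(rng.normal(size=(2, c1, size, size)).astype(np.float32)))
        assert out.data.shape == (2, c_out, size, size)
        with pytest.raises(ValueError, match="even"):
            ELAN(16, 33, 16, rng)

    def test_forward_map_shapes_and_determinism(self, rng):
        model = CenterXFNet(2, "tiny", rng).eval()
        x = rng.normal(size=(1, 1, 256, 256)).astype(np.float32)
        out1 = model(x)
        out2 = model(x)
        assert out1["heatmap"].data.shape == (1, 2, 64, 64)
        assert out1["offset"].data.shape == (1, 2, 64, 64)
        assert out1["depth"].data.shape == (1, 1, 64, 64)
        assert np.all((out1["heatmap"].data >= 0) & (out1["heatmap"].data <= 1))
        for key in out1:
            assert np.array_equal(out1[key].data, out2[key].data)

    @pytest.mark.parametrize("use_spp_csp,use_elan", [(False, True), (True, False), (False, False)])
    def test_block_swap_ablation_hooks(self, use_spp_csp, use_elan, rng):
        """Either neck block family can be swapped for plain conv-BN-ReLU."""
        model = CenterXFNet(2, "tiny", rng, use_spp_csp=use_spp_csp, use_elan=use_elan).eval()
        out = model(rng.normal(size=(1, 1, 128, 128)).astype(np.float32))
        assert out["heatmap"].data.shape == (1, 2, 32, 32)
        assert np.all(np.isfinite(out["heatmap"].data))

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = CenterXFNet(2, "tiny", rng).eval()
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        ref = model(x)["heatmap"].data
        save_checkpoint(model, tmp_path / "m.npz", {"input_size": 64, "z_min_um": -2.0, "z_max_um": 2.0})
        loaded, meta = load_checkpoint(tmp_path / "m.npz")
        assert meta["backbone"] == "tiny"
        assert np.allclose(loaded.eval()(x)["heatmap"].data, ref)
        with pytest.raises(ValueError, match="sidecar"):
            load_checkpoint(tmp_path / "m.npz", expect={"backbone": "resnet50"})


class TestLoss:
    @pytest.fixture
    def maps(self):
        optical = OpticalConfig(z_min_um=-2.0, z_max_um=2.0, z_step_um=0.5)
        classes = default_bead_classes()
        from widefield_track3d.compose import ParticleAnnotation

        anns = [
            ParticleAnnotation(40.2, 30.7, 1.0, "small", ("small", 0)),
            ParticleAnnotation(100.0, 90.5, -1.5, "big", ("big", 0)),
        ]
        return encode_targets(anns, 128, 4, classes, optical)

    def test_zero_at_ideal_prediction(self, maps):
        """Loss vanishes for the ideal output: unit peaks, exact offsets/depths."""
        heat, offs, depth, mask, dmask = batch_targets([maps])
        ideal_heat = (heat >= 1.0).astype(np.float32)
        pred = {"heatmap": Tensor(ideal_heat), "offset": Tensor(offs), "depth": Tensor(depth)}
        loss, parts = total_loss(pred, heat, offs, depth, mask, depth_mask=dmask)
        assert parts["offset"] == 0 and parts["depth"] == 0
        assert abs(parts["heat"]) < 1e-5
        assert loss.item() == pytest.approx(0, abs=1e-4)
        # any deviation at a supervised cell raises the loss
        worse = {"heatmap": Tensor(ideal_heat), "offset": Tensor(offs + 0.1), "depth": Tensor(depth)}
        assert total_loss(worse, heat, offs, depth, mask, depth_mask=dmask)[0].item() > loss.item()

    def test_empty_mask_leaves_heat_term_only(self, maps, rng):
        heat, offs, depth, _, _ = batch_targets([maps])
        empty = np.zeros_like(heat[:, :1], dtype=bool)
        pred = {
            "heatmap": Tensor(np.clip(heat * 0 + 0.1, 0, 1)),
            "offset": Tensor(rng.normal(size=offs.shape).astype(np.float32)),
            "depth": Tensor(rng.normal(size=depth.shape).astype(np.float32)),
        }
        _, parts = total_loss(pred, heat, offs, depth, empty, depth_mask=empty)
        assert parts["offset"] == 0 and parts["depth"] == 0 and parts["heat"] > 0

    def test_shape_mismatch_rejected(self, maps):
        heat, offs, depth, mask, dmask = batch_targets([maps])
        pred = {"heatmap": Tensor(heat[:, :1]), "offset": Tensor(offs), "depth": Tensor(depth)}
        with pytest.raises(ValueError, match="heatmap"):
            total_loss(pred, heat, offs, depth, mask, depth_mask=dmask)


@pytest.fixture(scope="module")
def overfit_scene():
    """A single 3-particle scene plus the library that produced it."""
    from widefield_track3d.fixtures import mini_library

    lib = mini_library(5)
    scene = compose_scene(lib, 3, 256, substream(5, "overfit"), noise_sd=0.01, seed=5)
    return lib, scene


@pytest.fixture(scope="module")
def overfit_model(overfit_scene):
    """Tiny model trained until it memorizes the single scene."""
    lib, scene = overfit_scene
    model = CenterXFNet(2, "tiny", substream(5, "init"))
    opt = Adam(model.parameters(), lr=2e-3)
    img = scene.pixels.astype(np.float32)
    x = ((img - img.mean()) / img.std())[None, None]
    maps = encode_targets(scene.annotations, 256, 4, lib.classes, lib.config)
    heat, offs, depth, mask, dmask = batch_targets([maps])
    weights = LossWeights(lambda_depth=5.0)
    for step in range(300):
        model.train()
        opt.zero_grad()
        out = model(x)
        loss, _ = total_loss(out, heat, offs, depth, mask, weights, dmask)
        loss.backward()
        opt.step()
        if step >= 40 and step % 20 == 0 and _overfit_converged(model, x, scene, lib):
            break
    return model


def _detect(model, x, lib, threshold=0.35):
    model.eval()
    out = model(x)
    return decode_detections(
        out["heatmap"].data[0], out["offset"].data[0], out["depth"].data[0],
        4, lib.classes, lib.config, threshold, 50,
    )


def _overfit_converged(model, x, scene, lib) -> bool:
    dets = _detect(model, x, lib)
    if len(dets) != len(scene.annotations):
        return False
    for a in scene.annotations:
        d = min(dets, key=lambda d: np.hypot(d.x_px - a.x_px, d.y_px - a.y_px))
        if np.hypot(d.x_px - a.x_px, d.y_px - a.y_px) >= 1.0:
            return False
    return True


class TestLearning:
    def test_single_step_decreases_loss(self, overfit_scene):
        """One Adam step on a one-scene batch lowers the loss for >= 9/10 seeds."""
        lib, scene = overfit_scene
        img = scene.pixels.astype(np.float32)
        x = ((img - img.mean()) / img.std())[None, None]
        maps = encode_targets(scene.annotations, 256, 4, lib.classes, lib.config)
        heat, offs, depth, mask, dmask = batch_targets([maps])
        wins = 0
        for seed in range(10):
            model = CenterXFNet(2, "tiny", substream(seed, "gradflow"))
            opt = Adam(model.parameters(), lr=1e-3)
            model.train()
            out = model(x)
            loss0, _ = total_loss(out, heat, offs, depth, mask, depth_mask=dmask)
            loss0.backward()
            opt.step()
            out = model(x)
            loss1, _ = total_loss(out, heat, offs, depth, mask, depth_mask=dmask)
            if loss1.item() < loss0.item():
                wins += 1
        assert wins >= 9

    def test_overfit_recall_and_subpixel_accuracy(self, overfit_model, overfit_scene):
        """Memorizing one scene: full recall, xy error < 1 px per particle."""
        lib, scene = overfit_scene
        img = scene.pixels.astype(np.float32)
        x = ((img - img.mean()) / img.std())[None, None]
        dets = _detect(overfit_model, x, lib)
        assert len(dets) == len(scene.annotations)
        for a in scene.annotations:
            d = min(dets, key=lambda d: np.hypot(d.x_px - a.x_px, d.y_px - a.y_px))
            assert np.hypot(d.x_px - a.x_px, d.y_px - a.y_px) < 1.0

    def test_translation_equivariance(self, overfit_model, overfit_scene):
        """Shifting the scene by a stride-32 multiple moves detections rigidly.

        The deepest pyramid level is downsampled 32x, so exact
        equivariance holds for 32-px multiples (8 output cells).
        """
        lib, scene = overfit_scene
        shift = 32  # k = 8 output cells
        img = scene.pixels.astype(np.float32)
        rolled = np.roll(img, (shift, shift), axis=(0, 1))
        xs = ((rolled - rolled.mean()) / rolled.std())[None, None]
        dets = _detect(overfit_model, xs, lib)
        margin = 50
        inner = [
            a for a in scene.annotations
            if margin < a.x_px < 256 - margin - shift and margin < a.y_px < 256 - margin - shift
        ]
        assert inner, "fixture scene left no interior particle"
        for a in inner:
            d = min(dets, key=lambda d: np.hypot(d.x_px - a.x_px - shift, d.y_px - a.y_px - shift))
            assert np.hypot(d.x_px - (a.x_px + shift), d.y_px - (a.y_px + shift)) < 1.5
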