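"""Backbone contracts: resolution/channel ladders, fusion, head, determinism,
gradient flow and checkpointing."""

import numpy as np
import pytest

from hrcxr import ConfigError, NetworkConfig, ShapeError, build_network, get_profile
from hrcxr.data import normalize_gray_batch
from hrcxr.profiler import profile_network
from hrcxr.train import load_checkpoint, save_checkpoint
from conftest import make_mini_config


def test_default_profile_is_literal_layer_table():
    cfg = get_profile("table1")
    assert cfg.branch_widths == (48, 96, 192, 384)
    assert cfg.modules_per_stage == (4, 4, 4)
    assert cfg.blocks_per_module == 4
    assert cfg.head_hidden == (2048, 512)
    assert cfg.num_classes == 14


@pytest.mark.parametrize("size,expected", [(224, (56, 28, 14, 7)),
                                           (256, (64, 32, 16, 8))])
def test_resolution_ladder(size, expected, rng):
    """Stream k sits at S/4/2^k: composing the two stride-2 stem convolutions
    with the k stride-2 transitions halves k+2 times in total."""
    cfg = make_mini_config(input_size=size)
    net = build_network(cfg, seed=0).eval()
    x = rng.standard_normal((1, 3, size, size)).astype(np.float32)
    streams = net.forward_features(x)
    assert tuple(s.shape[2] for s in streams) == expected
    assert tuple(s.shape[3] for s in streams) == expected
    assert tuple(s.shape[1] for s in streams) == cfg.branch_widths


def test_forward_pass_produces_probability_matrix(rng):
    cfg = make_mini_config(num_classes=14)
    net = build_network(cfg, seed=0).eval()
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    p = net.forward(x)
    assert p.shape == (2, 14)
    assert np.all(p > 0) and np.all(p < 1)


def test_identical_images_produce_identical_rows(rng):
    net = build_network(make_mini_config(), seed=0).eval()
    one = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
    streams = net.forward_features(np.concatenate([one, one]))
    for s in streams:
        np.testing.assert_array_equal(s[0], s[1])


def test_evaluation_mode_is_bit_deterministic(rng):
    net = build_network(make_mini_config(), seed=0).eval()
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    p1 = net.forward(x.copy())
    p2 = net.forward(x.copy())
    np.testing.assert_array_equal(p1, p2)


def test_fusion_path_ablation_makes_stream_passthrough(rng):
    """Zeroing every cross-resolution path into stream 0 turns the final
    fusion into the identity for that stream."""
    net = build_network(make_mini_config(), seed=0).eval()
    fuse = net.fusions[-1]
    for (j, k), idx in fuse.index.items():
        if k == 0:
            for p in fuse.paths[idx].parameters():
                p.data[...] = 0
    widths = net.config.branch_widths
    streams = [
        rng.standard_normal((2, widths[i], 16 // 2 ** i, 16 // 2 ** i)
                            ).astype(np.float32)
        for i in range(4)
    ]
    out = net.fuse_branches(streams)
    np.testing.assert_array_equal(out[0], streams[0])
    assert all(o.shape == s.shape for o, s in zip(out, streams))


def test_two_stream_fusion_preserves_shapes(rng):
    from hrcxr.backbone import FuseLayer
    fuse = FuseLayer((8, 16), rng=np.random.default_rng(0))
    streams = [rng.standard_normal((2, 8, 12, 12)).astype(np.float32),
               rng.standard_normal((2, 16, 6, 6)).astype(np.float32)]
    out = fuse.forward(streams)
    assert [o.shape for o in out] == [s.shape for s in streams]
    again = fuse.forward([s.copy() for s in streams])
    for a, b in zip(out, again):
        np.testing.assert_array_equal(a, b)


def test_head_ladder_widths_follow_branch_widths():
    cfg = get_profile("table1")
    assert cfg.ladder == (96, 192, 384)
    mini = make_mini_config()
    net = build_network(mini, seed=0)
    assert tuple(d.layers[0].out_ch for d in net.head.downs) == mini.ladder
    assert tuple(f.layers[0].out_ch for f in net.head.fuses) == mini.ladder


def test_zeroed_final_layer_outputs_exactly_half(rng):
    net = build_network(make_mini_config(), seed=0).eval()
    net.head.lin2.weight.data[...] = 0
    net.head.lin2.bias.data[...] = 0
    p = net.forward(rng.standard_normal((3, 3, 64, 64)).astype(np.float32))
    np.testing.assert_array_equal(p, np.full_like(p, 0.5))


def test_missing_streams_rejected_by_head(rng):
    net = build_network(make_mini_config(), seed=0).eval()
    x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
    streams = net.forward_features(x)
    with pytest.raises(ShapeError, match="4-stream"):
        net.classify_head(streams[:2])


@pytest.mark.parametrize("bad,field", [
    (dict(branch_widths=(8, 16, 32, 60)), "branch_widths"),
    (dict(modules_per_stage=(0, 1, 1)), "modules_per_stage"),
    (dict(num_classes=0), "num_classes"),
    (dict(input_size=100), "input_size"),
    (dict(head_ladder=(1, 2)), "head_ladder"),
])
def test_invalid_config_error_names_field(bad, field):
    with pytest.raises(ConfigError, match=field):
        make_mini_config(**bad)


@pytest.mark.parametrize("shape", [(1, 1, 64, 64), (1, 3, 64, 32),
                                   (1, 3, 60, 60)])
def test_malformed_inputs_raise_shape_error(shape, rng):
    net = build_network(make_mini_config(), seed=0).eval()
    with pytest.raises(ShapeError):
        net.forward_features(rng.standard_normal(shape).astype(np.float32))


def test_every_parameter_receives_gradient(rng):
    """No dead branches: one synthetic batch reaches every trainable array."""
    net = build_network(make_mini_config(num_classes=5), seed=0).train()
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    probs = net.forward(x)
    net.zero_grad()
    net.backward(rng.standard_normal(probs.shape).astype(np.float32))
    dead = [name for name, p in net.named_parameters()
            if float(np.abs(p.grad).max()) == 0.0]
    assert dead == []


def test_checkpoint_roundtrip_and_config_guard(tmp_path, rng):
    cfg = make_mini_config(num_classes=4)
    net = build_network(cfg, seed=7).eval()
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    before = net.forward(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, net)
    restored = load_checkpoint(path, expect_config=cfg).eval()
    np.testing.assert_array_equal(before, restored.forward(x))
    with pytest.raises(ConfigError, match="config"):
        load_checkpoint(path, expect_config=make_mini_config(num_classes=5))


def test_config_yaml_json_roundtrip(tmp_path):
    cfg = get_profile("calibrated")
    for name in ("c.yaml", "c.json"):
        cfg.save(tmp_path / name)
        assert NetworkConfig.load(tmp_path / name) == cfg
    with pytest.raises(ConfigError, match="profile"):
        get_profile("nonexistent")


def test_profile_shapes_agree_with_forward(rng):
    """The analytic profiler walks the same topology the forward pass runs."""
    cfg = make_mini_config()
    net = build_network(cfg, seed=0).eval()
    report = profile_network(net, 64)
    assert report.total_params == net.num_parameters()
    x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
    net.forward(x)  # would raise on any internal shape inconsistency
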