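"""The parallel multi-resolution classification network.

Layout: a two-convolution stride-2 stem, a bottleneck stage on the
high-resolution branch, then three stages that each spawn one additional
branch at half the resolution and twice the width, run multi-scale attention
modules on every branch, and exchange information through a dense
multi-resolution fusion layer.  A progressive downsample-concatenate-fuse head
collapses the four streams and two linear layers produce independent
per-class probabilities through a logistic output.

Branch k runs at spatial size S/4/2^k for input size S; for S=224 the four
streams sit at 56/28/14/7.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ConfigError, NetworkConfig


class ShapeError(ValueError):
    pass


def _conv_bn(in_ch, out_ch, k, stride, rng, relu=True):
    layers = [
        nn.Conv2d(in_ch, out_ch, k, stride=stride, rng=rng),
        nn.BatchNorm2d(out_ch),
    ]
    if relu:
        layers.append(nn.ReLU())
    return nn.Sequential(*layers)


class Bottleneck(nn.Module):
    """1x1 down, 3x3, 1x1 up residual unit used in stage 1."""

    def __init__(self, in_ch, mid, out_ch, rng):
        super().__init__()
        self.path = nn.Sequential(
            nn.Conv2d(in_ch, mid, 1, rng=rng), nn.BatchNorm2d(mid), nn.ReLU(),
            nn.Conv2d(mid, mid, 3, rng=rng), nn.BatchNorm2d(mid), nn.ReLU(),
            nn.Conv2d(mid, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch),
        )
        self.proj = (
            nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, rng=rng),
                          nn.BatchNorm2d(out_ch))
            if in_ch != out_ch else None
        )
        self.relu = nn.ReLU()

    def forward(self, x):
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu.forward(self.path.forward(x) + skip)

    def backward(self, grad):
        g = self.relu.backward(grad)
        gx = self.path.backward(g)
        gx += self.proj.backward(g) if self.proj is not None else g
        return gx


class MSABlock(nn.Module):
    """Multi-scale attention block: two (dynamic) 3x3 convolutions with batch
    norm, coordinate attention on the second branch, and an identity skip."""

    def __init__(self, ch, cfg: NetworkConfig, rng):
        super().__init__()

        def conv():
            if cfg.use_condconv:
                return nn.CondConv2d(ch, ch, 3, num_experts=cfg.num_experts,
                                     rng=rng)
            return nn.Conv2d(ch, ch, 3, rng=rng)

        self.conv1, self.bn1, self.relu1 = conv(), nn.BatchNorm2d(ch), nn.ReLU()
        self.conv2, self.bn2 = conv(), nn.BatchNorm2d(ch)
        self.ca = (
            nn.CoordinateAttention(ch, cfg.ca_reduction, rng=rng)
            if cfg.use_coordatt else None
        )
        self.relu2 = nn.ReLU()
        self.ch = ch

    def forward(self, x):
        if x.shape[1] != self.ch:
            raise ShapeError(f"block width {self.ch}, input has {x.shape[1]}")
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        h = self.bn2.forward(self.conv2.forward(h))
        if self.ca is not None:
            h = self.ca.forward(h)
        return self.relu2.forward(h + x)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        h = self.ca.backward(g) if self.ca is not None else g
        h = self.conv2.backward(self.bn2.backward(h))
        h = self.conv1.backward(self.bn1.backward(self.relu1.backward(h)))
        return h + g


class _DownPath(nn.Module):
    """j -> k (j < k): repeated stride-2 convolutions walking the width ladder."""

    def __init__(self, widths, j, k, rng):
        super().__init__()
        steps = []
        for level in range(j, k):
            steps.append(nn.Conv2d(widths[level], widths[level + 1], 3,
                                   stride=2, rng=rng))
            steps.append(nn.BatchNorm2d(widths[level + 1]))
            if level + 1 < k:
                steps.append(nn.ReLU())
        self.seq = nn.Sequential(*steps)

    forward = property(lambda self: self.seq.forward)
    backward = property(lambda self: self.seq.backward)


class _UpPath(nn.Module):
    """j -> k (j > k): stride-2 transposed convolutions applied level by level."""

    def __init__(self, widths, j, k, rng):
        super().__init__()
        steps = []
        for level in range(j, k, -1):
            steps.append(nn.ConvTranspose2d(widths[level], widths[level - 1],
                                            rng=rng))
            steps.append(nn.BatchNorm2d(widths[level - 1]))
            if level - 1 > k:
                steps.append(nn.ReLU())
        self.seq = nn.Sequential(*steps)

    forward = property(lambda self: self.seq.forward)
    backward = property(lambda self: self.seq.backward)


class FuseLayer(nn.Module):
    """Dense cross-resolution exchange: every stream receives additive
    contributions from every other stream after resolution adaptation."""

    def __init__(self, widths, rng):
        super().__init__()
        self.n = len(widths)
        paths = []
        self.index = {}
        for k in range(self.n):
            for j in range(self.n):
                if j == k:
                    continue
                path = (_DownPath(widths, j, k, rng) if j < k
                        else _UpPath(widths, j, k, rng))
                self.index[(j, k)] = len(paths)
                paths.append(path)
        self.paths = paths
        self.widths = tuple(widths)

    def forward(self, streams):
        if len(streams) != self.n:
            raise ShapeError(f"expected {self.n} streams, got {len(streams)}")
        for s, w in zip(streams, self.widths):
            if s.shape[1] != w:
                raise ShapeError(f"stream widths {self.widths} expected, "
                                 f"got {[t.shape[1] for t in streams]}")
        outs = []
        for k in range(self.n):
            acc = streams[k].copy()
            for j in range(self.n):
                if j != k:
                    acc += self.paths[self.index[(j, k)]].forward(streams[j])
            outs.append(acc)
        return outs

    def backward(self, gouts):
        gins = [g.copy() for g in gouts]
        for k in range(self.n):
            for j in range(self.n):
                if j != k:
                    gins[j] += self.paths[self.index[(j, k)]].backward(gouts[k])
        return gins


class _Concat(nn.Module):
    def forward(self, a, b):
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, grad):
        return grad[:, : self._split], grad[:, self._split:]


class Head(nn.Module):
    """Progressive downsample-concat-fuse head followed by the classifier."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        widths, ladder = cfg.branch_widths, cfg.ladder
        downs, cats, fuses = [], [], []
        prev = widths[0]
        for k in range(1, 4):
            h = ladder[k - 1]
            downs.append(_conv_bn(prev, h, 3, 2, rng))
            cats.append(_Concat())
            fuses.append(_conv_bn(h + widths[k], h, 1, 1, rng))
            prev = h
        self.downs, self.cats, self.fuses = downs, cats, fuses
        self.final_conv = _conv_bn(prev, cfg.head_hidden[0], 1, 1, rng)
        self.gap = nn.GlobalAvgPool()
        self.lin1 = nn.Linear(cfg.head_hidden[0], cfg.head_hidden[1], rng=rng)
        self.relu = nn.ReLU()
        self.lin2 = nn.Linear(cfg.head_hidden[1], cfg.num_classes, rng=rng)
        self.sigmoid = nn.Sigmoid()

    def forward(self, streams, capture=None):
        if len(streams) != 4:
            raise ShapeError(f"head needs the full 4-stream pyramid, "
                             f"got {len(streams)} streams")
        rep = streams[0]
        for k in range(3):
            rep = self.downs[k].forward(rep)
            rep = self.cats[k].forward(rep, streams[k + 1])
            rep = self.fuses[k].forward(rep)
        rep = self.final_conv.forward(rep)
        if capture is not None:
            capture["last_conv"] = rep
        z = self.relu.forward(self.lin1.forward(self.gap.forward(rep)))
        return self.sigmoid.forward(self.lin2.forward(z))

    def backward(self, grad):
        g = self.lin2.backward(self.sigmoid.backward(grad))
        g = self.gap.backward(self.lin1.backward(self.relu.backward(g)))
        g = self.final_conv.backward(g)
        gstreams = [None] * 4
        for k in range(2, -1, -1):
            g = self.fuses[k].backward(g)
            g, gstreams[k + 1] = self.cats[k].backward(g)
            g = self.downs[k].backward(g)
        gstreams[0] = g
        return gstreams


class Network(nn.Module):
    """Four-branch high-resolution classifier; see module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.branch_widths
        self.stem = nn.Sequential(
            *_conv_bn(3, config.stem_width, 3, 2, rng).layers,
            *_conv_bn(config.stem_width, config.stem_width, 3, 2, rng).layers,
        )
        s1w, s1out = config.s1_width, config.s1_out
        blocks, in_ch = [], config.stem_width
        for _ in range(config.stage1_blocks):
            blocks.append(Bottleneck(in_ch, s1w, s1out, rng))
            in_ch = s1out
        self.stage1 = nn.Sequential(*blocks)
        self.adapter = (_conv_bn(s1out, w[0], 3, 1, rng)
                        if s1out != w[0] else None)
        # stage s (0-indexed over stages 2..4) spawns branch s+1
        self.transitions = [
            _conv_bn(s1out, w[1], 3, 2, rng),
            _conv_bn(w[1], w[2], 3, 2, rng),
            _conv_bn(w[2], w[3], 3, 2, rng),
        ]
        stages, fusions = [], []
        for s in range(3):
            nb = s + 2  # branches in this stage
            per_branch = []
            for k in range(nb):
                per_branch.append(nn.Sequential(*[
                    MSABlock(w[k], config, rng)
                    for _ in range(config.modules_per_stage[s]
                                   * config.blocks_per_module)
                ]))
            stages.append(per_branch)
            fusions.append(FuseLayer(w[:nb], rng))
        self.stages = stages
        self.fusions = fusions
        # register nested per-branch chains for parameter traversal
        for s, per_branch in enumerate(self.stages):
            for k, chain in enumerate(per_branch):
                setattr(self, f"stage{s + 2}_branch{k}", chain)
        self.head = Head(config, rng)
        self._cache = None

    # -- forward pieces ----------------------------------------------------
    def _check_input(self, x):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (B,3,H,W) input, got {x.shape}")
        if x.shape[2] != x.shape[3]:
            raise ShapeError(f"expected square input, got {x.shape[2:]}")
        if x.shape[2] % 32 != 0:
            raise ShapeError(f"input size must be divisible by 32, "
                             f"got {x.shape[2]}")

    def forward_features(self, x):
        """Run stem and all four stages; returns the fused 4-stream pyramid."""
        self._check_input(x)
        h = self.stage1.forward(self.stem.forward(x.astype(np.float32)))
        lowest = h
        streams = [self.adapter.forward(h) if self.adapter is not None else h]
        for s in range(3):
            streams.append(self.transitions[s].forward(lowest))
            streams = [chain.forward(t)
                       for chain, t in zip(self.stages[s], streams)]
            streams = self.fusions[s].forward(streams)
            lowest = streams[-1]
        return streams

    def fuse_branches(self, streams):
        """Apply the stage-4 fusion layer to an explicit pyramid."""
        return self.fusions[-1].forward(streams)

    def classify_head(self, streams, capture=None):
        return self.head.forward(streams, capture=capture)

    def forward(self, x, capture=None):
        streams = self.forward_features(x)
        if capture is not None:
            capture["streams"] = streams
        return self.classify_head(streams, capture=capture)

    # -- backward ----------------------------------------------------------
    def backward(self, gprobs):
        gstreams = self.head.backward(gprobs)
        for s in range(2, -1, -1):
            gstreams = self.fusions[s].backward(gstreams)
            gstreams = [chain.backward(g)
                        for chain, g in zip(self.stages[s], gstreams)]
            gnew = gstreams.pop()
            glow = self.transitions[s].backward(gnew)
            if s == 0:
                gh = glow
                gh += (self.adapter.backward(gstreams[0])
                       if self.adapter is not None else gstreams[0])
            else:
                gstreams[-1] += glow
        g = self.stage1.backward(gh)
        return self.stem.backward(g)


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Construct the network; raises :class:`ConfigError` on invalid config."""
    if not isinstance(config, NetworkConfig):
        raise ConfigError("config: expected a NetworkConfig")
    return Network(config, seed=seed)
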