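"""Analytic parameter and FLOP accounting.

Parameters are counted by enumerating the trainable arrays of the built
network, so the totals are exact by construction.  FLOPs are derived per layer
from multiply-accumulate (MAC) counts at a stated input size, walking the same
module objects the forward pass uses.

Two conventions are exposed for dynamic convolutions:

``per_expert`` (default)
    Each expert kernel's convolution is charged separately (n x the standard
    convolution) plus the routing affine.  This is the multi-branch view of
    the layer — a dynamic convolution is mathematically the weighted sum of n
    parallel convolutions — and is the convention under which the published
    compute budgets were calibrated.

``aggregated``
    One convolution with the per-sample aggregated kernel, plus the routing
    affine and the kernel-mixing cost.  This reflects the actual runtime work.

``flops_per_mac`` selects between the 1-FLOP-per-MAC and 2-FLOPs-per-MAC
reporting styles; the package reports with 1 (mult-add counting) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import (
    Bottleneck, FuseLayer, Head, MSABlock, Network, _DownPath, _UpPath,
)
from .nn.functional import conv_out_size


@dataclass
class LayerProfile:
    name: str
    params: int
    macs: int            # aggregated-kernel convention
    macs_per_expert: int  # per-expert convention


@dataclass
class ProfileReport:
    input_size: int
    entries: list[LayerProfile] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(e.params for e in self.entries)

    def total_macs(self, condconv: str = "per_expert") -> int:
        if condconv == "per_expert":
            return sum(e.macs_per_expert for e in self.entries)
        if condconv == "aggregated":
            return sum(e.macs for e in self.entries)
        raise ValueError(f"unknown condconv convention {condconv!r}")

    def total_flops(self, condconv: str = "per_expert",
                    flops_per_mac: int = 1) -> float:
        return float(self.total_macs(condconv)) * flops_per_mac

    def to_rows(self):
        return [
            dict(name=e.name, params=e.params, macs=e.macs,
                 macs_per_expert=e.macs_per_expert)
            for e in self.entries
        ]


class _Profiler:
    def __init__(self):
        self.entries: list[LayerProfile] = []

    def add(self, name, module, macs, macs_pe=None):
        params = sum(p.size for p in module._params.values()) if hasattr(
            module, "_params") else 0
        # primitives carry their own params; composites delegate
        params = module.num_parameters() if isinstance(
            module, (nn.Conv2d, nn.ConvTranspose2d, nn.BatchNorm2d, nn.Linear,
                     nn.CondConv2d, nn.CoordinateAttention)) else params
        self.entries.append(LayerProfile(
            name, int(params), int(macs),
            int(macs if macs_pe is None else macs_pe)))

    # -- dispatch ----------------------------------------------------------
    def walk(self, mod, shape, name):
        """Returns the output shape (C, H, W); records entries."""
        C, H, W = shape
        if isinstance(mod, nn.Sequential):
            for i, layer in enumerate(mod.layers):
                shape = self.walk(layer, shape, f"{name}.{i}")
            return shape
        if isinstance(mod, nn.Conv2d):
            Ho = conv_out_size(H, mod.k, mod.stride, mod.pad)
            Wo = conv_out_size(W, mod.k, mod.stride, mod.pad)
            macs = mod.out_ch * mod.in_ch * mod.k * mod.k * Ho * Wo
            self.add(name, mod, macs)
            return (mod.out_ch, Ho, Wo)
        if isinstance(mod, nn.ConvTranspose2d):
            macs = mod.in_ch * mod.out_ch * mod.k * mod.k * H * W
            self.add(name, mod, macs)
            return (mod.out_ch, mod.stride * H, mod.stride * W)
        if isinstance(mod, nn.CondConv2d):
            Ho = conv_out_size(H, mod.k, mod.stride, mod.pad)
            Wo = conv_out_size(W, mod.k, mod.stride, mod.pad)
            std = mod.out_ch * mod.in_ch * mod.k * mod.k * Ho * Wo
            routing = mod.in_ch * mod.num_experts
            mixing = mod.num_experts * mod.out_ch * mod.in_ch * mod.k * mod.k
            self.add(name, mod, std + routing + mixing,
                     mod.num_experts * std + routing)
            return (mod.out_ch, Ho, Wo)
        if isinstance(mod, nn.CoordinateAttention):
            macs = mod.ch * mod.mid * 2 * (H + W)  # shared + directional 1x1
            self.add(name, mod, macs)
            return shape
        if isinstance(mod, nn.BatchNorm2d):
            self.add(name, mod, 0)
            return shape
        if isinstance(mod, (nn.ReLU, nn.Sigmoid, nn.HardSwish)):
            return shape
        if isinstance(mod, Bottleneck):
            out = self.walk(mod.path, shape, f"{name}.path")
            if mod.proj is not None:
                self.walk(mod.proj, shape, f"{name}.proj")
            return out
        if isinstance(mod, MSABlock):
            s = self.walk(mod.conv1, shape, f"{name}.conv1")
            self.walk(mod.bn1, s, f"{name}.bn1")
            s = self.walk(mod.conv2, s, f"{name}.conv2")
            self.walk(mod.bn2, s, f"{name}.bn2")
            if mod.ca is not None:
                s = self.walk(mod.ca, s, f"{name}.ca")
            return s
        if isinstance(mod, (_DownPath, _UpPath)):
            return self.walk(mod.seq, shape, name)
        raise TypeError(f"cannot profile module of type {type(mod).__name__}")

    def walk_fusion(self, fuse: FuseLayer, shapes, name):
        for (j, k), idx in fuse.index.items():
            self.walk(fuse.paths[idx], shapes[j], f"{name}.path{j}to{k}")
        return shapes

    def walk_head(self, head: Head, shapes, name):
        shape = shapes[0]
        for k in range(3):
            shape = self.walk(head.downs[k], shape, f"{name}.down{k + 1}")
            shape = (shape[0] + shapes[k + 1][0], shape[1], shape[2])
            shape = self.walk(head.fuses[k], shape, f"{name}.fuse{k + 1}")
        shape = self.walk(head.final_conv, shape, f"{name}.final_conv")
        self.add(f"{name}.lin1", head.lin1, head.lin1.in_f * head.lin1.out_f)
        self.add(f"{name}.lin2", head.lin2, head.lin2.in_f * head.lin2.out_f)
        return shape


def profile_network(net: Network, input_size: int | None = None) -> ProfileReport:
    cfg = net.config
    size = input_size or cfg.input_size
    if size % 32 != 0:
        raise ValueError(f"input size must be divisible by 32, got {size}")
    p = _Profiler()
    shape = p.walk(net.stem, (3, size, size), "stem")
    shape = p.walk(net.stage1, shape, "stage1")
    lowest = shape
    if net.adapter is not None:
        shape = p.walk(net.adapter, shape, "adapter")
    shapes = [shape]
    for s in range(3):
        shapes.append(p.walk(net.transitions[s], lowest, f"transition{s + 1}"))
        shapes = [
            p.walk(chain, sh, f"stage{s + 2}.branch{k}")
            for k, (chain, sh) in enumerate(zip(net.stages[s], shapes))
        ]
        shapes = p.walk_fusion(net.fusions[s], shapes, f"fusion{s + 2}")
        lowest = shapes[-1]
    p.walk_head(net.head, shapes, "head")
    return ProfileReport(input_size=size, entries=p.entries)


def count_parameters(net: Network) -> int:
    """Exact count of trainable scalars, by enumeration."""
    return net.num_parameters()


def count_flops(net: Network, input_size: int | None = None,
                condconv: str = "per_expert", flops_per_mac: int = 1) -> float:
    """Analytic forward-pass FLOPs at the given input size."""
    report = profile_network(net, input_size)
    return report.total_flops(condconv=condconv, flops_per_mac=flops_per_mac)
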