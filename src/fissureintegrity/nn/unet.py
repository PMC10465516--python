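"""3D attention U-Net assembled from the autograd primitives.

Encoder/decoder with ``levels`` resolution steps; each level applies two
3x3x3 convolutions with instance normalization and ReLU, channel count
doubling from ``base_filters`` per step.  Downsampling is 2x max pooling,
upsampling nearest-neighbor.  Each skip connection passes through an
additive attention gate: the coarser decoder feature map acts as the gating
signal, both signals are projected with 1x1x1 convolutions, added, passed
through ReLU and a sigmoid-activated 1x1x1 projection to a single spatial
coefficient map that multiplies the skip features.  The head is a 1x1x1
convolution to ``out_classes`` channels followed by a channel softmax, so
per-voxel class scores sum to one.

Spatial input sizes must be divisible by ``2**levels``; this is checked
before any computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


class ShapeError(ValueError):
    pass


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in),
                      size=shape).astype(np.float32)


class AttentionUNet3D:
    """Fully-convolutional 3D attention U-Net.

    Parameters
    ----------
    in_channels, out_classes : int
        Input channels (CT + fissure probability = 2) and output classes
        (background / intact / incomplete = 3).
    levels : int
        Number of encoding steps (downsamplings).
    base_filters : int
        Filter count at the highest resolution; doubles per level.
    attention_gates : bool
        Gate the skip connections (plain U-Net when off).
    """

    def __init__(self, in_channels: int = 2, out_classes: int = 3,
                 levels: int = 4, base_filters: int = 16,
                 attention_gates: bool = True, seed: int = 0):
        if levels < 1 or base_filters < 4:
            raise ValueError("levels >= 1 and base_filters >= 4 required")
        self.in_channels = in_channels
        self.out_classes = out_classes
        self.levels = levels
        self.base_filters = base_filters
        self.attention_gates = attention_gates
        self.seed = seed
        self.params: dict[str, Parameter] = {}
        self._build(np.random.default_rng(seed))

    # -- construction ------------------------------------------------------
    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int):
        fan = cin * k ** 3
        self.params[f"{name}.w"] = Parameter(_he(rng, (cout, cin, k, k, k), fan))
        self.params[f"{name}.b"] = Parameter(np.zeros(cout, np.float32))

    def _add_norm(self, name: str, c: int):
        self.params[f"{name}.g"] = Parameter(np.ones(c, np.float32))
        self.params[f"{name}.d"] = Parameter(np.zeros(c, np.float32))

    def _add_block(self, rng, name: str, cin: int, cout: int):
        self._add_conv(rng, f"{name}.c1", cin, cout, 3)
        self._add_norm(f"{name}.n1", cout)
        self._add_conv(rng, f"{name}.c2", cout, cout, 3)
        self._add_norm(f"{name}.n2", cout)

    def _build(self, rng):
        f = self.base_filters
        cin = self.in_channels
        for i in range(self.levels):
            self._add_block(rng, f"enc{i}", cin, f * 2 ** i)
            cin = f * 2 ** i
        self._add_block(rng, "bott", cin, f * 2 ** self.levels)
        for i in reversed(range(self.levels)):
            cs = f * 2 ** i                   # skip channels
            cg = f * 2 ** (i + 1)             # gating (coarser) channels
            if self.attention_gates:
                ci = max(1, cs // 2)
                self._add_conv(rng, f"att{i}.x", cs, ci, 1)
                self._add_conv(rng, f"att{i}.g", cg, ci, 1)
                self._add_conv(rng, f"att{i}.psi", ci, 1, 1)
            self._add_block(rng, f"dec{i}", cg + cs, cs)
        self._add_conv(rng, "head", f, self.out_classes, 1)

    # -- layers ------------------------------------------------------------
    def _conv(self, name: str, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _norm(self, name: str, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.params[f"{name}.g"],
                                self.params[f"{name}.d"])

    def _block(self, name: str, x: Tensor) -> Tensor:
        x = ag.relu(self._norm(f"{name}.n1", self._conv(f"{name}.c1", x)))
        return ag.relu(self._norm(f"{name}.n2", self._conv(f"{name}.c2", x)))

    def _gate(self, i: int, skip: Tensor, g: Tensor) -> Tensor:
        theta = self._conv(f"att{i}.x", skip)
        phi = ag.upsample2(self._conv(f"att{i}.g", g))
        coeff = ag.sigmoid(self._conv(f"att{i}.psi", ag.relu(theta + phi)))
        return skip * coeff

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Map (N, in_channels, X, Y, Z) to per-voxel class probabilities
        (N, out_classes, X, Y, Z)."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.data.ndim != 5 or t.data.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected (N, {self.in_channels}, X, Y, Z) input, "
                f"got {t.data.shape}")
        div = 2 ** self.levels
        spatial = t.data.shape[2:]
        if any(s % div for s in spatial):
            raise ShapeError(
                f"spatial size {spatial} not divisible by 2^levels = {div}")
        skips = []
        h = t
        for i in range(self.levels):
            h = self._block(f"enc{i}", h)
            skips.append(h)
            h = ag.maxpool2(h)
        h = self._block("bott", h)
        for i in reversed(range(self.levels)):
            skip = skips[i]
            if self.attention_gates:
                skip = self._gate(i, skip, h)
            h = ag.concat_channels(ag.upsample2(h), skip)
            h = self._block(f"dec{i}", h)
        logits = self._conv("head", h)
        return ag.softmax_channels(logits)

    __call__ = forward

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in self.params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], np.float32).copy()

    def config(self) -> dict:
        return {"in_channels": self.in_channels,
                "out_classes": self.out_classes,
                "levels": self.levels,
                "base_filters": self.base_filters,
                "attention_gates": self.attention_gates,
                "seed": self.seed}

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __config__=json.dumps(self.config()),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "AttentionUNet3D":
        with np.load(Path(path), allow_pickle=False) as f:
            cfg = json.loads(str(f["__config__"]))
            model = cls(**cfg)
            model.load_state_dict(
                {k: f[k] for k in f.files if k != "__config__"})
        return model
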