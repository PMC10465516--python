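"""Case-to-network-input transformations.

CT intensities are clipped to (−1024, 200) HU and mapped affinely onto
[−1, 1]; each lung is cropped to its bounding box (default 2-voxel margin)
and the rescaled CT and the fissure probability map are stacked as a
2-channel array.  The right-lung input is used twice downstream, once for
the right oblique and once for the right horizontal fissure.  Training uses
fixed-size random crops; crops smaller than the lung are padded with the
channel-appropriate background value (−1 for CT, 0 for probability and
labels).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volio import LabelVolume, Volume3D, require_same_grid

CLIP_LOW = -1024.0
CLIP_HIGH = 200.0

LUNG_LABELS = {"left": 1, "right": 2}


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Per-axis inclusive start / exclusive end voxel indices."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self):
        for a, b in zip(self.start, self.stop):
            if not a < b:
                raise ValueError(f"degenerate box: start {self.start}, "
                                 f"stop {self.stop}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))


@dataclasses.dataclass
class NetworkInput:
    """2-channel network input: rescaled CT and fissure probability."""

    data: np.ndarray            # (2, nx, ny, nz), float32
    box: BoundingBox
    side: str                   # 'left' | 'right'
    full_shape: tuple[int, int, int]    # shape of the source volume

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError(
                f"expected (2, nx, ny, nz) data, got {self.data.shape}")


def clip_rescale_ct(ct: Volume3D | np.ndarray) -> Volume3D | np.ndarray:
    """Clip HU to (−1024, 200) and linearly rescale onto [−1, 1]."""
    arr = ct.data if isinstance(ct, Volume3D) else np.asarray(ct)
    clipped = np.clip(arr, CLIP_LOW, CLIP_HIGH)
    scaled = (2.0 * (clipped - CLIP_LOW) / (CLIP_HIGH - CLIP_LOW)
              - 1.0).astype(np.float32)
    if isinstance(ct, Volume3D):
        return ct.with_data(scaled)
    return scaled


def lung_bounding_box(lung_mask: LabelVolume, side: str,
                      margin: int = 2) -> BoundingBox:
    """Tightest box containing the requested lung, expanded by ``margin``
    and clamped to the volume bounds."""
    if side not in LUNG_LABELS:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    mask = lung_mask.data == LUNG_LABELS[side]
    if not mask.any():
        raise ValueError(f"lung mask contains no {side}-lung voxels")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + 1 + margin
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    return BoundingBox(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


def make_network_input(ct: Volume3D, fissure_prob: Volume3D,
                       lung_mask: LabelVolume, side: str,
                       margin: int = 2) -> NetworkInput:
    """Crop CT and probability to the per-lung box and stack as channels."""
    require_same_grid(ct, fissure_prob, lung_mask)
    box = lung_bounding_box(lung_mask, side, margin=margin)
    ct_crop = clip_rescale_ct(ct.data[box.slices])
    prob_crop = np.asarray(fissure_prob.data[box.slices], dtype=np.float32)
    data = np.stack([ct_crop, prob_crop]).astype(np.float32)
    return NetworkInput(data=data, box=box, side=side,
                        full_shape=ct.data.shape)


def crop_target(target: LabelVolume, box: BoundingBox) -> np.ndarray:
    """Integrity-mask crop matching a network input's box."""
    return np.ascontiguousarray(target.data[box.slices])


def uncrop(data: np.ndarray, box: BoundingBox,
           full_shape: tuple[int, int, int], fill=0) -> np.ndarray:
    """Re-embed a cropped array at its recorded box in the full volume."""
    out = np.full(full_shape, fill, dtype=data.dtype)
    out[box.slices] = data
    return out


#: per-channel padding values: CT channel −1 (air), probability channel 0
PAD_VALUES = (-1.0, 0.0)


def _pad_to(arr: np.ndarray, size: tuple[int, int, int], value):
    """Symmetric zero-padding (with ``value``) of the spatial axes up to
    ``size``; spatial axes are the trailing three."""
    spatial = arr.shape[-3:]
    pads = [(0, 0)] * (arr.ndim - 3)
    for s, t in zip(spatial, size):
        extra = max(0, t - s)
        pads.append((extra // 2, extra - extra // 2))
    if all(p == (0, 0) for p in pads):
        return arr
    return np.pad(arr, pads, constant_values=value)


def random_crop(inp: NetworkInput, target: np.ndarray,
                size: tuple[int, int, int] = (128, 128, 64),
                rng: np.random.Generator | None = None,
                fg_bias: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Random fixed-size crop of an input/target pair for training.

    When the lung crop is smaller than ``size`` on an axis it is padded
    (CT with −1, probability with 0, target with background).  With
    probability ``fg_bias`` the crop is constrained to contain at least one
    fissure-surface voxel — the surface is a thin sheet, so unconstrained
    uniform crops would often contain no foreground at all.  Deterministic
    given ``rng``.
    """
    rng = rng or np.random.default_rng()
    x = inp.data
    if target.shape != x.shape[1:]:
        raise ValueError("target shape does not match input spatial shape")
    # pad each channel with its own value
    chans = [_pad_to(x[c], size, PAD_VALUES[c]) for c in range(2)]
    x = np.stack(chans)
    t = _pad_to(target, size, 0)
    spatial = x.shape[1:]
    max_off = [s - k for s, k in zip(spatial, size)]

    use_fg = rng.random() < fg_bias and (t > 0).any()
    if use_fg:
        coords = np.argwhere(t > 0)
        vx = coords[rng.integers(len(coords))]
        off = []
        for axis in range(3):
            lo = max(0, vx[axis] - size[axis] + 1)
            hi = min(max_off[axis], vx[axis])
            off.append(int(rng.integers(lo, hi + 1)))
    else:
        off = [int(rng.integers(0, m + 1)) for m in max_off]
    sl = tuple(slice(o, o + k) for o, k in zip(off, size))
    return (np.ascontiguousarray(x[(slice(None),) + sl]),
            np.ascontiguousarray(t[sl]))
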