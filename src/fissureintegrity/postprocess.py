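"""Three-step cleanup of a raw network labeling.

1. False-positive removal: every voxel outside the complete fissure surface
   (known from the lobe segmentation) is set to background.
2. False-negative filling: surface voxels left as background take the
   majority class of their 26-connected intact/incomplete neighbors.  The
   vote runs in synchronous passes (all updates computed from the previous
   state, so the result is independent of traversal order) until no surface
   background remains or ``fill_max_iters`` is hit; stragglers on surface
   components with no labeled voxel at all are assigned the class of the
   Euclidean-nearest labeled surface voxel.  Ties vote "incomplete" — the
   conservative reading for collateral-ventilation screening.
3. Label smoothing: one simultaneous 26-neighborhood majority pass over the
   surface; by default a voxel's own label is excluded from its vote and
   ties (or an isolated voxel) keep the original label.

After the pipeline the label support equals the complete surface exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .boundary import INCOMPLETE, INTACT
from .volio import LabelVolume


class PostprocessError(ValueError):
    pass


@dataclasses.dataclass
class PostprocessConfig:
    connectivity: int = 26
    tie_break: int = INCOMPLETE
    fill_max_iters: int = 100
    smooth_include_center: bool = False

    def __post_init__(self):
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.tie_break not in (INTACT, INCOMPLETE):
            raise ValueError("tie_break must be 1 (intact) or 2 (incomplete)")


def _kernel(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    k = ndimage.generate_binary_structure(3, order).astype(np.float32)
    k[1, 1, 1] = 0.0
    return k


def _neighbor_counts(labels: np.ndarray, kern: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    n1 = ndimage.convolve((labels == INTACT).astype(np.float32), kern,
                          mode="constant")
    n2 = ndimage.convolve((labels == INCOMPLETE).astype(np.float32), kern,
                          mode="constant")
    return np.rint(n1).astype(np.int32), np.rint(n2).astype(np.int32)


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, LabelVolume) else np.asarray(x)


def _wrap(template, data: np.ndarray):
    if isinstance(template, LabelVolume):
        return dataclasses.replace(template, data=data.astype(np.uint8))
    return data.astype(np.uint8)


def remove_false_positives(raw, complete):
    """Background everywhere off the complete fissure; on-surface labels
    unchanged."""
    r = _as_array(raw)
    surf = _as_array(complete).astype(bool)
    if r.shape != surf.shape:
        raise PostprocessError(
            f"grid mismatch: {r.shape} vs {surf.shape}")
    out = np.where(surf, r, 0)
    return _wrap(raw, out)


def fill_false_negatives(mask, complete, cfg: PostprocessConfig | None = None):
    """Assign every background surface voxel the majority class of its
    labeled neighbors; see module docstring for the pass/tie conventions."""
    cfg = cfg or PostprocessConfig()
    m = _as_array(mask).copy()
    surf = _as_array(complete).astype(bool)
    if m.shape != surf.shape:
        raise PostprocessError(f"grid mismatch: {m.shape} vs {surf.shape}")
    if np.any((m > 0) & ~surf):
        raise PostprocessError("mask has labels outside the surface; "
                               "run remove_false_positives first")
    holes = surf & (m == 0)
    if not holes.any():
        return _wrap(mask, m)
    if not (m > 0).any():
        raise PostprocessError(
            "mask is entirely background on a non-empty surface; "
            "nothing to propagate")
    kern = _kernel(cfg.connectivity)
    other = {INTACT: INCOMPLETE, INCOMPLETE: INTACT}[cfg.tie_break]
    for _ in range(cfg.fill_max_iters):
        holes = surf & (m == 0)
        if not holes.any():
            break
        n1, n2 = _neighbor_counts(m, kern)
        tie_n = n1 if cfg.tie_break == INTACT else n2
        oth_n = n2 if cfg.tie_break == INTACT else n1
        upd = holes & ((n1 + n2) > 0)
        if not upd.any():
            break  # remaining holes are disconnected from any label
        new = np.where(tie_n >= oth_n, cfg.tie_break, other)
        m[upd] = new[upd]
    holes = surf & (m == 0)
    if holes.any():
        # stragglers: class of the Euclidean-nearest labeled surface voxel,
        # decided per class so distance ties resolve like the vote tie rule
        d1 = ndimage.distance_transform_edt(m != INTACT)
        d2 = ndimage.distance_transform_edt(m != INCOMPLETE)
        if not (m == INTACT).any():
            d1 = np.full_like(d1, np.inf)
        if not (m == INCOMPLETE).any():
            d2 = np.full_like(d2, np.inf)
        if cfg.tie_break == INCOMPLETE:
            m[holes] = np.where(d1[holes] < d2[holes], INTACT, INCOMPLETE)
        else:
            m[holes] = np.where(d2[holes] < d1[holes], INCOMPLETE, INTACT)
    return _wrap(mask, m)


def smooth_labels(mask, complete, cfg: PostprocessConfig | None = None):
    """One simultaneous majority-vote pass over the surface."""
    cfg = cfg or PostprocessConfig()
    m = _as_array(mask).copy()
    surf = _as_array(complete).astype(bool)
    if m.shape != surf.shape:
        raise PostprocessError(f"grid mismatch: {m.shape} vs {surf.shape}")
    kern = _kernel(cfg.connectivity)
    n1, n2 = _neighbor_counts(m, kern)
    if cfg.smooth_include_center:
        n1 = n1 + (m == INTACT)
        n2 = n2 + (m == INCOMPLETE)
    out = m.copy()
    vote = surf & ((n1 + n2) > 0)
    out[vote & (n1 > n2)] = INTACT
    out[vote & (n2 > n1)] = INCOMPLETE
    # ties and isolated voxels keep their original label
    return _wrap(mask, out)


def postprocess_prediction(raw, complete,
                           cfg: PostprocessConfig | None = None):
    """remove_false_positives -> fill_false_negatives -> smooth_labels."""
    cfg = cfg or PostprocessConfig()
    step1 = remove_false_positives(raw, complete)
    step2 = fill_false_negatives(step1, complete, cfg)
    return smooth_labels(step2, complete, cfg)
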