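"""Synthetic thoracic phantoms with fissure gaps of known location and size.

A phantom case emulates the output contract of an upstream lung / fissure /
lobe segmentation pipeline: a CT-like volume in HU, a left/right lung mask, a
five-lobe segmentation whose lobar boundaries carry fissure-like bright
sheets, and per-side fissure probability maps that are high only where the
fissure is radiographically visible.  Each lobar boundary surface has a
contiguous patch of requested area fraction where the fissure sheet is
absent (the "incomplete" portion), so the true fissure integrity percentage
is known by construction.

Geometry: lungs are two half-overlapping ellipsoids; the oblique fissures
are tilted, smoothly undulating graph surfaces z = f(x, y); the right
horizontal fissure is a near-axial undulating plane.  Where the horizontal
plane dips below the right oblique surface the middle lobe pinches out and
the upper lobe meets the lower lobe directly — reproducing the double
adjacency (RML|RLL anteriorly, RUL|RLL posteriorly) of the right oblique
fissure.

CT texture: parenchyma −850 HU, visible fissure sheet −650 HU one voxel
thick, surrounding body 0 HU, additive Gaussian noise (default SD 30 HU).
Only the contrast between sheet and parenchyma matters downstream, not the
absolute attenuation values.

Default gap fractions follow the completeness reported for human cohorts:
oblique fissures are mostly complete (mean FI% near 90) while the right
horizontal fissure is the most variable and least complete (mean FI% near
68), giving defaults of 0.10 / 0.08 / 0.32 for LOBL / ROBL / RHOR.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import metrics
from .boundary import (LLL, LUL, RLL, RML, RUL, FissureKind,
                       encode_ground_truth, extract_complete_fissure)
from .volio import LabelVolume, Volume3D, read_volume, write_volume

PARENCHYMA_HU = -850.0
FISSURE_HU = -650.0
BODY_HU = 0.0


class GenerationError(RuntimeError):
    """Raised when the requested geometry cannot produce five valid lobes."""


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``gap_*`` are the requested fractions of each lobar boundary surface
    lacking visible fissure.  ``fissure_undulation`` is the amplitude (in
    voxels) of the sinusoidal perturbation of each fissure surface;
    ``noise_sd`` the additive CT noise in HU; ``prob_blur`` the Gaussian
    smoothing scale of the probability maps in voxels.  ``noise_seed``
    defaults to being derived from ``seed``; passing a different value
    regenerates the same geometry under new noise (for reproducibility
    studies).
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: float = 1.0
    gap_lobl: float = 0.10
    gap_robl: float = 0.08
    gap_rhor: float = 0.32
    fissure_undulation: float = 2.0
    noise_sd: float = 30.0
    prob_blur: float = 1.0
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError(
                f"shape must be 3D with every axis >= 32, got {self.shape}")
        for name in ("gap_lobl", "gap_robl", "gap_rhor"):
            g = getattr(self, name)
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {g}")

    def gap_for(self, kind: FissureKind) -> float:
        return {FissureKind.LOBL: self.gap_lobl,
                FissureKind.ROBL: self.gap_robl,
                FissureKind.RHOR: self.gap_rhor}[kind]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d


@dataclasses.dataclass
class PhantomCase:
    """A bundled synthetic subject."""

    ct: Volume3D
    lung_mask: LabelVolume                      # 0 bg, 1 left, 2 right
    lobes: LabelVolume                          # 0 bg, 1..5 lobes
    fissure_prob: dict[str, Volume3D]           # side -> probability map
    gt_integrity: dict[FissureKind, LabelVolume]
    true_fi: dict[FissureKind, float]
    spec: PhantomSpec


def _fissure_surface_fn(rng, nx, ny, nz, und, kind):
    """Random smooth graph surface z = f(x, y) in voxel units."""
    yc = 0.5 * ny
    if kind == "oblique":
        z0 = nz * rng.uniform(0.48, 0.56)
        slope = -rng.uniform(0.28, 0.42) * (nz / ny) * 2.0
    else:  # horizontal
        z0 = nz * rng.uniform(0.62, 0.70)
        slope = rng.uniform(-0.06, 0.06)
    lx = nx * rng.uniform(0.8, 1.4)
    ly = ny * rng.uniform(0.8, 1.4)
    px, py = rng.uniform(0, 2 * np.pi, size=2)
    amp = und * rng.uniform(0.6, 1.0)

    def f(x, y):
        return (z0 + slope * (y - yc)
                + amp * np.sin(2 * np.pi * x / lx + px)
                + amp * np.sin(2 * np.pi * y / ly + py))

    return f


def _grow_patch(surface: np.ndarray, target: int, rng) -> np.ndarray:
    """Contiguous patch of ``target`` voxels grown geodesically on a binary
    surface from a peripheral seed (gaps in real lungs are typically
    peripheral).  If a 26-connected component is exhausted before the target
    is met, growth restarts from the unvisited surface voxel nearest to the
    patch."""
    coords = np.argwhere(surface)
    n = len(coords)
    patch = np.zeros_like(surface, dtype=bool)
    if target <= 0:
        return patch
    if target >= n:
        return surface.astype(bool).copy()

    index = {tuple(c): i for i, c in enumerate(coords)}
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    # seed among the most peripheral third of surface voxels
    order = np.argsort(dist)[::-1]
    candidates = order[: max(1, n // 3)]
    seed_idx = int(rng.choice(candidates))

    visited = np.zeros(n, dtype=bool)
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    grown = 0
    frontier = [seed_idx]
    visited[seed_idx] = True
    while grown < target:
        if not frontier:
            # component exhausted: jump to the unvisited voxel nearest the patch
            unvisited = np.flatnonzero(~visited)
            pc = coords[np.flatnonzero(visited)]
            d = np.linalg.norm(
                coords[unvisited][:, None, :] - pc[None, :, :],
                axis=2).min(axis=1)
            nxt = int(unvisited[np.argmin(d)])
            visited[nxt] = True
            frontier = [nxt]
        new_frontier = []
        for i in frontier:
            if grown >= target:
                break
            c = tuple(coords[i])
            patch[c] = True
            grown += 1
            for off in offsets:
                nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
                j = index.get(nb)
                if j is not None and not visited[j]:
                    visited[j] = True
                    new_frontier.append(j)
        frontier = new_frontier
    return patch


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case; deterministic given ``spec.seed`` (and
    ``spec.noise_seed`` for the CT noise draw)."""
    nx, ny, nz = spec.shape
    geom_rng = np.random.default_rng([int(spec.seed), 0])
    noise_seed = spec.seed if spec.noise_seed is None else spec.noise_seed
    noise_rng = np.random.default_rng([int(noise_seed), 1])

    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")

    def ellipsoid(cx_frac):
        cx, cy, cz = cx_frac * nx, 0.5 * ny, 0.5 * nz
        ax, ay, az = 0.20 * nx, 0.40 * ny, 0.42 * nz
        return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                + ((z - cz) / az) ** 2) <= 1.0

    right = ellipsoid(0.30)
    left = ellipsoid(0.70)
    left &= ~right  # disjoint by construction (centers far apart anyway)

    und = spec.fissure_undulation
    f_lo = _fissure_surface_fn(geom_rng, nx, ny, nz, und, "oblique")
    f_ro = _fissure_surface_fn(geom_rng, nx, ny, nz, und, "oblique")
    f_rh = _fissure_surface_fn(geom_rng, nx, ny, nz, und, "horizontal")

    zlo = f_lo(x, y)
    zro = f_ro(x, y)
    zrh = f_rh(x, y)

    lobes = np.zeros(spec.shape, dtype=np.uint8)
    lobes[left & (z > zlo)] = LUL
    lobes[left & (z <= zlo)] = LLL
    lobes[right & (z <= zro)] = RLL
    lobes[right & (z > zro) & (z > zrh)] = RUL
    lobes[right & (z > zro) & (z <= zrh)] = RML

    counts = {lab: int(np.count_nonzero(lobes == lab))
              for lab in (LUL, LLL, RUL, RML, RLL)}
    if min(counts.values()) < 30:
        raise GenerationError(
            f"degenerate lobe geometry (lobe voxel counts {counts}); "
            "enlarge the grid or reduce undulation")

    lung_mask = np.zeros(spec.shape, dtype=np.uint8)
    lung_mask[left] = 1
    lung_mask[right] = 2

    grid = dict(spacing=np.full(3, spec.spacing), origin=np.zeros(3),
                direction=np.eye(3))
    lobes_vol = LabelVolume(data=lobes, **grid)

    gt_integrity: dict[FissureKind, LabelVolume] = {}
    true_fi: dict[FissureKind, float] = {}
    visible = np.zeros(spec.shape, dtype=bool)
    for kind in FissureKind:
        complete = extract_complete_fissure(lobes_vol, kind)
        surf = complete.data.astype(bool)
        n_surf = int(surf.sum())
        if n_surf == 0:
            raise GenerationError(f"empty boundary surface for {kind.value}")
        target = int(round(spec.gap_for(kind) * n_surf))
        patch = _grow_patch(surf, target, geom_rng)
        intact = surf & ~patch
        gt = encode_ground_truth(
            complete, dataclasses.replace(complete,
                                          data=intact.astype(np.uint8)))
        gt_integrity[kind] = gt
        true_fi[kind] = metrics.fi_percent(gt)
        visible |= intact

    ct = np.full(spec.shape, BODY_HU, dtype=np.float32)
    ct[lung_mask > 0] = PARENCHYMA_HU
    ct[visible] = FISSURE_HU
    if spec.noise_sd > 0:
        ct += noise_rng.normal(0.0, spec.noise_sd,
                               size=spec.shape).astype(np.float32)

    # probability maps: blurred indicator of the visible sheet, rescaled so a
    # locally planar sheet keeps a peak near 1 after smoothing
    scale = spec.prob_blur * np.sqrt(2 * np.pi) if spec.prob_blur > 0 else 1.0
    fissure_prob = {}
    for side, mask in (("left", lung_mask == 1), ("right", lung_mask == 2)):
        ind = (visible & mask).astype(np.float32)
        if spec.prob_blur > 0:
            ind = ndimage.gaussian_filter(ind, spec.prob_blur) * scale
        fissure_prob[side] = Volume3D(
            data=np.clip(ind, 0.0, 1.0), **grid)

    return PhantomCase(
        ct=Volume3D(data=ct, **grid),
        lung_mask=LabelVolume(data=lung_mask, **grid),
        lobes=lobes_vol,
        fissure_prob=fissure_prob,
        gt_integrity=gt_integrity,
        true_fi=true_fi,
        spec=spec,
    )


_RANGE_FIELDS = ("gap_lobl", "gap_robl", "gap_rhor", "fissure_undulation",
                 "noise_sd", "prob_blur")


def generate_cohort(n: int, spec_ranges: dict[str, tuple[float, float]],
                    seed: int, base: PhantomSpec | None = None
                    ) -> list[PhantomCase]:
    """Generate ``n`` cases with ranged fields drawn uniformly per case.

    ``spec_ranges`` maps spec field names (``gap_lobl``, ``gap_robl``,
    ``gap_rhor``, ``fissure_undulation``, ``noise_sd``, ``prob_blur``) to
    inclusive (low, high) ranges; the shorthand key ``gap_fraction`` applies
    one range to all three fissures.  Remaining fields come from ``base``.
    Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not spec_ranges:
        raise ValueError("spec_ranges must not be empty")
    ranges = dict(spec_ranges)
    if "gap_fraction" in ranges:
        r = ranges.pop("gap_fraction")
        for k in ("gap_lobl", "gap_robl", "gap_rhor"):
            ranges.setdefault(k, r)
    for key, (lo, hi) in ranges.items():
        if key not in _RANGE_FIELDS:
            raise ValueError(f"unknown spec field {key!r}")
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: ({lo}, {hi})")
    base = base or PhantomSpec()
    rng = np.random.default_rng(int(seed))
    cases = []
    for _ in range(n):
        draws = {k: float(rng.uniform(lo, hi))
                 for k, (lo, hi) in ranges.items()}
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(base, seed=case_seed, **draws)
        cases.append(generate_case(spec))
    return cases


_GT_FILES = {FissureKind.LOBL: "gt_lobl.nii.gz",
             FissureKind.ROBL: "gt_robl.nii.gz",
             FissureKind.RHOR: "gt_rhor.nii.gz"}


def save_case(case: PhantomCase, outdir: str | Path) -> None:
    """Write a case as a directory of NIfTI files plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(case.ct, outdir / "ct.nii.gz")
    write_volume(case.lung_mask, outdir / "lung.nii.gz")
    write_volume(case.lobes, outdir / "lobes.nii.gz")
    for side, vol in case.fissure_prob.items():
        write_volume(vol, outdir / f"fissure_prob_{side}.nii.gz")
    for kind, gt in case.gt_integrity.items():
        write_volume(gt, outdir / _GT_FILES[kind])
    sidecar = {
        "spec": case.spec.to_dict(),
        "true_fi": {k.value: case.true_fi[k] for k in case.true_fi},
    }
    (outdir / "case.json").write_text(json.dumps(sidecar, indent=2))


def load_case(casedir: str | Path) -> PhantomCase:
    """Read back a case directory written by :func:`save_case`."""
    casedir = Path(casedir)
    sidecar = json.loads((casedir / "case.json").read_text())
    spec_d = dict(sidecar["spec"])
    spec_d["shape"] = tuple(spec_d["shape"])
    spec = PhantomSpec(**spec_d)
    gt = {k: read_volume(casedir / f) for k, f in _GT_FILES.items()
          if (casedir / f).exists()}
    return PhantomCase(
        ct=read_volume(casedir / "ct.nii.gz"),
        lung_mask=read_volume(casedir / "lung.nii.gz"),
        lobes=read_volume(casedir / "lobes.nii.gz"),
        fissure_prob={side: read_volume(casedir / f"fissure_prob_{side}.nii.gz")
                      for side in ("left", "right")},
        gt_integrity=gt,
        true_fi={FissureKind(k): v for k, v in sidecar["true_fi"].items()},
        spec=spec,
    )
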