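"""Lobar-boundary (complete fissure) extraction and ground-truth encoding.

The complete fissure for a given fissure is the full lobar boundary surface
between its adjacent lobes — the union of the radiographically intact fissure
and any incomplete portion.  It is recovered from a five-lobe segmentation by
finding voxels of a reference lobe that are face-adjacent (6-connectivity) to
the partner lobe.  Face adjacency yields the thinnest well-formed digital
surface; using only the reference lobe's side keeps it one voxel thick.

Lobe label scheme: 0 background, 1 LUL, 2 LLL, 3 RUL, 4 RML, 5 RLL.
Integrity mask labels: 0 background, 1 intact fissure, 2 incomplete fissure.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import ndimage

from .volio import LabelVolume

LUL, LLL, RUL, RML, RLL = 1, 2, 3, 4, 5

LOBE_LABELS = {"LUL": LUL, "LLL": LLL, "RUL": RUL, "RML": RML, "RLL": RLL}

#: integrity-mask codes
BACKGROUND, INTACT, INCOMPLETE = 0, 1, 2


class FissureKind(enum.Enum):
    """The three fissures, each defined by (reference lobe, partner lobe) pairs.

    The right oblique fissure separates the middle from the lower lobe
    anteriorly and the upper from the lower lobe posteriorly, hence two
    adjacency pairs; the surface is taken on the reference (first) lobe of
    each pair.
    """

    LOBL = "LOBL"   # left oblique: LUL | LLL
    ROBL = "ROBL"   # right oblique: RML | RLL and RUL | RLL
    RHOR = "RHOR"   # right horizontal: RUL | RML

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return _PAIRS[self]

    @property
    def side(self) -> str:
        return "left" if self is FissureKind.LOBL else "right"


_PAIRS = {
    FissureKind.LOBL: ((LUL, LLL),),
    FissureKind.ROBL: ((RML, RLL), (RUL, RLL)),
    FissureKind.RHOR: ((RUL, RML),),
}

# 6-connectivity structuring element (faces only)
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class MissingLobeError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


def extract_complete_fissure(lobes: LabelVolume, kind: FissureKind,
                             two_sided: bool = False) -> LabelVolume:
    """Binary mask of the complete fissure surface for ``kind``.

    A voxel belongs to the surface when it carries the reference lobe label
    of one of the kind's adjacency pairs and has a 6-neighbor carrying the
    partner label.  With ``two_sided=True`` partner-side voxels adjacent to
    the reference lobe are included as well (a two-voxel-thick surface).

    Raises
    ------
    MissingLobeError
        If any lobe label referenced by ``kind`` is absent.
    """
    data = lobes.data
    present = set(np.unique(data).tolist())
    names = {v: k for k, v in LOBE_LABELS.items()}
    for a, b in kind.pairs:
        for lab in (a, b):
            if lab not in present:
                raise MissingLobeError(
                    f"{kind.value}: lobe {names[lab]} (label {lab}) "
                    "absent from segmentation")

    surf = np.zeros(data.shape, dtype=bool)
    for ref, partner in kind.pairs:
        near_partner = ndimage.binary_dilation(
            data == partner, structure=_FACE_STRUCT)
        surf |= (data == ref) & near_partner
        if two_sided:
            near_ref = ndimage.binary_dilation(
                data == ref, structure=_FACE_STRUCT)
            surf |= (data == partner) & near_ref
    return dataclasses.replace(lobes, data=surf.astype(np.uint8))


def encode_ground_truth(complete: LabelVolume,
                        intact: LabelVolume) -> LabelVolume:
    """Encode an integrity mask: 1 where intact, 2 where complete but not
    intact, 0 elsewhere.  ``intact`` must be a voxelwise subset of
    ``complete``."""
    comp = complete.data.astype(bool)
    inta = intact.data.astype(bool)
    if np.any(inta & ~comp):
        n = int(np.count_nonzero(inta & ~comp))
        raise ConsistencyError(
            f"{n} intact voxels lie outside the complete fissure surface")
    out = np.zeros(comp.shape, dtype=np.uint8)
    out[comp] = INCOMPLETE
    out[inta] = INTACT
    return dataclasses.replace(complete, data=out)
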