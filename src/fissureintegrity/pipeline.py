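"""End-to-end per-case assessment: preprocess -> predict -> post-process ->
report."""

from __future__ import annotations

import dataclasses

import numpy as np

from .boundary import FissureKind, extract_complete_fissure
from .metrics import (FissureReport, UndefinedMetricError, acc_fis,
                      categorize, fi_percent, fis_error)
from .network import predict_integrity
from .nn import AttentionUNet3D
from .phantom import PhantomCase
from .postprocess import PostprocessConfig, postprocess_prediction
from .preprocess import make_network_input, uncrop
from .volio import LabelVolume


def predict_raw(model: AttentionUNet3D, case: PhantomCase,
                kind: FissureKind, margin: int = 2) -> LabelVolume:
    """Raw argmax labeling on the full grid, before post-processing."""
    side = kind.side
    inp = make_network_input(case.ct, case.fissure_prob[side],
                             case.lung_mask, side, margin=margin)
    probs = predict_integrity(model, inp)
    labels = probs.argmax(axis=0).astype(np.uint8)
    return dataclasses.replace(
        case.lobes, data=uncrop(labels, inp.box, inp.full_shape, fill=0))


def assess_case(model: AttentionUNet3D, case: PhantomCase,
                kind: FissureKind,
                post_cfg: PostprocessConfig | None = None,
                margin: int = 2) -> tuple[FissureReport, LabelVolume]:
    """Assess one fissure of one case; returns the report and the final
    post-processed integrity mask."""
    post_cfg = post_cfg or PostprocessConfig()
    raw = predict_raw(model, case, kind, margin=margin)
    complete = extract_complete_fissure(case.lobes, kind)
    final = postprocess_prediction(raw, complete, post_cfg)
    fi = fi_percent(final)
    report = FissureReport(
        fissure=kind, fi_percent=fi,
        n_surface_voxels=int(np.count_nonzero(complete.data)),
        category=categorize(fi))
    gt = case.gt_integrity.get(kind)
    if gt is not None:
        report.acc_fis = acc_fis(final, gt)
        report.true_fi = case.true_fi.get(kind, fi_percent(gt))
        try:
            report.fis_error = fis_error(fi, report.true_fi)
        except UndefinedMetricError:
            report.fis_error = None
    return report, final
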