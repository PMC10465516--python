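"""Quantitative fissure-integrity outputs.

Definitions (all on the complete fissure surface, labels 1 = intact,
2 = incomplete):

    FI%       = 100 * |intact| / |intact u incomplete|
    FIS error = (FI%_pred - FI%_truth) / FI%_truth          (signed ratio)
    ACC_FIS%  = 100 * |correctly labeled surface voxels| / |surface|

Fissures are categorized from FI% as complete (>= 90), partial (>= 10) or
missing (< 10); ROC AUC for complete-vs-rest uses the predicted FI% as the
continuous score with rank (Mann-Whitney) handling of ties.  Cohort
summaries report sample (n-1) standard deviations.  FIS error is aggregated
as the mean of absolute values by default, with the signed mean also
emitted.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np
from scipy import stats

from .boundary import FissureKind
from .volio import LabelVolume


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty or degenerate."""


class Category(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    MISSING = "missing"


@dataclasses.dataclass
class FissureReport:
    """Per-fissure quantitative outputs for one case."""

    fissure: FissureKind
    fi_percent: float
    n_surface_voxels: int
    category: Category
    fis_error: float | None = None      # None when truth FI% = 0
    acc_fis: float | None = None
    true_fi: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fissure"] = self.fissure.value
        d["category"] = self.category.value
        return d


def _surface_counts(mask: LabelVolume | np.ndarray) -> tuple[int, int]:
    data = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
    n_intact = int(np.count_nonzero(data == 1))
    n_incomplete = int(np.count_nonzero(data == 2))
    return n_intact, n_incomplete


def fi_percent(mask: LabelVolume | np.ndarray) -> float:
    """Fissure integrity percentage of an integrity mask."""
    n1, n2 = _surface_counts(mask)
    if n1 + n2 == 0:
        raise UndefinedMetricError("FI% undefined: mask has no surface voxels")
    return 100.0 * n1 / (n1 + n2)


def fis_error(fi_pred: float, fi_truth: float) -> float:
    """Signed relative error of predicted FI% w.r.t. ground truth."""
    if fi_truth == 0:
        raise UndefinedMetricError("FIS error undefined for truth FI% = 0")
    return (fi_pred - fi_truth) / fi_truth


def acc_fis(pred: LabelVolume | np.ndarray,
            truth: LabelVolume | np.ndarray) -> float:
    """Fraction (as a percentage) of surface voxels labeled correctly.

    Both masks must cover the identical surface (same {label > 0} support).
    """
    p = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise UndefinedMetricError("shape mismatch between pred and truth")
    ps, ts = p > 0, t > 0
    if not np.array_equal(ps, ts):
        raise UndefinedMetricError(
            "pred and truth cover different surfaces "
            f"({int(ps.sum())} vs {int(ts.sum())} voxels)")
    n = int(ts.sum())
    if n == 0:
        raise UndefinedMetricError("ACC_FIS% undefined on an empty surface")
    return 100.0 * int(np.count_nonzero((p == t) & ts)) / n


def categorize(fi: float) -> Category:
    """complete (>= 90), partial (>= 10), missing (< 10)."""
    if not 0.0 <= fi <= 100.0:
        raise ValueError(f"FI% must be in [0, 100], got {fi}")
    if fi >= 90.0:
        return Category.COMPLETE
    if fi >= 10.0:
        return Category.PARTIAL
    return Category.MISSING


def auc_complete(scores: list[tuple[float, Category | str]]) -> float:
    """Rank-based ROC AUC for complete-vs-rest.

    ``scores`` holds (predicted FI%, true category) pairs; the complete
    category is the positive class and ties count one half.
    """
    y = np.array([1 if Category(c) is Category.COMPLETE else 0
                  for _, c in scores])
    s = np.array([float(v) for v, _ in scores])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUC undefined without both positive and negative cases")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def reproducibility(fi_by_timepoint: dict[str, dict[str, float]],
                    pairs: list[tuple[str, str]] | None = None
                    ) -> dict[tuple[str, str], dict[str, float]]:
    """Absolute FI% differences between timepoints.

    ``fi_by_timepoint`` maps case id -> {timepoint -> FI%}.  For each
    requested timepoint pair the per-case absolute difference in percentage
    points is summarized as mean and sample SD; cases missing a timepoint
    are excluded with a warning.
    """
    if pairs is None:
        tps = sorted({tp for d in fi_by_timepoint.values() for tp in d})
        pairs = [(a, b) for i, a in enumerate(tps) for b in tps[i + 1:]]
    out = {}
    for a, b in pairs:
        diffs = []
        for cid, d in fi_by_timepoint.items():
            if a not in d or b not in d:
                warnings.warn(
                    f"case {cid}: missing timepoint for pair ({a}, {b}); "
                    "excluded", stacklevel=2)
                continue
            diffs.append(abs(d[a] - d[b]))
        arr = np.asarray(diffs, dtype=float)
        out[(a, b)] = {
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def summarize_cohort(reports: list[FissureReport],
                     grouping: dict | None = None) -> dict:
    """Per-fissure (and optionally per-group) mean +/- SD of each metric.

    ``grouping`` maps a report's index to a group name; empty groups are
    omitted.  Returns a nested dict: fissure -> group -> metric -> stats.
    FIS error is summarized both as mean |error| (default reading) and as
    the signed mean; reports whose truth FI% was 0 carry ``fis_error=None``
    and are excluded from that metric, with their count reported.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    out: dict = {}
    groups = grouping or {i: "all" for i in range(len(reports))}
    for kind in FissureKind:
        sel = [(i, r) for i, r in enumerate(reports) if r.fissure is kind]
        if not sel:
            continue
        per_group: dict = {}
        for i, r in sel:
            per_group.setdefault(groups.get(i, "all"), []).append(r)
        kind_out = {}
        for gname, rs in per_group.items():
            fi_mean, fi_sd = _mean_sd([r.fi_percent for r in rs])
            entry = {
                "n": len(rs),
                "fi_percent": {"mean": fi_mean, "sd": fi_sd},
            }
            accs = [r.acc_fis for r in rs if r.acc_fis is not None]
            if accs:
                m, s = _mean_sd(accs)
                entry["acc_fis"] = {"mean": m, "sd": s}
            errs = [r.fis_error for r in rs if r.fis_error is not None]
            if errs:
                m, s = _mean_sd([abs(e) for e in errs])
                sm, ss = _mean_sd(errs)
                entry["fis_error_abs"] = {"mean": m, "sd": s}
                entry["fis_error_signed"] = {"mean": sm, "sd": ss}
            entry["n_excluded_fis_error"] = sum(
                1 for r in rs if r.fis_error is None)
            kind_out[gname] = entry
        # overall AUC per fissure when truth categories are available
        scored = [(r.fi_percent, categorize(r.true_fi))
                  for _, r in sel if r.true_fi is not None]
        try:
            kind_out["auc"] = auc_complete(scored) if scored else None
        except UndefinedMetricError:
            kind_out["auc"] = None
        out[kind.value] = kind_out
    return out
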