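"""Training orchestration: splits, k-fold plans, and the estimator.

Three independent networks are trained, one per fissure (left oblique,
right oblique, right horizontal), each consuming the corresponding lung's
2-channel input.  Training minimizes the Tversky loss with Adam at a static
learning rate; per-epoch validation loss selects the best epoch.  Subjects
(never crops) are the unit of splitting: the default train/test/validation
proportions are 0.75 / 0.15 / 0.10, and cross-validation uses k = 8 folds
with a 0.10 validation carve-out taken from each fold's training portion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .boundary import FissureKind
from .network import (LossConfig, NetworkConfig, build_network, one_hot,
                      predict_integrity, tversky_loss, tversky_loss_graph)
from .nn import Adam
from .phantom import PhantomCase
from .preprocess import (NetworkInput, crop_target, make_network_input,
                         random_crop, uncrop)
from .volio import LabelVolume


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 2e-4         # static (no schedule)
    epochs: int = 20
    batch_size: int = 2
    crop_size: tuple[int, int, int] = (128, 128, 64)
    proportions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    crops_per_case: int = 4
    fg_crop_prob: float = 0.5
    margin: int = 2
    seed: int = 0

    def __post_init__(self):
        p = self.proportions
        if len(p) != 3 or any(x <= 0 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ValueError(
                "proportions must be three positive values summing to 1")


@dataclasses.dataclass
class SplitPlan:
    """Subject-level assignment to train / validation / test."""

    train: list
    val: list
    test: list

    def __post_init__(self):
        all_ids = self.train + self.val + self.test
        if len(set(map(str, all_ids))) != len(all_ids):
            raise ValueError("splits overlap or contain duplicates")


def make_splits(case_ids: Sequence, proportions=(0.75, 0.15, 0.10),
                seed: int = 0) -> SplitPlan:
    """Random subject-level partition into train/test/val by largest-
    remainder rounding of the proportions; deterministic given ``seed``."""
    n = len(case_ids)
    if n < 3:
        raise ValueError(
            f"need at least 3 cases for a 3-way split, got {n}")
    p_train, p_test, p_val = proportions
    if any(x <= 0 for x in proportions) or abs(sum(proportions) - 1) > 1e-9:
        raise ValueError("proportions must be positive and sum to 1")
    raw = np.array([p_train * n, p_test * n, p_val * n])
    sizes = np.floor(raw).astype(int)
    rema = raw - sizes
    for i in np.argsort(-rema)[: n - sizes.sum()]:
        sizes[i] += 1
    # every split must be non-empty: steal from the largest when needed
    while sizes.min() == 0:
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = [case_ids[i] for i in order]
    n_tr, n_te, n_va = map(int, sizes)
    return SplitPlan(train=ids[:n_tr], test=ids[n_tr:n_tr + n_te],
                     val=ids[n_tr + n_te:])


def kfold_plan(case_ids: Sequence, k: int = 8, seed: int = 0,
               val_fraction: float = 0.10) -> list[SplitPlan]:
    """k subject-level folds: each plan tests one fold (sizes differ by at
    most 1 across folds) and carves ``val_fraction`` of the remaining cases
    out for validation."""
    n = len(case_ids)
    if n < k:
        raise ValueError(f"need at least k={k} cases, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = [case_ids[i] for i in order]
    folds = [list(f) for f in np.array_split(np.arange(n), k)]
    plans = []
    for i in range(k):
        test = [ids[j] for j in folds[i]]
        rest = [ids[j] for f in folds[:i] + folds[i + 1:] for j in f]
        n_val = max(1, int(round(val_fraction * len(rest))))
        plans.append(SplitPlan(train=rest[n_val:], val=rest[:n_val],
                               test=test))
    return plans


def select_best_epoch(history: list[dict]) -> int:
    """Epoch (0-based) with minimum validation loss; ties go to the
    earliest epoch."""
    losses = [h["val_loss"] for h in history if "val_loss" in h]
    if not losses:
        raise ValueError("history has no validation entries")
    return int(np.argmin(losses))


def _case_pair(case: PhantomCase, kind: FissureKind,
               margin: int) -> tuple[NetworkInput, np.ndarray]:
    side = kind.side
    inp = make_network_input(case.ct, case.fissure_prob[side],
                             case.lung_mask, side, margin=margin)
    target = crop_target(case.gt_integrity[kind], inp.box)
    return inp, target


class IntegrityNetModel(BaseEstimator):
    """Trainable fissure-integrity segmenter for one fissure.

    A scikit-learn style estimator whose samples are whole cases rather
    than feature vectors: ``fit`` takes a list of cases (CT, lung mask,
    lobe segmentation, fissure probability, ground-truth integrity mask),
    ``predict`` returns the raw per-case integrity labeling on the full
    grid (before post-processing).

    Parameters mirror the published configuration: Tversky ``alpha=0.05``,
    Adam with static ``learning_rate=0.0002``, random crops of
    ``crop_size`` per epoch, and best-epoch selection on validation loss.
    """

    def __init__(self, kind: FissureKind | str = FissureKind.LOBL,
                 levels: int = 4, base_filters: int = 16,
                 attention_gates: bool = True, alpha: float = 0.05,
                 smooth: float = 1.0, learning_rate: float = 2e-4,
                 epochs: int = 20, batch_size: int = 2,
                 crop_size: tuple[int, int, int] = (128, 128, 64),
                 crops_per_case: int = 4, fg_crop_prob: float = 0.5,
                 margin: int = 2, val_fraction: float = 0.10,
                 seed: int = 0):
        self.kind = kind
        self.levels = levels
        self.base_filters = base_filters
        self.attention_gates = attention_gates
        self.alpha = alpha
        self.smooth = smooth
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.crop_size = crop_size
        self.crops_per_case = crops_per_case
        self.fg_crop_prob = fg_crop_prob
        self.margin = margin
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _kind(self) -> FissureKind:
        return FissureKind(self.kind)

    def _val_loss(self, model, pairs, loss_cfg) -> float:
        total = 0.0
        for inp, target in pairs:
            probs = predict_integrity(model, inp)
            total += tversky_loss(probs, one_hot(target), loss_cfg)
        return total / len(pairs)

    def fit(self, cases: Sequence[PhantomCase],
            val_cases: Sequence[PhantomCase] | None = None
            ) -> "IntegrityNetModel":
        """Train on ``cases``; when ``val_cases`` is not given, a
        ``val_fraction`` share of the cases is held out for epoch
        selection."""
        kind = self._kind()
        div = 2 ** self.levels
        if any(s % div for s in self.crop_size):
            raise ValueError(
                f"crop_size {self.crop_size} not divisible by 2^levels")
        cases = list(cases)
        if val_cases is None:
            if len(cases) < 2:
                raise ValueError("need >= 2 cases to carve out validation")
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(cases))
            n_val = max(1, int(round(self.val_fraction * len(cases))))
            val_cases = [cases[i] for i in order[:n_val]]
            cases = [cases[i] for i in order[n_val:]]
        if not cases:
            raise ValueError("empty training split")

        train_pairs = [_case_pair(c, kind, self.margin) for c in cases]
        val_pairs = [_case_pair(c, kind, self.margin) for c in val_cases]

        net_cfg = NetworkConfig(levels=self.levels,
                                base_filters=self.base_filters,
                                attention_gates=self.attention_gates,
                                seed=self.seed)
        loss_cfg = LossConfig(alpha=self.alpha, smooth=self.smooth)
        model = build_network(net_cfg)
        opt = Adam(model.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng([self.seed, 101])

        history: list[dict] = []
        best = (np.inf, None)
        for epoch in range(self.epochs):
            crops = []
            for inp, target in train_pairs:
                for _ in range(self.crops_per_case):
                    crops.append(random_crop(
                        inp, target, size=tuple(self.crop_size), rng=rng,
                        fg_bias=self.fg_crop_prob))
            crops = [crops[i] for i in rng.permutation(len(crops))]
            epoch_loss, n_batches = 0.0, 0
            for i in range(0, len(crops), self.batch_size):
                batch = crops[i:i + self.batch_size]
                x = np.stack([b[0] for b in batch])
                g = np.stack([one_hot(b[1]) for b in batch])
                opt.zero_grad()
                loss = tversky_loss_graph(model.forward(x), g, loss_cfg)
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            val_loss = self._val_loss(model, val_pairs, loss_cfg)
            history.append({"epoch": epoch,
                            "train_loss": epoch_loss / max(1, n_batches),
                            "val_loss": val_loss})
            if val_loss < best[0]:
                best = (val_loss, model.state_dict())

        if best[1] is not None:
            model.load_state_dict(best[1])
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = select_best_epoch(history)
        self.loss_cfg_ = loss_cfg
        return self

    def predict(self, cases: Sequence[PhantomCase]) -> list[LabelVolume]:
        """Raw (pre-post-processing) integrity labeling per case, embedded
        on the full volume grid."""
        self._check_fitted()
        kind = self._kind()
        out = []
        for case in cases:
            side = kind.side
            inp = make_network_input(case.ct, case.fissure_prob[side],
                                     case.lung_mask, side,
                                     margin=self.margin)
            probs = predict_integrity(self.model_, inp)
            labels = probs.argmax(axis=0).astype(np.uint8)
            full = uncrop(labels, inp.box, inp.full_shape, fill=0)
            out.append(dataclasses.replace(case.lobes, data=full))
        return out

    def score(self, cases: Sequence[PhantomCase]) -> float:
        """Mean voxel accuracy restricted to the true fissure surface
        (raw predictions, fraction in [0, 1])."""
        kind = self._kind()
        preds = self.predict(cases)
        accs = []
        for case, pred in zip(cases, preds):
            gt = case.gt_integrity[kind].data
            surf = gt > 0
            accs.append(float((pred.data[surf] == gt[surf]).mean()))
        return float(np.mean(accs))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


def train_model(cases: Sequence[PhantomCase], kind: FissureKind,
                net_cfg: NetworkConfig | None = None,
                loss_cfg: LossConfig | None = None,
                train_cfg: TrainConfig | None = None,
                val_cases: Sequence[PhantomCase] | None = None
                ) -> tuple[dict, list[dict]]:
    """Functional wrapper over :class:`IntegrityNetModel`; returns the
    trained weights (state dict) and the per-epoch history."""
    net_cfg = net_cfg or NetworkConfig()
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    est = IntegrityNetModel(
        kind=kind, levels=net_cfg.levels, base_filters=net_cfg.base_filters,
        attention_gates=net_cfg.attention_gates, alpha=loss_cfg.alpha,
        smooth=loss_cfg.smooth, learning_rate=train_cfg.learning_rate,
        epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
        crop_size=train_cfg.crop_size,
        crops_per_case=train_cfg.crops_per_case,
        fg_crop_prob=train_cfg.fg_crop_prob, margin=train_cfg.margin,
        seed=train_cfg.seed)
    est.fit(cases, val_cases=val_cases)
    return est.model_.state_dict(), est.history_
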