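"""Episodic training of the backbone + reconstruction head, with stratified
cross-validation and held-out evaluation.

Each optimisation step samples an episode from the training split: k support
and q query subjects per class, disjoint within the episode.  The episode
batch passes through the backbone once; support feature maps are pooled per
class, every query map is reconstructed from both pools in closed form, and
the loss is the query cross-entropy plus 0.03 times the inter-class
orthogonality penalty on the pools.  At test time the support bank defaults
to the full training split of each class — the most information-preserving
reading of pooling "all" support features.

The optimiser is SGD with momentum 0.9; weight decay applies to backbone
weights only (decaying the head's log-scale scalars would fight their
calibration).  The learning rate drops by ×0.1 when the validation loss
fails to improve for 10 consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .backbone import Backbone, BackboneConfig, FeatureMap, build_backbone
from .frn import FRNHead, SupportPool, classify, pool_support
from .losses import AUX_WEIGHT, aux_orthogonality_loss_t, nll_from_log_probs
from .metrics import MetricsReport, evaluate_predictions
from .nn import Linear
from .optim import SGD, ReduceLROnPlateau
from .synthetic import SyntheticCohort, VolumeSample

__all__ = [
    "TrainConfig",
    "Episode",
    "FoldResult",
    "TrainedModel",
    "split_folds",
    "make_episode",
    "train_model",
    "train_single_fold",
    "evaluate",
    "baseline_fc_head",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and episode geometry."""

    lr: float = 0.01
    weight_decay: float = 0.001
    epochs: int = 100
    plateau_patience: int = 10
    lr_factor: float = 0.1
    k_support: int = 3
    q_query: int = 2
    episodes_per_epoch: int = 20
    folds: int = 5
    seed: int = 0
    aux_weight: float = AUX_WEIGHT
    momentum: float = 0.9

    def __post_init__(self):
        if min(self.lr, self.lr_factor) <= 0 or self.weight_decay < 0:
            raise ValueError("lr and lr_factor must be positive, weight_decay >= 0")
        if min(self.epochs, self.plateau_patience, self.k_support,
               self.q_query, self.episodes_per_epoch) < 1:
            raise ValueError("schedule and episode sizes must be positive integers")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class Episode:
    support: dict[int, list[VolumeSample]]
    query: dict[int, list[VolumeSample]]


@dataclass
class FoldResult:
    fold_id: int
    report: MetricsReport
    train_loss_history: list[float] = field(default_factory=list)
    val_loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)


@dataclass
class TrainedModel:
    backbone: Backbone
    head: FRNHead
    backbone_config: BackboneConfig
    train_config: TrainConfig


def split_folds(cohort: SyntheticCohort | list[VolumeSample], folds: int,
                seed: int) -> list[np.ndarray]:
    """Stratified fold assignment: returns, per fold, the held-out indices."""
    from sklearn.model_selection import StratifiedKFold

    samples = cohort.samples if isinstance(cohort, SyntheticCohort) else cohort
    labels = np.array([s.label for s in samples])
    for lbl in (0, 1):
        if int((labels == lbl).sum()) < folds:
            raise ValueError(f"need at least {folds} samples of class {lbl}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def make_episode(split: list[VolumeSample], k_support: int, q_query: int,
                 rng: np.random.Generator) -> Episode:
    """Sample k support + q query subjects per class without replacement."""
    by_class = {0: [s for s in split if s.label == 0],
                1: [s for s in split if s.label == 1]}
    need = k_support + q_query
    support, query = {}, {}
    for lbl, pool in by_class.items():
        if len(pool) < need:
            raise ValueError(
                f"class {lbl} has {len(pool)} samples; episode needs {need}")
        idx = rng.choice(len(pool), size=need, replace=False)
        support[lbl] = [pool[i] for i in idx[:k_support]]
        query[lbl] = [pool[i] for i in idx[k_support:]]
    return Episode(support=support, query=query)


def _batch_tensor(samples: list[VolumeSample]) -> Tensor:
    return Tensor(np.stack([s.volume for s in samples])[:, None])


def _flatten_features(out: Tensor) -> tuple[Tensor, int]:
    """(N, d, D', H', W') activations → (N·r)×d row matrix (row-major over
    depth, height, width within each sample) and the per-sample row count r."""
    n, d = out.shape[0], out.shape[1]
    r = int(np.prod(out.shape[2:]))
    flat = out.transpose(0, 2, 3, 4, 1).reshape(n * r, d)
    return flat, r


def _episode_loss(backbone: Backbone, head: FRNHead, episode: Episode,
                  aux_weight: float) -> Tensor:
    sup0, sup1 = episode.support[0], episode.support[1]
    qry = episode.query[0] + episode.query[1]
    batch = sup0 + sup1 + qry
    out = backbone(_batch_tensor(batch))
    flat, r = _flatten_features(out)
    k0, k1 = len(sup0), len(sup1)
    pool0 = flat[0 : k0 * r]
    pool1 = flat[k0 * r : (k0 + k1) * r]
    queries = flat[(k0 + k1) * r :]
    dist = head.distances(queries, r, [(pool0, k0), (pool1, k1)])
    log_p = head.log_probabilities(dist)
    labels = np.array([s.label for s in qry])
    ce = nll_from_log_probs(log_p, labels)
    aux = aux_orthogonality_loss_t([pool0, pool1])
    return ce + aux * aux_weight


def _support_bank(backbone: Backbone, split: list[VolumeSample],
                  max_per_class: int | None = None) -> list[SupportPool]:
    """Eval-mode feature-map pools, one per class, from a sample list."""
    pools = []
    for lbl in (0, 1):
        members = [s for s in split if s.label == lbl]
        if max_per_class is not None:
            members = members[:max_per_class]
        if not members:
            raise ValueError(f"support source has no samples of class {lbl}")
        maps = _feature_maps(backbone, members)
        pools.append(pool_support(maps, class_id=lbl))
    return pools


def _feature_maps(backbone: Backbone, samples: list[VolumeSample],
                  batch_size: int = 16) -> list[FeatureMap]:
    was_training = backbone.training
    backbone.eval()
    maps: list[FeatureMap] = []
    try:
        with no_grad():
            for i in range(0, len(samples), batch_size):
                out = backbone(_batch_tensor(samples[i : i + batch_size]))
                data = out.data
                spatial = tuple(int(s) for s in data.shape[2:])
                flat = data.transpose(0, 2, 3, 4, 1).reshape(data.shape[0], -1, data.shape[1])
                maps.extend(FeatureMap(values=v, spatial_shape=spatial) for v in flat)
    finally:
        backbone.train(was_training)
    return maps


def evaluate(model: TrainedModel, split: list[VolumeSample],
             support_source: list[VolumeSample]) -> MetricsReport:
    """Classify every sample of ``split`` against the support bank built from
    ``support_source`` (all of it, per class) and report the metrics."""
    pools = _support_bank(model.backbone, support_source)
    params = model.head.params()
    y_true, y_pred, scores = [], [], []
    for fmap in zip(split, _feature_maps(model.backbone, split)):
        sample, q = fmap
        pred, probs, _ = classify(q, pools, params)
        y_true.append(sample.label)
        y_pred.append(pred)
        scores.append(probs[1])
    return evaluate_predictions(y_true, y_pred, scores)


def _validation_loss(backbone: Backbone, head: FRNHead,
                     train_split: list[VolumeSample],
                     val_split: list[VolumeSample]) -> float:
    from .losses import cross_entropy

    pools = _support_bank(backbone, train_split)
    params = head.params()
    y, p1 = [], []
    for sample, q in zip(val_split, _feature_maps(backbone, val_split)):
        _, probs, _ = classify(q, pools, params)
        y.append(sample.label)
        p1.append(probs[1])
    return cross_entropy(np.array(y), np.array(p1))


def train_single_fold(train_split: list[VolumeSample],
                      val_split: list[VolumeSample],
                      cfg: TrainConfig, bcfg: BackboneConfig,
                      fold_id: int = 0) -> tuple[TrainedModel, FoldResult]:
    """Run the episodic loop on one train/validation split."""
    backbone = build_backbone(bcfg, seed=cfg.seed + 1009 * fold_id + 1)
    head = FRNHead()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, fold_id]))
    opt = SGD(
        [{"params": backbone.parameters(), "weight_decay": cfg.weight_decay},
         {"params": head.parameters(), "weight_decay": 0.0}],
        lr=cfg.lr, momentum=cfg.momentum)
    sched = ReduceLROnPlateau(opt, factor=cfg.lr_factor, patience=cfg.plateau_patience)
    result = FoldResult(fold_id=fold_id, report=None)

    for _epoch in range(cfg.epochs):
        backbone.train()
        epoch_losses = []
        for _ in range(cfg.episodes_per_epoch):
            episode = make_episode(train_split, cfg.k_support, cfg.q_query, rng)
            loss = _episode_loss(backbone, head, episode, cfg.aux_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {_epoch}, "
                    f"lr={opt.lr:.3g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss = _validation_loss(backbone, head, train_split, val_split)
        result.train_loss_history.append(float(np.mean(epoch_losses)))
        result.val_loss_history.append(val_loss)
        result.lr_history.append(opt.lr)
        sched.step(val_loss)

    model = TrainedModel(backbone=backbone, head=head,
                         backbone_config=bcfg, train_config=cfg)
    result.report = evaluate(model, val_split, train_split)
    return model, result


def train_model(cohort: SyntheticCohort | list[VolumeSample], cfg: TrainConfig,
                bcfg: BackboneConfig, folds_to_run: list[int] | None = None
                ) -> tuple[list[TrainedModel], list[FoldResult]]:
    """Cross-validated training: one model per (held-out) fold.

    ``folds_to_run`` restricts execution to a subset of folds (the split is
    still computed over all of them), which keeps small studies cheap.
    """
    samples = cohort.samples if isinstance(cohort, SyntheticCohort) else cohort
    assignments = split_folds(samples, cfg.folds, cfg.seed)
    models, results = [], []
    for fold_id, held_out in enumerate(assignments):
        if folds_to_run is not None and fold_id not in folds_to_run:
            continue
        held = set(int(i) for i in held_out)
        train_split = [s for i, s in enumerate(samples) if i not in held]
        val_split = [s for i, s in enumerate(samples) if i in held]
        model, result = train_single_fold(train_split, val_split, cfg, bcfg, fold_id)
        models.append(model)
        results.append(result)
    return models, results


# -- fully-connected baseline -------------------------------------------------

def baseline_fc_head(cohort: SyntheticCohort | list[VolumeSample], cfg: TrainConfig,
                     bcfg: BackboneConfig,
                     folds_to_run: list[int] | None = None) -> list[FoldResult]:
    """Same backbone and schedule, but the reconstruction head is replaced by
    global average pooling + a dense softmax layer — the in-repo reference
    point for what the reconstruction head adds."""
    samples = cohort.samples if isinstance(cohort, SyntheticCohort) else cohort
    assignments = split_folds(samples, cfg.folds, cfg.seed)
    results = []
    for fold_id, held_out in enumerate(assignments):
        if folds_to_run is not None and fold_id not in folds_to_run:
            continue
        held = set(int(i) for i in held_out)
        train_split = [s for i, s in enumerate(samples) if i not in held]
        val_split = [s for i, s in enumerate(samples) if i in held]
        results.append(_train_fc_fold(train_split, val_split, cfg, bcfg, fold_id))
    return results


def _fc_log_probs(backbone: Backbone, fc: Linear, samples: list[VolumeSample]) -> Tensor:
    out = backbone(_batch_tensor(samples))
    pooled = out.mean(axis=(2, 3, 4))  # global average pool → (N, d)
    logits = fc(pooled)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=1, keepdims=True).log()


def _train_fc_fold(train_split, val_split, cfg: TrainConfig, bcfg: BackboneConfig,
                   fold_id: int) -> FoldResult:
    from .losses import cross_entropy

    backbone = build_backbone(bcfg, seed=cfg.seed + 1009 * fold_id + 1)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, fold_id, 7]))
    fc = Linear(bcfg.feature_channels, 2,
                rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, fold_id, 11])))
    opt = SGD([{"params": backbone.parameters(), "weight_decay": cfg.weight_decay},
               {"params": fc.parameters(), "weight_decay": 0.0}],
              lr=cfg.lr, momentum=cfg.momentum)
    sched = ReduceLROnPlateau(opt, factor=cfg.lr_factor, patience=cfg.plateau_patience)
    batch = 2 * (cfg.k_support + cfg.q_query)
    result = FoldResult(fold_id=fold_id, report=None)

    for _epoch in range(cfg.epochs):
        backbone.train()
        losses = []
        for _ in range(cfg.episodes_per_epoch):
            idx = rng.choice(len(train_split), size=min(batch, len(train_split)),
                             replace=False)
            chunk = [train_split[i] for i in idx]
            log_p = _fc_log_probs(backbone, fc, chunk)
            loss = nll_from_log_probs(log_p, np.array([s.label for s in chunk]))
            if not np.isfinite(loss.data):
                raise RuntimeError("baseline training diverged (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        backbone.eval()
        with no_grad():
            log_p = _fc_log_probs(backbone, fc, val_split)
        p1 = np.exp(log_p.data[:, 1])
        val_loss = cross_entropy(np.array([s.label for s in val_split]), p1)
        result.train_loss_history.append(float(np.mean(losses)))
        result.val_loss_history.append(val_loss)
        result.lr_history.append(opt.lr)
        sched.step(val_loss)

    backbone.eval()
    with no_grad():
        log_p = _fc_log_probs(backbone, fc, val_split)
    scores = np.exp(log_p.data[:, 1])
    preds = (scores >= 0.5).astype(int)
    y = np.array([s.label for s in val_split])
    result.report = evaluate_predictions(y, preds, scores)
    return result
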