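"""Leave-one-subject-out evaluation, metrics, and ablation variants.

Every subject serves once as the unlabeled target/test domain while the
remaining subjects form the labeled source domain. Reports follow the
ACC / macro-F1 / Cohen's-kappa triple, per split and mean +/- STD across
splits. Classification is per 4-s window (no trial-level vote by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .dann import DannModel, TrainConfig, make_rng_streams, predict, train
from .dataset import FeatureDataset, Normalizer
from .satfem import GatBranchConfig, ResNetBranchConfig

__all__ = [
    "LosoSplit",
    "MetricsReport",
    "AblationVariant",
    "ABLATION_VARIANTS",
    "make_loso_splits",
    "compute_metrics",
    "run_loso",
    "run_ablation",
]


@dataclass(frozen=True)
class LosoSplit:
    source_subjects: tuple
    target_subject: object

    def __post_init__(self):
        if self.target_subject in self.source_subjects:
            raise ValueError("target subject must not appear among sources")


def make_loso_splits(subject_ids) -> list[LosoSplit]:
    """One split per subject, in the cohort's subject order."""
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [
        LosoSplit(tuple(s for s in ids if s != t), t) for t in ids
    ]


@dataclass
class MetricsReport:
    """Confusion matrix (rows true, cols predicted) and summary scalars."""

    confusion: np.ndarray
    accuracy: float
    macro_f1: float
    kappa: float
    n: int

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "n": self.n,
        }


def compute_metrics(y_true, y_pred, n_classes: int) -> MetricsReport:
    """ACC, macro-F1 and Cohen's kappa.

    Macro-F1 averages per-class F1 over classes present in either the truth
    or the predictions; kappa is (p_o - p_e) / (1 - p_e) with expected
    agreement p_e from the marginals.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.arange(n_classes)
    conf = skm.confusion_matrix(y_true, y_pred, labels=labels)
    acc = float(np.trace(conf)) / float(conf.sum())
    present = np.union1d(np.unique(y_true), np.unique(y_pred))
    f1_per_class = skm.f1_score(
        y_true, y_pred, labels=present, average=None, zero_division=0
    )
    macro_f1 = float(np.mean(f1_per_class))
    with np.errstate(invalid="ignore"):
        kappa = float(skm.cohen_kappa_score(y_true, y_pred, labels=labels))
    if not np.isfinite(kappa):
        # p_e = 1 only when both marginals concentrate on one class, which
        # forces perfect agreement; define kappa = 1 there instead of 0/0
        kappa = 1.0 if acc == 1.0 else 0.0
    return MetricsReport(confusion=conf, accuracy=acc, macro_f1=macro_f1,
                         kappa=kappa, n=int(conf.sum()))


@dataclass(frozen=True)
class AblationVariant:
    """Which components are active: activity branch, topology branch, DANN."""

    id: str
    use_activity_branch: bool
    use_topology_branch: bool
    use_dann: bool

    def __post_init__(self):
        if not (self.use_activity_branch or self.use_topology_branch):
            raise ValueError("at least one branch must be enabled")


ABLATION_VARIANTS: dict[str, AblationVariant] = {
    "SAE": AblationVariant("SAE", True, False, False),
    "STE": AblationVariant("STE", False, True, False),
    "SAE-STE": AblationVariant("SAE-STE", True, True, False),
    "SAE-DANN": AblationVariant("SAE-DANN", True, False, True),
    "STE-DANN": AblationVariant("STE-DANN", False, True, True),
    "DSP": AblationVariant("DSP", True, True, True),
}


def _build_model(variant: AblationVariant, n_classes: int, cfg: TrainConfig,
                 rngs, gat_cfg, resnet_cfg, layout_hw, n_nodes) -> DannModel:
    return DannModel(
        n_classes=n_classes,
        rng_streams=rngs,
        gat_cfg=gat_cfg,
        resnet_cfg=resnet_cfg,
        use_activity=variant.use_activity_branch,
        use_topology=variant.use_topology_branch,
        use_dann=variant.use_dann,
        dropout=cfg.dropout,
        n_nodes=n_nodes,
        input_hw=layout_hw,
    )


def run_loso(
    data: FeatureDataset,
    variant: AblationVariant,
    cfg: TrainConfig,
    gat_cfg: GatBranchConfig | None = None,
    resnet_cfg: ResNetBranchConfig | None = None,
    splits: list[LosoSplit] | None = None,
) -> dict:
    """Train and evaluate the variant on every leave-one-subject-out split.

    Per split: the training-split z-score normaliser is fit on source DE
    features; adversarial variants additionally see the target subject's
    unlabeled windows through the domain loss. Returns per-split reports,
    per-split histories and a mean +/- STD summary.
    """
    subjects = data.subject_ids()
    splits = splits or make_loso_splits(subjects)
    n_classes = data.n_classes
    layout_hw = (data.layout.height, data.layout.width)
    n_nodes = len(data.layout)
    per_split, histories = [], []
    for si, split in enumerate(splits):
        source = data.split_by_subjects(split.source_subjects)
        target = data.split_by_subjects([split.target_subject])
        # one deterministic seed per (run seed, split index)
        split_seed = int(
            np.random.SeedSequence([cfg.seed, si]).generate_state(1)[0] % (2**31)
        )
        split_cfg = TrainConfig(
            lr=cfg.lr, batch=cfg.batch, dropout=cfg.dropout, epochs=cfg.epochs,
            seed=split_seed, lambda_mode=cfg.lambda_mode,
            lambda_value=cfg.lambda_value, mode=cfg.mode,
            use_dann=variant.use_dann,
        )
        rngs = make_rng_streams(split_seed)
        model = _build_model(variant, n_classes, split_cfg, rngs,
                             gat_cfg, resnet_cfg, layout_hw, n_nodes)
        normalizer = Normalizer.fit(source.de)
        model, hist = train(
            model, source, target if variant.use_dann else None,
            split_cfg, normalizer=normalizer, rng_streams=rngs,
            eval_each_epoch=False,
        )
        pred = predict(model, target, normalizer)
        report = compute_metrics(target.labels, pred, n_classes)
        per_split.append({"target_subject": split.target_subject,
                          "report": report})
        histories.append(hist)
    accs = np.array([p["report"].accuracy for p in per_split])
    f1s = np.array([p["report"].macro_f1 for p in per_split])
    kappas = np.array([p["report"].kappa for p in per_split])
    return {
        "variant": variant.id,
        "per_split": per_split,
        "histories": histories,
        "summary": {
            "acc_mean": float(accs.mean()), "acc_std": float(accs.std()),
            "f1_mean": float(f1s.mean()), "f1_std": float(f1s.std()),
            "kappa_mean": float(kappas.mean()), "kappa_std": float(kappas.std()),
            "n_splits": len(per_split),
        },
    }


def run_ablation(
    data: FeatureDataset,
    variants: list[str] | None = None,
    cfg: TrainConfig | None = None,
    gat_cfg: GatBranchConfig | None = None,
    resnet_cfg: ResNetBranchConfig | None = None,
) -> dict[str, dict]:
    """Run several ablation variants on the same cohort and seed."""
    cfg = cfg or TrainConfig()
    out = {}
    for vid in variants or list(ABLATION_VARIANTS):
        variant = ABLATION_VARIANTS[vid]
        out[vid] = run_loso(data, variant, cfg, gat_cfg, resnet_cfg)
    return out
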