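"""Domain-adversarial training of the dual-branch extractor.

The model has three parameter groups: the shared feature extractor
``theta_f`` (the dual-branch network), an emotion classifier ``phi_y``
(one fully connected K-way layer) and a domain classifier ``psi_d``
(a 2-layer MLP deciding source vs target subject). The adversarial objective

    E(theta_f, phi_y, psi_d) = sum_{source} L_emotion - lambda * sum_{s+t} L_domain

is realised either by a gradient-reversal layer (identity forward, gradient
scaled by -lambda on the way back into the extractor; the optimizer then
simply minimises L_emotion + L_domain), or by explicit alternation:
minimise E over (theta_f, phi_y), then maximise it over psi_d.

Unlabeled target-domain windows participate only through the domain loss;
their emotion labels are never consumed during training (transductive
protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, gradient_reversal
from .dataset import FeatureDataset, Normalizer
from .nn import Adam, Dropout, Linear, Module
from .satfem import GatBranchConfig, ResNetBranchConfig, Satfem

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "DannModel",
    "lambda_schedule",
    "train",
    "predict",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults follow the reference protocol
    (Adam, lr 5e-4, batch 64, dropout 0.7, cross-entropy)."""

    lr: float = 5e-4
    batch: int = 64
    dropout: float = 0.7
    epochs: int = 100
    seed: int = 0
    lambda_mode: str = "ramp"  # "ramp": 2/(1+e^{-10 p}) - 1, or "constant"
    lambda_value: float = 1.0  # asymptote (ramp) or the constant value
    mode: str = "grl_joint"  # or "alternating"
    use_dann: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch % 2:
            raise ValueError("batch must be even (half source, half target)")
        if self.mode not in ("grl_joint", "alternating"):
            raise ValueError("mode must be grl_joint or alternating")
        if self.lambda_mode not in ("ramp", "constant"):
            raise ValueError("lambda_mode must be ramp or constant")


@dataclass
class LossBreakdown:
    """Objective decomposition in nats. ``e_total`` is the adversarial
    objective L_emotion - lambda * L_domain."""

    e_total: float
    l_emotion: float
    l_domain: float
    lam: float

    def as_dict(self) -> dict:
        return {
            "e_total": self.e_total,
            "l_emotion": self.l_emotion,
            "l_domain": self.l_domain,
            "lambda": self.lam,
        }


def lambda_schedule(cfg: TrainConfig, progress: float) -> float:
    """GRL coefficient at training progress ``p`` in [0, 1]."""
    if not cfg.use_dann:
        return 0.0
    if cfg.lambda_mode == "constant":
        return cfg.lambda_value
    return cfg.lambda_value * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)


class DannModel(Module):
    """Feature extractor + emotion head (+ optional domain head)."""

    def __init__(
        self,
        n_classes: int,
        rng_streams: dict[str, np.random.Generator],
        gat_cfg: GatBranchConfig | None = None,
        resnet_cfg: ResNetBranchConfig | None = None,
        use_activity: bool = True,
        use_topology: bool = True,
        use_dann: bool = True,
        dropout: float = 0.7,
        domain_hidden: int = 64,
        n_nodes: int = 62,
        input_hw: tuple[int, int] = (9, 9),
    ):
        super().__init__()
        self.n_classes = n_classes
        self.use_dann = use_dann
        self.extractor = Satfem(
            rng_streams["extractor"], gat_cfg, resnet_cfg,
            use_activity=use_activity, use_topology=use_topology,
            n_nodes=n_nodes, input_hw=input_hw,
        )
        fused = self.extractor.out_dim
        self.drop = Dropout(dropout)
        self.emotion_head = Linear(fused, n_classes, rng_streams["emotion"])
        if use_dann:
            self.domain_fc1 = Linear(fused, domain_hidden, rng_streams["domain"])
            self.domain_fc2 = Linear(domain_hidden, 2, rng_streams["domain"])

    # -- forward pieces -------------------------------------------------------
    def features(self, maps, nodes, adjacency) -> Tensor:
        m = Tensor(maps) if maps is not None and not isinstance(maps, Tensor) else maps
        f = Tensor(nodes) if nodes is not None and not isinstance(nodes, Tensor) else nodes
        return self.extractor(m, f, adjacency)

    def emotion_logits(self, h: Tensor) -> Tensor:
        return self.emotion_head(h)

    def domain_logits(self, h: Tensor, lam: float) -> Tensor:
        if not self.use_dann:
            raise RuntimeError("model was built without a domain head")
        return self.domain_fc2(self.domain_fc1(gradient_reversal(h, lam)).relu())

    def forward(self, maps, nodes, adjacency, lam: float = 0.0):
        """Return (H, emotion probabilities, domain probabilities or None)."""
        h = self.features(maps, nodes, adjacency)
        y = self.emotion_logits(h).softmax(axis=-1)
        d = self.domain_logits(h, lam).softmax(axis=-1) if self.use_dann else None
        return h, y, d


def make_rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent generators so ablated models share initial weights
    for the components they have in common."""
    names = ["extractor", "emotion", "domain", "batching", "target_batching",
             "dropout_source", "dropout_target"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def total_loss(
    model: DannModel,
    source: tuple[np.ndarray, np.ndarray, np.ndarray],
    target: tuple[np.ndarray, np.ndarray] | None,
    adjacency: np.ndarray,
    lam: float,
    target_labels=None,
) -> LossBreakdown:
    """Evaluate the objective on explicit batches (no parameter update).

    ``source``: (maps, nodes, emotion_labels); ``target``: (maps, nodes).
    Passing emotion labels for target samples is a protocol violation and is
    rejected.
    """
    if target_labels is not None:
        raise ValueError("target-domain samples must not carry emotion labels")
    s_maps, s_nodes, s_y = source
    h_s = model.features(s_maps, s_nodes, adjacency)
    l_em = model.emotion_logits(h_s).cross_entropy(s_y)
    if model.use_dann and target is not None:
        t_maps, t_nodes = target
        h_t = model.features(t_maps, t_nodes, adjacency)
        d_s = model.domain_logits(h_s, lam)
        d_t = model.domain_logits(h_t, lam)
        n_s, n_t = d_s.shape[0], d_t.shape[0]
        l_dom_t = (d_s.cross_entropy(np.zeros(n_s, dtype=int)) * (n_s / (n_s + n_t))
                   + d_t.cross_entropy(np.ones(n_t, dtype=int)) * (n_t / (n_s + n_t)))
        l_dom = float(l_dom_t.data)
    else:
        l_dom = 0.0
    l_em_f = float(l_em.data)
    return LossBreakdown(e_total=l_em_f - lam * l_dom, l_emotion=l_em_f,
                         l_domain=l_dom, lam=lam)


def _batch_indices(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n - batch + 1, batch):
        yield order[i : i + batch]


def predict(model: DannModel, data: FeatureDataset, normalizer: Normalizer,
            batch: int = 256) -> np.ndarray:
    """Emotion-head argmax predictions in eval mode (running BN statistics)."""
    model.eval()
    maps, nodes = data.model_views(normalizer)
    out = []
    for i in range(0, len(data), batch):
        h = model.features(maps[i : i + batch], nodes[i : i + batch], data.adjacency)
        logits = model.emotion_logits(h)
        out.append(logits.data.argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def train(
    model: DannModel,
    source_data: FeatureDataset,
    target_data: FeatureDataset | None,
    cfg: TrainConfig,
    normalizer: Normalizer | None = None,
    rng_streams: dict[str, np.random.Generator] | None = None,
    eval_each_epoch: bool = True,
) -> tuple[DannModel, list[dict]]:
    """Run the adversarial (or plain supervised) training loop.

    Per step, half a batch of labeled source windows is drawn; in adversarial
    mode it is paired with half a batch of unlabeled target windows. The
    source and target halves pass through the extractor separately (each with
    its own batch statistics). History records per-epoch loss means and
    source/target accuracy; everything is driven by named rng streams so a
    rerun with the same seed is bit-identical.
    """
    if len(source_data) == 0:
        raise ValueError("source domain is empty")
    adversarial = cfg.use_dann and model.use_dann and target_data is not None
    if cfg.use_dann and target_data is not None and len(target_data) == 0:
        raise ValueError("target domain is empty")
    rngs = rng_streams or make_rng_streams(cfg.seed)
    normalizer = normalizer or Normalizer.fit(source_data.de)

    s_maps, s_nodes = source_data.model_views(normalizer)
    s_y = source_data.labels
    if target_data is not None:
        t_maps, t_nodes = target_data.model_views(normalizer)
    adjacency = source_data.adjacency

    params = model.parameters()
    if cfg.mode == "alternating" and adversarial:
        fe_em = (model.extractor.parameters()
                 + model.emotion_head.parameters())
        dom = model.domain_fc1.parameters() + model.domain_fc2.parameters()
        opt_main = Adam(fe_em, lr=cfg.lr)
        opt_dom = Adam(dom, lr=cfg.lr)
    else:
        opt_main = Adam(params, lr=cfg.lr)
        opt_dom = None

    half = cfg.batch // 2
    n_s = len(source_data)
    steps_per_epoch = max(n_s // half, 1)
    total_steps = cfg.epochs * steps_per_epoch
    history: list[dict] = []
    step = 0

    for epoch in range(cfg.epochs):
        model.train()
        ep_em, ep_dom, ep_tot, ep_lam = [], [], [], []
        src_iter = _batch_indices(n_s, min(half, n_s), rngs["batching"])
        if adversarial:
            tgt_order = rngs["target_batching"].permutation(len(target_data))
            tgt_pos = 0
        for sb in src_iter:
            lam = lambda_schedule(cfg, step / max(total_steps - 1, 1))
            opt_main.zero_grad()
            if opt_dom is not None:
                opt_dom.zero_grad()

            h_s = model.features(s_maps[sb], s_nodes[sb], adjacency)
            h_s = model.drop(h_s, rngs["dropout_source"])
            l_em = model.emotion_logits(h_s).cross_entropy(s_y[sb])

            if adversarial:
                tb = np.array([
                    tgt_order[(tgt_pos + j) % len(tgt_order)] for j in range(half)
                ])
                tgt_pos += half
                h_t = model.features(t_maps[tb], t_nodes[tb], adjacency)
                h_t = model.drop(h_t, rngs["dropout_target"])
                if cfg.mode == "grl_joint":
                    d_s = model.domain_logits(h_s, lam)
                    d_t = model.domain_logits(h_t, lam)
                    l_dom = 0.5 * (d_s.cross_entropy(np.zeros(len(sb), dtype=int))
                                   + d_t.cross_entropy(np.ones(len(tb), dtype=int)))
                    loss = l_em + l_dom
                    loss.backward()
                    _check_finite(loss, epoch, step)
                    opt_main.step()
                else:  # explicit alternation of Eq 27 / Eq 28
                    d_s = model.domain_logits(h_s, 0.0)
                    d_t = model.domain_logits(h_t, 0.0)
                    l_dom = 0.5 * (d_s.cross_entropy(np.zeros(len(sb), dtype=int))
                                   + d_t.cross_entropy(np.ones(len(tb), dtype=int)))
                    # min over (theta_f, phi_y) of L_em - lambda L_dom
                    loss_a = l_em - lam * l_dom
                    loss_a.backward()
                    _check_finite(loss_a, epoch, step)
                    opt_main.step()
                    # max over psi_d of -lambda L_dom  ==  min of L_dom
                    opt_dom.zero_grad()
                    model.zero_grad()
                    h_s2 = model.features(s_maps[sb], s_nodes[sb], adjacency)
                    h_t2 = model.features(t_maps[tb], t_nodes[tb], adjacency)
                    d_s2 = model.domain_logits(h_s2, 0.0)
                    d_t2 = model.domain_logits(h_t2, 0.0)
                    l_dom_b = 0.5 * (d_s2.cross_entropy(np.zeros(len(sb), dtype=int))
                                     + d_t2.cross_entropy(np.ones(len(tb), dtype=int)))
                    l_dom_b.backward()
                    opt_dom.step()
                l_dom_val = float(l_dom.data)
            else:
                l_em.backward()
                _check_finite(l_em, epoch, step)
                opt_main.step()
                l_dom_val = 0.0

            l_em_val = float(l_em.data)
            ep_em.append(l_em_val)
            ep_dom.append(l_dom_val)
            ep_tot.append(l_em_val - lam * l_dom_val)
            ep_lam.append(lam)
            step += 1

        rec = {
            "epoch": epoch,
            "e_total": float(np.mean(ep_tot)),
            "l_emotion": float(np.mean(ep_em)),
            "l_domain": float(np.mean(ep_dom)),
            "lambda": float(ep_lam[-1]),
        }
        if eval_each_epoch:
            pred_s = predict(model, source_data, normalizer)
            rec["source_acc"] = float((pred_s == s_y).mean())
            if target_data is not None and (target_data.labels >= 0).all():
                pred_t = predict(model, target_data, normalizer)
                rec["target_acc"] = float((pred_t == target_data.labels).mean())
        history.append(rec)
    model.eval()
    return model, history


def _check_finite(loss, epoch: int, step: int) -> None:
    if not np.isfinite(loss.data):
        raise RuntimeError(
            f"non-finite loss at epoch {epoch}, step {step}: {float(loss.data)}"
        )
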