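"""Weakly supervised multiple-instance training with top-k proxy labels.

Only slide-level diagnoses are available, so per-patch labels are
manufactured during training: every patch sampled from a normal slide is
labelled normal, while in a bag from a coeliac slide only the ``alpha``
"least normal" patches (ranked by the model's own normal-head probability)
receive a coeliac label, the ``beta`` "most normal" receive a normal label,
and the remainder are masked out of the loss entirely so no gradient flows
from them. One optimiser step is taken per slide visit; each epoch visits
every slide once in a shuffled order with a freshly sampled bag of 100
patches drawn with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, TinyConvNet, sigmoid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """MIL training recipe: 10 epochs, bag 100, alpha=10, beta=0, Adam 1e-4."""

    epochs: int = 10
    bag_size: int = 100
    alpha: int = 10
    beta: int = 0
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.alpha + self.beta > self.bag_size:
            raise ValueError("alpha + beta must not exceed the bag size")


@dataclass(frozen=True)
class Bag:
    """Indices (with replacement) into a slide's kept tiles."""

    slide_id: str
    patch_refs: np.ndarray
    bag_size: int

    def __post_init__(self) -> None:
        refs = np.asarray(self.patch_refs, dtype=np.int64)
        if refs.shape != (self.bag_size,):
            raise ValueError("bag must contain exactly bag_size references")
        object.__setattr__(self, "patch_refs", refs)


@dataclass(frozen=True)
class ProxyLabelSet:
    """Per-patch two-class labels plus the gradient-activity mask."""

    labels: np.ndarray  # B x 2 in {0, 1}; columns (normal, coeliac)
    mask: np.ndarray  # B in {0, 1}; 0 = excluded from the loss


@dataclass
class SlidePatches:
    """Prepared features for every kept tile of one slide, training-ready."""

    slide_id: str
    label: str
    features: np.ndarray  # n_tiles x C x H x W, already model-prepared
    case_id: str = ""

    @property
    def n_tiles(self) -> int:
        return int(self.features.shape[0])


def sample_bag(kept_tiles: "np.ndarray | list", bag_size: int,
               rng: np.random.Generator, slide_id: str = "") -> Bag:
    """Uniform draws with replacement from a slide's kept tiles."""
    n = len(kept_tiles)
    if n == 0:
        raise ValueError("slide has no tissue tiles")
    refs = rng.integers(0, n, size=bag_size)
    return Bag(slide_id=slide_id, patch_refs=refs, bag_size=bag_size)


def assign_proxy_labels(predictions: np.ndarray, slide_label: str,
                        alpha: int, beta: int) -> ProxyLabelSet:
    """Top-k proxy labelling of a bag from its slide-level diagnosis.

    Normal slide: every patch labelled (1, 0), all active. Coeliac slide:
    patches ranked by normal-head probability ascending (ties broken by bag
    index); the ``alpha`` least-normal get (0, 1), the ``beta`` most-normal
    get (1, 0), everything else is masked.
    """
    preds = np.asarray(predictions, dtype=np.float64)
    b = preds.shape[0]
    if preds.ndim != 2 or preds.shape[1] != 2:
        raise ValueError("predictions must be B x 2")
    if alpha + beta > b:
        raise ValueError("alpha + beta must not exceed the bag size")
    labels = np.zeros((b, 2), dtype=np.int64)
    mask = np.zeros(b, dtype=np.int64)
    if slide_label == "normal":
        labels[:, 0] = 1
        mask[:] = 1
        return ProxyLabelSet(labels=labels, mask=mask)
    if slide_label != "coeliac":
        raise ValueError(f"unknown slide label {slide_label!r}")
    order = np.argsort(preds[:, 0], kind="stable")  # ascending normality
    least_normal = order[:alpha]
    labels[least_normal, 1] = 1
    mask[least_normal] = 1
    if beta > 0:
        most_normal = order[b - beta :]
        labels[most_normal, 0] = 1
        mask[most_normal] = 1
    return ProxyLabelSet(labels=labels, mask=mask)


def _bce_elements(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    # numerically stable binary cross-entropy with logits
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    return np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))


def masked_bce_loss(logits: np.ndarray, proxy: ProxyLabelSet) -> float:
    """Mean binary cross-entropy over the active (unmasked) label entries."""
    active = proxy.mask.astype(bool)
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("no active labels")
    elems = _bce_elements(logits[active], proxy.labels[active])
    return float(elems.mean())


def masked_bce_grad(logits: np.ndarray, proxy: ProxyLabelSet) -> np.ndarray:
    """d(loss)/d(logits); exactly zero for every masked entry."""
    active = proxy.mask.astype(bool)
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("no active labels")
    grad = np.zeros_like(np.asarray(logits, dtype=np.float64))
    z = logits[active]
    y = proxy.labels[active]
    grad[active] = (sigmoid(z) - y) / (2.0 * n_active)
    return grad


@dataclass
class TrainLog:
    """Per-step loss trace: one entry per slide visit."""

    epochs: list[int] = field(default_factory=list)
    slide_ids: list[str] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)

    def append(self, epoch: int, slide_id: str, loss: float) -> None:
        self.epochs.append(epoch)
        self.slide_ids.append(slide_id)
        self.losses.append(loss)

    def epoch_means(self) -> np.ndarray:
        ep = np.asarray(self.epochs)
        ls = np.asarray(self.losses)
        return np.array([ls[ep == e].mean() for e in np.unique(ep)])


def train(slides: list[SlidePatches], model: TinyConvNet,
          config: TrainConfig = TrainConfig()) -> TrainLog:
    """Run the MIL training loop; the model is updated in place.

    Per epoch: shuffle the slides, and for each slide sample one fresh bag,
    infer, proxy-label, and take one Adam step on the masked BCE loss.
    Deterministic for a fixed ``config.seed`` and model initialisation.
    """
    usable = [s for s in slides if s.n_tiles > 0]
    for s in slides:
        if s.n_tiles == 0:
            logger.warning("slide %s has no tissue tiles; skipped", s.slide_id)
    if not usable:
        raise ValueError("no slides with tissue tiles")
    present = {s.label for s in usable}
    if present != {"normal", "coeliac"}:
        raise ValueError(
            f"training data must contain both classes, found {sorted(present)}"
        )
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(model.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    log = TrainLog()
    for epoch in range(config.epochs):
        order = rng.permutation(len(usable))
        for i in order:
            slide = usable[i]
            bag = sample_bag(np.arange(slide.n_tiles), config.bag_size, rng,
                             slide_id=slide.slide_id)
            feats = slide.features[bag.patch_refs]
            logits = model.forward(feats)
            proxy = assign_proxy_labels(sigmoid(logits), slide.label,
                                        config.alpha, config.beta)
            loss = masked_bce_loss(logits, proxy)
            optimiser.zero_grad()
            model.backward(masked_bce_grad(logits, proxy))
            optimiser.step()
            log.append(epoch, slide.slide_id, loss)
    return log


def predict_slide(model: TinyConvNet, slide: SlidePatches,
                  batch_size: int = 256) -> np.ndarray:
    """Head probabilities for every kept tile of a slide (no sampling)."""
    if slide.n_tiles == 0:
        raise ValueError("slide has no tissue tiles")
    return model.predict_proba_features(slide.features, batch_size=batch_size)
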