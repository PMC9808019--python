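"""End-to-end orchestration: tile, normalise, train with CV, evaluate.

The driver mirrors the study design: slides are tiled with Otsu background
rejection, kept tiles are Macenko-normalised to the reference stain basis
and reduced to model features once, and a fresh classifier is trained per
cross-validation fold on the training cases only. Held-out predictions are
pooled for ROC analysis, thresholds are selected by the
sensitivity = specificity balance rule, and per-fold metrics are reported
per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation, mil, stain, tiling
from .manifest import ArrayRegionReader, RegionReader, SlideRecord, open_slide
from .nn import TinyConvNet

logger = logging.getLogger(__name__)


@dataclass
class PreparedSlide:
    """A tiled, stain-normalised, feature-extracted slide."""

    record: SlideRecord
    grid: tiling.TileGrid
    patches: mil.SlidePatches
    lesion_mask: np.ndarray | None = None  # ground truth when synthetic


def prepare_slide(reader: RegionReader, record: SlideRecord,
                  reference: stain.StainProfile = stain.REFERENCE_PROFILE,
                  lesion_mask: np.ndarray | None = None,
                  stain_granularity: str = "slide",
                  shared_profile: stain.StainProfile | None = None,
                  ) -> PreparedSlide:
    """Tile one slide and build normalised model features for kept tiles.

    Stain normalisation granularity:

    * ``shared_profile`` given (usually a per-source estimate pooled over
      all slides of one scanner) — the profile is applied to every tile
      with full normalisation including concentration rescaling; source
      pools contain both classes, so their robust maxima carry no label
      information.
    * ``stain_granularity="slide"`` — one profile estimated from this
      slide's pixels, applied to every tile with *basis correction only*:
      a slide's concentration maxima are shifted by disease itself, and
      rescaling by them would imprint the slide label onto every tile.
    * ``stain_granularity="patch"`` — independent per-tile estimation with
      rescaling (each tile is its own context).
    """
    if stain_granularity not in ("slide", "patch"):
        raise ValueError("stain_granularity must be 'slide' or 'patch'")
    grid = tiling.tile_slide(reader, slide_id=record.slide_id)
    kept = grid.kept_tiles
    profile = shared_profile
    rescale = shared_profile is not None
    if profile is None and stain_granularity == "slide" and kept:
        try:
            profile = stain.estimate_slide_profile(reader)
        except stain.StainEstimationError:
            logger.warning("slide %s has no estimable stain profile",
                           record.slide_id)
    feats = []
    for t in kept:
        patch = reader.read_region(t.x, t.y, t.size, t.size)
        try:
            patch = stain.normalize_patch(
                patch, reference, source_profile=profile,
                rescale_concentrations=rescale or profile is None)
        except stain.StainEstimationError:
            logger.warning("tile (%d, %d) of %s not normalisable; using raw",
                           t.x, t.y, record.slide_id)
        feats.append(TinyConvNet.prepare(patch)[0])
    features = (np.stack(feats) if feats
                else np.empty((0, 4, tiling.TILE_SIZE // TinyConvNet.BLOCK,
                               tiling.TILE_SIZE // TinyConvNet.BLOCK)))
    patches = mil.SlidePatches(slide_id=record.slide_id, label=record.label,
                               features=features, case_id=record.case_id)
    return PreparedSlide(record=record, grid=grid, patches=patches,
                         lesion_mask=lesion_mask)


def prepare_slides(slides, reference: stain.StainProfile = stain.REFERENCE_PROFILE,
                   stain_granularity: str = "source") -> list[PreparedSlide]:
    """Prepare a cohort: synthetic slides in memory, or manifest records.

    Accepts a list of :class:`~duomil.synth.SynthSlide` (images and lesion
    masks in memory) or of :class:`SlideRecord` (rasters read from
    ``image_uri``). With the default ``stain_granularity="source"`` one
    stain profile is estimated per source (scanner tag in the manifest)
    from pixels pooled over all of that source's slides — the most stable
    estimate of scanner colour drift, and label-balanced by construction;
    ``"slide"`` and ``"patch"`` fall back to per-slide / per-tile
    estimation.
    """
    def _reader(s):
        return (open_slide(s) if isinstance(s, SlideRecord)
                else ArrayRegionReader(s.image))

    def _record(s):
        return s if isinstance(s, SlideRecord) else s.record

    source_profiles: dict[str, stain.StainProfile | None] = {}
    if stain_granularity == "source":
        by_source: dict[str, list] = {}
        for s in slides:
            by_source.setdefault(_record(s).source, []).append(s)
        for source, members in by_source.items():
            samples = []
            per_slide = max(2000, 50000 // max(len(members), 1))
            for s in members:
                reader = _reader(s)
                w, h = reader.dims
                image = reader.read_region(0, 0, w, h)
                step = max(1, int(np.sqrt(w * h / per_slide)))
                samples.append(image[::step, ::step].reshape(-1, 3))
            pooled = np.concatenate(samples, axis=0)
            try:
                source_profiles[source] = stain.estimate_stain_profile(
                    pooled, max_pixels=100000)
            except stain.StainEstimationError:
                logger.warning("source %s has no estimable stain profile",
                               source)
                source_profiles[source] = None

    prepared = []
    for s in slides:
        record = _record(s)
        shared = source_profiles.get(record.source)
        prepared.append(prepare_slide(
            _reader(s), record, reference,
            lesion_mask=None if isinstance(s, SlideRecord) else s.lesion_mask,
            stain_granularity=("slide" if stain_granularity == "source"
                               else stain_granularity),
            shared_profile=shared,
        ))
    return prepared


@dataclass
class CrossValResult:
    """Held-out scores, thresholds, tile predictions and per-fold metrics."""

    table: pd.DataFrame  # slide_id, case_id, label, fold, means, n_tiles
    thresholds: evaluation.ThresholdPair
    tile_predictions: dict[str, np.ndarray]  # slide_id -> n_kept x 2
    fold_of_case: dict[str, int]
    roc: dict[str, float] = field(default_factory=dict)  # pooled AUC per class
    train_logs: list[mil.TrainLog] = field(default_factory=list)

    def class_scores(self, cls: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(scores, is-this-class labels, fold ids) for one head."""
        col = "mean_normal" if cls == "normal" else "mean_coeliac"
        return (self.table[col].to_numpy(),
                (self.table["label"] == cls).to_numpy(),
                self.table["fold"].to_numpy())

    def metrics_frame(self) -> pd.DataFrame:
        """Per-fold accuracy / ROC AUC / precision / recall per class."""
        rows = []
        for cls, thr in (("normal", self.thresholds.t_normal),
                         ("coeliac", self.thresholds.t_coeliac)):
            scores, labels, folds = self.class_scores(cls)
            for f in sorted(np.unique(folds)):
                sel = folds == f
                m = evaluation.compute_metrics(scores[sel] > thr, labels[sel])
                auc = evaluation.roc_and_pr(scores[sel], labels[sel]).roc_auc
                rows.append({"class": cls, "fold": int(f),
                             "accuracy": m.accuracy, "roc_auc": auc,
                             "precision": m.precision, "recall": m.recall})
            cls_rows = [r for r in rows if r["class"] == cls]
            rows.append({"class": cls, "fold": "mean",
                         **{k: float(np.mean([r[k] for r in cls_rows]))
                            for k in ("accuracy", "roc_auc", "precision", "recall")}})
        return pd.DataFrame(rows)

    def pooled_metrics(self, cls: str) -> evaluation.ClassMetrics:
        thr = (self.thresholds.t_normal if cls == "normal"
               else self.thresholds.t_coeliac)
        scores, labels, _ = self.class_scores(cls)
        return evaluation.compute_metrics(scores > thr, labels)


def run_cross_validation(prepared: list[PreparedSlide], k: int = 5,
                         config: mil.TrainConfig = mil.TrainConfig(),
                         seed: int = 0,
                         backbone_channels: tuple[int, int, int] = (8, 16, 32),
                         ) -> CrossValResult:
    """Case-grouped k-fold CV of the full MIL pipeline.

    Each fold trains a freshly initialised classifier on the other folds'
    slides and predicts every kept tile of its own held-out slides; the
    held-out slide scores are pooled across folds, thresholds are selected
    by the balance rule averaged over folds, and metrics are computed with
    those thresholds.
    """
    records = [p.record for p in prepared]
    fold_of_case = evaluation.make_folds(records, k=k,
                                         rng=np.random.default_rng(seed))
    rows = []
    tile_predictions: dict[str, np.ndarray] = {}
    logs = []
    for f in range(1, k + 1):
        train_set = [p.patches for p in prepared
                     if fold_of_case[p.record.case_id] != f]
        test_set = [p for p in prepared if fold_of_case[p.record.case_id] == f]
        if not test_set:
            continue
        model = TinyConvNet(seed=(seed * 1009 + f) % (2**31),
                            channels=backbone_channels)
        fold_config = replace(config, seed=(seed * 9176 + f) % (2**31))
        logs.append(mil.train(train_set, model, fold_config))
        for p in test_set:
            preds = mil.predict_slide(model, p.patches)
            tile_predictions[p.record.slide_id] = preds
            score = evaluation.slide_score(preds, slide_id=p.record.slide_id)
            rows.append({"slide_id": p.record.slide_id,
                         "case_id": p.record.case_id,
                         "label": p.record.label, "fold": f,
                         "mean_normal": score.mean_normal,
                         "mean_coeliac": score.mean_coeliac,
                         "n_tiles": score.n_tiles})
    table = pd.DataFrame(rows)

    thresholds = evaluation.ThresholdPair(
        t_normal=_clip_unit(evaluation.select_threshold(
            table["mean_normal"].to_numpy(),
            (table["label"] == "normal").to_numpy(),
            folds=table["fold"].to_numpy())),
        t_coeliac=_clip_unit(evaluation.select_threshold(
            table["mean_coeliac"].to_numpy(),
            (table["label"] == "coeliac").to_numpy(),
            folds=table["fold"].to_numpy())),
    )
    result = CrossValResult(table=table, thresholds=thresholds,
                            tile_predictions=tile_predictions,
                            fold_of_case=fold_of_case, train_logs=logs)
    for cls in ("normal", "coeliac"):
        scores, labels, _ = result.class_scores(cls)
        result.roc[cls] = evaluation.roc_and_pr(scores, labels).roc_auc
    return result


def _clip_unit(t: float, eps: float = 1e-9) -> float:
    # selected thresholds are score midpoints; keep them inside (0, 1)
    return float(min(max(t, eps), 1.0 - eps))


@dataclass
class LocalisationReport:
    """Do positive predictions concentrate on lesion tiles, slide by slide?"""

    fraction_localised: float
    per_slide: pd.DataFrame


def localisation_report(prepared: list[PreparedSlide],
                        tile_predictions: dict[str, np.ndarray],
                        lesion_tile_min_fraction: float = 0.5,
                        ) -> LocalisationReport:
    """Compare mean coeliac predictions on lesion vs non-lesion tiles.

    For every positive slide with predictions, kept tiles are split by
    ground-truth lesion overlap: "lesion" tiles have at least
    ``lesion_tile_min_fraction`` of their area inside the mask, "non-lesion"
    tiles have none. A slide counts as localised when the mean coeliac
    probability over lesion tiles strictly exceeds that over non-lesion
    tiles.
    """
    rows = []
    for p in prepared:
        if p.record.label != "coeliac" or p.lesion_mask is None:
            continue
        preds = tile_predictions.get(p.record.slide_id)
        if preds is None:
            continue
        kept = p.grid.kept_tiles
        fracs = np.array([
            p.lesion_mask[t.y : t.y + t.size, t.x : t.x + t.size].mean()
            for t in kept
        ])
        lesion_sel = fracs >= lesion_tile_min_fraction
        clean_sel = fracs == 0.0
        if not lesion_sel.any() or not clean_sel.any():
            continue
        mean_lesion = float(preds[lesion_sel, 1].mean())
        mean_clean = float(preds[clean_sel, 1].mean())
        rows.append({"slide_id": p.record.slide_id,
                     "mean_coeliac_lesion": mean_lesion,
                     "mean_coeliac_non_lesion": mean_clean,
                     "localised": mean_lesion > mean_clean})
    per_slide = pd.DataFrame(rows)
    frac = float(per_slide["localised"].mean()) if len(per_slide) else float("nan")
    return LocalisationReport(fraction_localised=frac, per_slide=per_slide)
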