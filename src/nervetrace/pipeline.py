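"""End-to-end orchestration: analysis, subject-wise CV, observer reports.

The full analysis of one image is flat-fielding, network inference,
hysteresis/skeletonization post-processing, then quantification — a pure
function of (inputs, configs, seed), bit-reproducible on CPU.

Cross-validation is subject-wise: folds partition *subjects*, never images,
so no individual contributes to both the training and the test side of any
fold. Held-out predictions from all folds are pooled into a single
predicted-vs-reference CNFL comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement as agr
from .core import IVCMImage, NerveAnalysis, SkeletonMap, TracingMap
from .metrics import analyze_skeleton, cnfl, tolerance_jaccard
from .model import ModelConfig, TrainConfig, TrainedModel, build_model, predict_probability, train
from .phantom import PhantomSample
from .postprocess import PostprocessConfig, postprocess
from .preprocess import PreprocessConfig, flatfield

__all__ = [
    "CVReport",
    "InterobserverReport",
    "analyze_image",
    "assign_subject_folds",
    "cross_validate",
    "train_final",
    "interobserver_report",
]


@dataclass
class CVReport:
    """Pooled result of a subject-wise k-fold cross-validation."""

    fold_assignments: dict[str, int]
    per_image: pd.DataFrame
    pooled_r2: float
    bland_altman: agr.BlandAltman

    @property
    def k(self) -> int:
        return len(set(self.fold_assignments.values()))


@dataclass
class InterobserverReport:
    """Agreement of the automated method with a panel of readers."""

    agreement: agr.AgreementReport
    reader_matrix: agr.ReaderMatrix
    jaccard: pd.DataFrame  # mean/sd tolerance-JI of auto vs each reader
    vs_average_reader: pd.DataFrame  # each observer vs mean-of-readers CNFL


def analyze_image(
    image: IVCMImage,
    model: TrainedModel,
    pre: PreprocessConfig | None = None,
    post: PostprocessConfig | None = None,
) -> NerveAnalysis:
    """Quantify one image: flatfield -> predict -> postprocess -> metrics."""
    flat = flatfield(image, pre or PreprocessConfig())
    prob = predict_probability(model, flat)
    skel = postprocess(prob, post or PostprocessConfig())
    return analyze_skeleton(skel, image_id=image.image_id, subject_id=image.subject_id)


def segment_image(
    image: IVCMImage,
    model: TrainedModel,
    pre: PreprocessConfig | None = None,
    post: PostprocessConfig | None = None,
) -> SkeletonMap:
    """The skeletonized tracing produced by the full pipeline for one image."""
    flat = flatfield(image, pre or PreprocessConfig())
    prob = predict_probability(model, flat)
    return postprocess(prob, post or PostprocessConfig())


def assign_subject_folds(
    subject_ids, k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Assign each subject to exactly one of ``k`` folds (sizes differ <= 1)."""
    subjects = sorted(set(subject_ids))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return {subjects[idx]: i % k for i, idx in enumerate(order)}


def _normalize_dataset(
    dataset,
) -> list[tuple[IVCMImage, TracingMap, float, str]]:
    """Accept PhantomSamples (reference = true CNFL) or (image, tracing) pairs
    (reference = manual tracing CNFL); both flow through the same report path."""
    out = []
    for entry in dataset:
        if isinstance(entry, PhantomSample):
            out.append((entry.image, entry.truth, entry.true_cnfl, entry.subject_id))
        else:
            image, tracing = entry
            out.append((image, tracing, cnfl(tracing), image.subject_id))
    return out


def cross_validate(
    dataset,
    k: int = 5,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    pre: PreprocessConfig | None = None,
    post: PostprocessConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Subject-wise k-fold cross-validation of the whole pipeline.

    For each fold, a fresh network is trained on the out-of-fold subjects
    (with the per-epoch 90/10 train/validation re-split inside ``train``)
    and applied to the in-fold images; held-out predictions are pooled and
    compared against the reference CNFL with R^2 and Bland-Altman.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    pre = pre or PreprocessConfig()
    post = post or PostprocessConfig()
    data = _normalize_dataset(dataset)
    folds = assign_subject_folds([s for *_, s in data], k=k, seed=seed)

    rows = []
    for fold in range(k):
        train_pairs = []
        test_items = []
        for image, tracing, ref, subject in data:
            if folds[subject] == fold:
                test_items.append((image, ref, subject))
            else:
                train_pairs.append((flatfield(image, pre), tracing))
        if not train_pairs:
            raise ValueError(f"fold {fold} has an empty training set")
        assert not {s for *_, s in test_items} & {
            img.subject_id for img, _ in train_pairs
        }, "subject leakage across folds"
        fold_train_cfg = TrainConfig(
            **{**train_cfg.__dict__, "seed": train_cfg.seed + fold}
        )
        net = build_model(model_cfg, seed=fold_train_cfg.seed)
        trained = train(net, train_pairs, fold_train_cfg)
        for image, ref, subject in test_items:
            analysis = analyze_image(image, trained, pre, post)
            rows.append(
                {
                    "image_id": image.image_id,
                    "subject_id": subject,
                    "fold": fold,
                    "reference_cnfl": ref,
                    "predicted_cnfl": analysis.cnfl_mm_per_mm2,
                }
            )
    per_image = pd.DataFrame(rows)
    pooled_r2 = agr.coefficient_of_determination(
        per_image["reference_cnfl"].to_numpy(), per_image["predicted_cnfl"].to_numpy()
    )
    ba = agr.bland_altman(
        per_image["predicted_cnfl"].to_numpy(), per_image["reference_cnfl"].to_numpy()
    )
    return CVReport(folds, per_image, pooled_r2, ba)


def train_final(
    dataset,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    pre: PreprocessConfig | None = None,
) -> TrainedModel:
    """Train one model on the full dataset and freeze it.

    This mirrors the protocol of applying a frozen model to sequestered data:
    after architecture selection by CV, retrain on all CV data before
    touching any held-back images.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    pre = pre or PreprocessConfig()
    data = _normalize_dataset(dataset)
    pairs = [(flatfield(image, pre), tracing) for image, tracing, *_ in data]
    net = build_model(model_cfg, seed=train_cfg.seed)
    return train(net, pairs, train_cfg)


def interobserver_report(
    readers: dict[str, dict[str, TracingMap]],
    auto: dict[str, SkeletonMap],
    tol_px: float = 3.0,
    auto_id: str = "auto",
) -> InterobserverReport:
    """Agreement statistics of the automated tracings against a reader panel.

    ``readers`` maps reader id -> image id -> tracing; ``auto`` maps
    image id -> automated skeleton. All observers must cover the same image
    set. Produces the full pairwise agreement report (readers plus the
    automated method as an extra observer), mean +/- SD tolerance-Jaccard of
    the automated tracing against each reader, and each observer's
    comparison to the average-reader CNFL (the per-image mean over readers).
    """
    image_ids = sorted(auto)
    gaps = {
        rid: sorted(set(image_ids) ^ set(maps))
        for rid, maps in readers.items()
        if set(maps) != set(image_ids)
    }
    if gaps:
        raise ValueError(f"image coverage mismatch per reader: {gaps}")

    reader_ids = sorted(readers)
    columns = [
        [cnfl(readers[rid][iid]) for iid in image_ids] for rid in reader_ids
    ]
    columns.append([cnfl(auto[iid]) for iid in image_ids])
    matrix = agr.ReaderMatrix(
        np.asarray(columns).T, reader_ids + [auto_id], image_ids
    )
    report = agr.build_agreement_report(matrix)

    ji_rows = {}
    for rid in reader_ids:
        scores = [
            tolerance_jaccard(auto[iid], readers[rid][iid], tol_px) for iid in image_ids
        ]
        ji_rows[rid] = {
            "ji_mean": float(np.mean(scores)),
            "ji_sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
        }
    jaccard = pd.DataFrame(ji_rows).T

    values = matrix.values
    avg_reader = values[:, : len(reader_ids)].mean(axis=1)
    vs_rows = {}
    for j, oid in enumerate(matrix.reader_ids):
        col = values[:, j]
        if len(reader_ids) == 1 and oid != auto_id:
            r2 = 1.0  # a single reader IS the average reader
        else:
            r2 = agr.coefficient_of_determination(col, avg_reader)
        ba = agr.bland_altman(col, avg_reader)
        vs_rows[oid] = {
            "r2_vs_average": r2,
            "mean_diff": ba.mean_diff,
            "rpc": ba.rpc,
        }
    vs_average = pd.DataFrame(vs_rows).T
    return InterobserverReport(report, matrix, jaccard, vs_average)
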