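"""High-level Model/Results interface over the full detection pipeline.

``EndoleakDetector`` holds the training and validation cases plus all stage
configuration; ``fit()`` estimates lesion/sac intensity statistics, trains the
segmentation network through the augmentor, picks the operating threshold on
the validation set, and returns an ``EndoleakDetectorResults`` carrying the
trained network, the fitted decision rule, training history and diagnostics.
Prediction, evaluation and a summary table hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .augment import IntensityStats
from .evaluate import MetricReport, bootstrap_sd, confusion, metrics, roc_auc
from .postprocess import (CaseDecision, PostprocessSpec, call_slices, decide_case,
                          select_threshold, slice_score)
from .preprocess import PreprocessSpec
from .segmentation import (AugmentorSettings, ModelConfig, TrainedModel,
                           build_model, predict_case, train)
from .types import POSITIVE, CaseRecord

DEFAULT_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.05), 2))


class EndoleakDetector:
    """End-to-end endoleak detection model over a labeled cohort.

    Parameters
    ----------
    train_cases, val_cases : disjoint lists of CaseRecord
    model_config : network architecture/optimisation settings
    augmentor : lesion + standard augmentation settings
    preprocess : normalisation settings (dataset mean fitted during fit())
    postprocess : decision-stage settings; the probability threshold inside is
        replaced by the validation-optimised one during fit()
    threshold_grid : candidate probability thresholds searched on validation
    """

    def __init__(self, train_cases: Sequence[CaseRecord],
                 val_cases: Sequence[CaseRecord],
                 model_config: Optional[ModelConfig] = None,
                 augmentor: Optional[AugmentorSettings] = None,
                 preprocess: Optional[PreprocessSpec] = None,
                 postprocess: Optional[PostprocessSpec] = None,
                 threshold_grid: Sequence[float] = DEFAULT_GRID):
        self.train_cases = list(train_cases)
        self.val_cases = list(val_cases)
        self.model_config = model_config or ModelConfig()
        self.augmentor = augmentor or AugmentorSettings()
        self.preprocess = preprocess
        self.postprocess = postprocess or PostprocessSpec()
        self.threshold_grid = list(threshold_grid)

    def fit(self) -> "EndoleakDetectorResults":
        net = build_model(self.model_config)
        trained = train(net, self.train_cases, self.val_cases,
                        augmentor=self.augmentor, config=self.model_config,
                        preprocess_spec=self.preprocess)
        val_maps, val_truth = [], []
        for case in self.val_cases:
            maps = predict_case(trained, case)
            val_maps.extend(maps)
            val_truth.extend(
                ms.endoleak if ms.endoleak is not None
                else np.zeros(sl.shape, dtype=np.uint8)
                for sl, ms in zip(case.slices, case.masks))
        thr, diag = select_threshold(val_maps, val_truth, self.threshold_grid)
        post = replace(self.postprocess, prob_threshold=thr)
        return EndoleakDetectorResults(model=self, trained=trained,
                                       postprocess=post, threshold_diag=diag)


@dataclass
class EndoleakDetectorResults:
    """Fitted pipeline: trained network + validation-tuned decision rule."""

    model: EndoleakDetector
    trained: TrainedModel
    postprocess: PostprocessSpec
    threshold_diag: dict

    @property
    def intensity_stats(self) -> Optional[IntensityStats]:
        return self.trained.stats

    @property
    def history(self) -> dict:
        return self.trained.history

    def predict_case(self, case: CaseRecord):
        return predict_case(self.trained, case)

    def decide_case(self, case: CaseRecord) -> CaseDecision:
        calls = call_slices(self.predict_case(case), self.postprocess)
        return decide_case(calls, self.postprocess)

    def evaluate(self, test_cases: Sequence[CaseRecord],
                 n_boot: int = 1000, seed: int = 0) -> dict:
        """Slice-level AUC and case-level confusion metrics on held-out cases.

        Returns a dict with 'slice_auc', 'case_metrics' (MetricReport),
        'case_decisions', and 'case_correct' flags.
        """
        slice_scores, slice_truth = [], []
        decisions, case_truth = [], []
        for case in test_cases:
            maps = self.predict_case(case)
            for pm, ms in zip(maps, case.masks):
                slice_scores.append(slice_score(pm, self.postprocess))
                slice_truth.append(ms.has_endoleak)
            decisions.append(decide_case(call_slices(maps, self.postprocess),
                                         self.postprocess))
            case_truth.append(case.label == POSITIVE)
        pred_flags = [d.positive for d in decisions]
        counts = confusion(pred_flags, case_truth)
        report = metrics(counts)
        correct = [p == t for p, t in zip(pred_flags, case_truth)]
        report.bootstrap_sd = bootstrap_sd(correct, n_boot=n_boot, seed=seed)
        if any(slice_truth) and not all(slice_truth):
            report.auc = None  # case-level AUC not defined for hard decisions
            auc = roc_auc(slice_scores, slice_truth)
        else:
            auc = None
        return {"slice_auc": auc, "case_metrics": report,
                "case_decisions": decisions, "case_correct": correct,
                "confusion": counts}

    def summary(self, evaluation: Optional[dict] = None) -> str:
        """Plain-text summary table in the spirit of a model-results printout."""
        cfg = self.trained.config
        lines = [
            "Endoleak Detection Results",
            "=" * 58,
            f"Encoder-decoder depth {cfg.depth}, base channels "
            f"{cfg.base_channels}, input {cfg.input_size}x{cfg.input_size}",
            f"Epochs trained: {len(self.history['train_loss'])}   "
            f"best val F1: {max(self.history['val_f1']):.3f}",
            f"Operating threshold (val-optimised): "
            f"{self.postprocess.prob_threshold:.2f} "
            f"(val slice F1 {self.threshold_diag['f1']:.3f})",
            f"Size filter: [{self.postprocess.min_area_px}, "
            f"{self.postprocess.max_area_px}] px; case rule: "
            f"{self.postprocess.case_rule} k={self.postprocess.case_k}",
        ]
        if self.intensity_stats is not None:
            s = self.intensity_stats
            lines.append(
                f"Intensity model: leak {s.u_e:.1f}±{s.sigma_e:.1f} HU "
                f"(n={s.n_e}), sac {s.u_a:.1f}±{s.sigma_a:.1f} HU (n={s.n_a})")
        if evaluation is not None:
            rep: MetricReport = evaluation["case_metrics"]
            lines += [
                "-" * 58,
                f"Per-slice AUC:   {evaluation['slice_auc']:.3f}"
                if evaluation["slice_auc"] is not None else "Per-slice AUC:   n/a",
                f"Per-case accuracy {rep.accuracy:.1f}%  precision "
                f"{rep.precision:.1f}%  recall {rep.recall:.1f}%",
                f"Bootstrap SD of accuracy: {rep.bootstrap_sd:.1f} points",
            ]
        return "\n".join(lines)
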