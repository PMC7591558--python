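"""Canned phantom-cohort experiments exercising the whole pipeline.

The standard experiment mirrors the study design the package is built around:
a cohort of 50 endoleak-positive and 20 control cases, split 32+8 / 8+2 /
10+10 (train/validation/test, positives+controls), a depth-3 encoder–decoder
trained through the lesion augmentor, threshold selection on validation, and
slice-level AUC plus case-level metrics on the held-out test cases.

Problem sizes are desk-scale: 64×64 slices, 6 slices per case, base 8
channels, 10 epochs at learning rate 3e-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import EndoleakDetector
from .phantom import PhantomConfig, generate_cohort
from .segmentation import AugmentorSettings, ModelConfig
from .types import select_cases, split_cohort

SPLIT_COUNTS = (32, 8, 8, 2, 10, 10)  # train/val/test, positives+controls
COHORT_COUNTS = (50, 20)


@dataclass
class ExperimentResult:
    seed: int
    augmentor_enabled: bool
    slice_auc: float
    case_accuracy: float
    case_precision: float
    case_recall: float
    bootstrap_sd: float
    threshold: float
    history: dict


def run_phantom_experiment(seed: int, augmentor_enabled: bool = True,
                           phantom: Optional[PhantomConfig] = None,
                           model_config: Optional[ModelConfig] = None,
                           n_boot: int = 1000) -> ExperimentResult:
    """Generate a phantom cohort, train, and evaluate; all seeded by ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_split, s_model, s_boot = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(4))
    phantom = phantom or PhantomConfig()
    phantom.seed = s_cohort
    cohort = generate_cohort(phantom, *COHORT_COUNTS)
    split = split_cohort(cohort, *SPLIT_COUNTS, seed=s_split)
    tr = select_cases(cohort, split.train)
    va = select_cases(cohort, split.validation)
    te = select_cases(cohort, split.test)
    model_config = model_config or ModelConfig(
        seed=s_model, epochs=10, learning_rate=3e-3)
    detector = EndoleakDetector(
        tr, va, model_config=model_config,
        augmentor=AugmentorSettings(enabled=augmentor_enabled))
    results = detector.fit()
    ev = results.evaluate(te, n_boot=n_boot, seed=s_boot)
    rep = ev["case_metrics"]
    return ExperimentResult(
        seed=seed, augmentor_enabled=augmentor_enabled,
        slice_auc=ev["slice_auc"], case_accuracy=rep.accuracy,
        case_precision=rep.precision, case_recall=rep.recall,
        bootstrap_sd=rep.bootstrap_sd,
        threshold=results.postprocess.prob_threshold,
        history=results.history)
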