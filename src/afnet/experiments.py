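"""Desk-scale reference experiments.

The full detector was designed against multi-thousand-record challenge
datasets; these experiments rerun the same pipeline at a size a single
CPU handles in minutes: 400 synthetic records with the 1:5 AF:non-AF
imbalance, a reduced backbone (2 dense blocks of 4 layers), and a
20-epoch schedule.  They are the package's own evidence that every stage
— generation, denoising, the network, the optimizer, the metrics —
composes into a working detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import best_threshold_accuracy
from .metrics import MetricsReport, evaluate_predictions
from .nn import AFNet, DenseNetConfig, RecurrentConfig
from .preprocess import denoise, segment_and_normalize
from .synth import ECGSynthConfig, generate_dataset
from .training import TrainConfig, TrainHistory, cross_entropy, train

__all__ = ["ScaledStudyResult", "run_scaled_study", "REDUCED_BACKBONE"]

REDUCED_BACKBONE = DenseNetConfig(num_blocks=2, layers_per_block=4)


@dataclass
class ScaledStudyResult:
    history: TrainHistory
    val_accuracy: float
    test_report: MetricsReport
    baseline_accuracy: float
    n_records: int
    model: AFNet


def run_scaled_study(
    seed: int = 0,
    n_records: int = 400,
    epochs: int = 20,
    verbose: bool = False,
) -> ScaledStudyResult:
    """Generate -> denoise -> segment -> train (reduced model) -> score.

    Also fits the RR-irregularity threshold baseline on the same records
    as a learnability floor.
    """
    synth = ECGSynthConfig(seed=seed)
    records = generate_dataset(n_records, synth)
    segments = [segment_and_normalize(denoise(r)) for r in records]

    baseline_acc, _ = best_threshold_accuracy(records)

    model = AFNet(REDUCED_BACKBONE, RecurrentConfig(), seed=seed)
    train_cfg = TrainConfig(epochs=epochs, seed=seed)
    model, history, split = train(model, segments, train_cfg, verbose=verbose)

    x_te = np.stack([segments[i].values for i in split.test]).astype(np.float32)
    y_te = np.array([segments[i].label.binary_label for i in split.test])
    model.eval()
    probs = model.predict_proba(x_te)
    report = evaluate_predictions(y_te, (probs >= 0.5).astype(int),
                                  loss=cross_entropy(y_te.astype(float), probs))
    return ScaledStudyResult(
        history=history,
        val_accuracy=history.val_acc[-1],
        test_report=report,
        baseline_accuracy=baseline_acc,
        n_records=n_records,
        model=model,
    )
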