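"""Per-frame keyframe evaluation and the multi-method comparison harness.

Predictions and ground truth are compared frame-wise: with tolerance 0
this is the confusion matrix of two binary vectors; with tolerance k a
predicted frame counts as a true positive if it can be matched
one-to-one to a true keyframe within ±k frames (greedy, nearest pairs
first).  Precision and recall with a zero denominator are reported as
NaN, never silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cdkd.errors import ConfigurationError, ValidationError
from cdkd.keyframe_detection import DetectorParams, detect
from cdkd.sequence_io import FrameSequence, KeyframeResult, LabelVector

__all__ = ["EvalReport", "evaluate", "compare_methods", "ComparisonTable"]


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived rates for one method."""

    tp: int
    fp: int
    fn: int
    tn: int
    tolerance: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else math.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "tolerance": self.tolerance,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
        }


def _predicted_indices(predicted) -> list[int]:
    if isinstance(predicted, KeyframeResult):
        return list(predicted.keyframes)
    return sorted(int(i) for i in predicted)


def evaluate(predicted, truth: LabelVector, tolerance: int = 0) -> EvalReport:
    """Score predicted keyframes against per-frame binary labels.

    Parameters
    ----------
    predicted : KeyframeResult or iterable of int
        Predicted keyframe indices.
    truth : LabelVector
        Ground-truth per-frame labels.
    tolerance : int
        Matching tolerance in frames.  0 = strict per-frame confusion;
        k > 0 matches predictions to truths one-to-one within ±k,
        nearest pairs first (ties to the earlier truth frame).
    """
    n = len(truth)
    if tolerance < 0:
        raise ConfigurationError("tolerance must be non-negative")
    if tolerance >= n:
        raise ConfigurationError(f"tolerance {tolerance} >= sequence length {n}")
    pred = _predicted_indices(predicted)
    if any(i < 0 or i >= n for i in pred):
        raise ValidationError("predicted index out of range")
    true_frames = truth.keyframe_indices

    if tolerance == 0:
        pred_set = set(pred)
        true_set = set(true_frames)
        tp = len(pred_set & true_set)
        fp = len(pred_set - true_set)
        fn = len(true_set - pred_set)
        tn = n - tp - fp - fn
        return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, tolerance=0)

    # greedy one-to-one matching, nearest pairs first
    pairs = sorted(
        (
            (abs(p - t), t, p)
            for p in pred
            for t in true_frames
            if abs(p - t) <= tolerance
        )
    )
    matched_pred: set[int] = set()
    matched_true: set[int] = set()
    for _, t, p in pairs:
        if p in matched_pred or t in matched_true:
            continue
        matched_pred.add(p)
        matched_true.add(t)
    tp = len(matched_pred)
    fp = len(pred) - tp
    fn = len(true_frames) - len(matched_true)
    tn = max(n - tp - fp - fn, 0)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, tolerance=tolerance)


class ComparisonTable(dict):
    """Mapping of method name → EvalReport, with a tabular export."""

    def to_dataframe(self):
        import pandas as pd

        rows = {name: rep.as_dict() for name, rep in self.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "method"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def compare_methods(
    seq: FrameSequence,
    truth: LabelVector,
    methods: dict[str, DetectorParams] | list[DetectorParams],
    tolerance: int = 0,
) -> ComparisonTable:
    """Run several detector configurations on one sequence and score each.

    ``methods`` is either a mapping of display name → params, or a list
    of params (named by their metric/backend).
    """
    if not methods:
        raise ConfigurationError("need at least one method")
    if not isinstance(methods, dict):
        named: dict[str, DetectorParams] = {}
        for p in methods:
            base = p.metric.name if p.metric.domain == "pixel" else f"{p.metric.name}+{p.backend.name}"
            name = base
            k = 2
            while name in named:
                name = f"{base}#{k}"
                k += 1
            named[name] = p
        methods = named
    if len(truth) != len(seq):
        raise ValidationError(f"{len(truth)} labels for a {len(seq)}-frame sequence")
    table = ComparisonTable()
    for name, params in methods.items():
        result = detect(seq, params)
        table[name] = evaluate(result, truth, tolerance)
    return table
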