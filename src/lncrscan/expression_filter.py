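"""ROC-based FPKM quality filtering of assembled transcripts.

Complete assemblies ('=' class code) tend to carry much higher FPKM than
partial ones ('c').  Treating "complete" as the positive label and FPKM as
the score, an ROC curve over candidate thresholds yields an optimum cutoff
t* — the threshold whose (sensitivity, specificity) point lies closest to
the perfect corner (1, 1):

    i* = argmin_i (1 - sensitivities[i])^2 + (1 - specificities[i])^2
    t* = T[i*]

Novel assemblies with FPKM below t* are discarded as likely partial or
artifactual; complete ('=') assemblies are kept without an expression
requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation_compare import ClassificationResult
from .transcript_model import TranscriptModel


@dataclass(frozen=True)
class RocCurve:
    """Candidate thresholds with their sensitivities and specificities.

    Thresholds ascend; the classification rule is strict (predict positive
    when value > threshold), so sensitivity is non-increasing and
    specificity non-decreasing along the curve.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        if len(self.sensitivities) != n or len(self.specificities) != n:
            raise ValueError("threshold/sensitivity/specificity lengths differ")
        if np.any(np.diff(self.sensitivities) > 1e-12):
            raise ValueError("sensitivities must be non-increasing in threshold")
        if np.any(np.diff(self.specificities) < -1e-12):
            raise ValueError("specificities must be non-decreasing in threshold")


@dataclass(frozen=True)
class ThresholdResult:
    optimum_index: int
    optimum_threshold: float
    auc: float


def build_roc(
    positive_values: Sequence[float], negative_values: Sequence[float]
) -> RocCurve:
    """ROC curve of the score "FPKM" separating positives from negatives.

    Candidate thresholds are -inf, the midpoints between consecutive
    distinct pooled values, and +inf.  At threshold t: sensitivity is the
    fraction of positives strictly above t; specificity the fraction of
    negatives at or below t.
    """
    pos = np.sort(np.asarray(positive_values, dtype=float))
    neg = np.sort(np.asarray(negative_values, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("build_roc requires non-empty positive and negative samples")
    pooled = np.unique(np.concatenate([pos, neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # fraction of positives > t  /  fraction of negatives <= t
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size
    return RocCurve(thresholds=thresholds, sensitivities=sens, specificities=spec)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under sensitivity vs (1 - specificity).

    Equals the Mann-Whitney probability P(X_pos > X_neg) + 0.5 P(X_pos =
    X_neg) on the samples the curve was built from.
    """
    x = 1.0 - roc.specificities
    y = roc.sensitivities
    # thresholds ascend => x descends; integrate left-to-right
    return float(np.trapezoid(y[::-1], x[::-1]))


def optimal_threshold(roc: RocCurve) -> ThresholdResult:
    """Closest-to-corner optimum: minimise (1-sens)^2 + (1-spec)^2.

    Ties resolve to the smallest index (lowest threshold), the choice that
    retains the most transcripts.
    """
    objective = (1.0 - roc.sensitivities) ** 2 + (1.0 - roc.specificities) ** 2
    i_star = int(np.argmin(objective))
    return ThresholdResult(
        optimum_index=i_star,
        optimum_threshold=float(roc.thresholds[i_star]),
        auc=auc(roc),
    )


def filter_by_fpkm(
    transcripts: Iterable[TranscriptModel], cutoff: float
) -> list[TranscriptModel]:
    """Keep transcripts with FPKM >= cutoff (inclusive)."""
    retained = []
    for t in transcripts:
        if t.fpkm is None:
            raise ValueError(f"transcript {t.transcript_id} has no FPKM value")
        if t.fpkm >= cutoff:
            retained.append(t)
    return retained


def select_high_quality(
    classified: Iterable[tuple[TranscriptModel, ClassificationResult]],
    cutoff: float,
) -> list[tuple[TranscriptModel, ClassificationResult]]:
    """High-quality assemblies: all '=' transcripts, plus novel transcripts
    (code outside {=, c}) meeting the expression criterion FPKM >= cutoff.

    Partial ('c') assemblies are always excluded; complete ('=') ones are
    kept with no expression requirement.
    """
    kept = []
    for t, res in classified:
        if res.code == "=":
            kept.append((t, res))
        elif res.code == "c":
            continue
        else:
            if t.fpkm is None:
                raise ValueError(f"transcript {t.transcript_id} has no FPKM value")
            if t.fpkm >= cutoff:
                kept.append((t, res))
    return kept
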