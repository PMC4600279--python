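"""Agreement between methylation-based labels and an external reference.

The reference labelling (e.g. clonality calls from copy-number profiling)
is treated as the actual tumour origin; reference RECURRENT is the
positive condition. The 2x2 table then yields sensitivity, specificity,
and the positive/negative predictive values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .model import ClonalityLabel, InputValidationError


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement counts with reference RECURRENT as the positive condition."""

    tp: int  # reference recurrent, predicted recurrent
    fn: int  # reference recurrent, predicted de novo
    fp: int  # reference de novo, predicted recurrent
    tn: int  # reference de novo, predicted de novo

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InputValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class PredictiveValues:
    """The four diagnostic summaries; None where the denominator is zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def build_confusion(
    predicted: Mapping[str, ClonalityLabel],
    reference: Mapping[str, ClonalityLabel],
) -> ConfusionTable:
    """Count agreement over the patient ids present in both maps."""
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise InputValidationError(
            "no shared patient ids between predicted and reference labels"
        )
    tp = fn = fp = tn = 0
    for pid in shared:
        ref_pos = reference[pid] is ClonalityLabel.RECURRENT
        pred_pos = predicted[pid] is ClonalityLabel.RECURRENT
        if ref_pos and pred_pos:
            tp += 1
        elif ref_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def predictive_values(table: ConfusionTable) -> PredictiveValues:
    """Sensitivity, specificity, PPV and NPV of a confusion table.

    A value whose denominator is zero (e.g. sensitivity with no reference
    positives) is reported as None rather than 0, so tiny cohorts do not
    produce silently misleading summaries.
    """
    if table.total < 1:
        raise InputValidationError("confusion table is empty")
    return PredictiveValues(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
    )
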