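"""Empirical null distribution of LRs and counting p-values.

Tumours from different patients are non-recurrent by construction, so
pairing every tumour with every tumour of every *other* patient yields a
null population of LRs. With n patients contributing 2 tumours each this
gives 2n * 2(n-1) ordered pairings (ordered, because the LR is asymmetric
in which tumour plays the primary role); a 29-patient cohort yields
2 * 29 * 2 * 28 = 3248.

The p-value of an observed LR is the fraction of null LRs strictly larger
than it; values tied with the observed LR are not counted. Recurrence is
called at p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .likelihood import (
    LRResult,
    cross_lr_matrix,
    encode_calls,
    log_ratio_table,
)
from .model import (
    ClonalityLabel,
    ClonalityParams,
    GenePanel,
    InputValidationError,
    TumourPair,
    TumourProfile,
)

logger = logging.getLogger("methclonal")


@dataclass
class NullDistribution:
    """Multiset of cross-patient LRs used as the non-recurrence reference."""

    values: np.ndarray
    n_individuals: int
    n_comparisons: int
    n_degenerate_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InputValidationError("null distribution contains non-finite LRs")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def enumerate_cross_pairs(
    cohort: Sequence[TumourPair],
) -> list[tuple[TumourProfile, TumourProfile]]:
    """Every ordered (tumour-as-primary, tumour-as-second) cross-patient pairing.

    Same-patient pairings are excluded; both orientations of each
    cross-patient pairing are kept.
    """
    if len(cohort) < 2:
        raise InputValidationError(
            "need at least 2 individuals to build cross-patient pairings"
        )
    tumours = [(pair.patient_id, t) for pair in cohort for t in (pair.primary, pair.second)]
    return [
        (ta, tb)
        for pa, ta in tumours
        for pb, tb in tumours
        if pa != pb
    ]


def build_null_distribution(
    cohort: Sequence[TumourPair],
    panel: GenePanel,
    params: ClonalityParams,
    *,
    exclude_patient: Optional[str] = None,
) -> NullDistribution:
    """LR of every ordered cross-patient pairing, as a null distribution.

    Pairings where no gene is informative in both tumours are dropped (and
    counted). ``exclude_patient`` removes one patient's tumours entirely,
    for a leave-one-individual-out null; by default the tested patient's
    tumours participate in pairings with other patients, matching the
    pooled-null construction.
    """
    used = [p for p in cohort if p.patient_id != exclude_patient]
    if len(used) < 2:
        raise InputValidationError(
            "need at least 2 individuals to build cross-patient pairings"
        )
    owners: list[str] = []
    calls = []
    for pair in used:
        for t in (pair.primary, pair.second):
            t.validate_against(panel)
            owners.append(pair.patient_id)
            calls.append(t.calls)
    codes = encode_calls(calls, panel)
    table = log_ratio_table(panel, params)
    lr, ninf = cross_lr_matrix(codes, table)
    owner_arr = np.array(owners)
    cross = owner_arr[:, None] != owner_arr[None, :]
    n_comparisons = int(cross.sum())
    keep = cross & (ninf > 0)
    dropped = n_comparisons - int(keep.sum())
    if dropped:
        logger.warning("dropped %d degenerate cross-pairings from the null", dropped)
    values = lr[keep]
    if values.size == 0:
        raise InputValidationError("all cross-pairings are degenerate; null is empty")
    return NullDistribution(
        values=values,
        n_individuals=len(used),
        n_comparisons=n_comparisons,
        n_degenerate_dropped=dropped,
    )


def empirical_p_value(
    lr: float, null: NullDistribution, *, smoothing: bool = False
) -> float:
    """Fraction of null LRs strictly greater than the observed LR.

    With ``smoothing`` a +1 pseudocount is applied to numerator and
    denominator so p = 0 is unreachable; the default is the raw count, as
    in the original construction.
    """
    n = len(null)
    if n == 0:
        raise InputValidationError("empty null distribution")
    count = int((null.values > lr).sum())
    if smoothing:
        return (count + 1) / (n + 1)
    return count / n


def classify_empirical(
    result: LRResult,
    null: NullDistribution,
    params: ClonalityParams,
    *,
    smoothing: bool = False,
) -> LRResult:
    """Fill the counting p-value and the alpha-level label (in place).

    RECURRENT iff p < alpha (strict); degenerate results stay unlabelled.
    """
    if result.degenerate:
        logger.warning(
            "pair %r is degenerate; empirical label left unset", result.patient_id
        )
        return result
    result.empirical_p = empirical_p_value(result.LR, null, smoothing=smoothing)
    result.empirical_label = (
        ClonalityLabel.RECURRENT
        if result.empirical_p < params.alpha
        else ClonalityLabel.DE_NOVO
    )
    return result
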