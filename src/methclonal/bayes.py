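"""Bayesian posterior log-odds classification.

The posterior log-odds of recurrence add the log prior odds to the data
log-odds ratio:

  PLR = ln( Pr(R) / (1 - Pr(R)) ) + LR

PLR > 0 calls the second tumour a recurrence, PLR < 0 a new primary.
Equivalently, LR is compared against the threshold -ln(prior odds): with
the default priors this is -1.099 for ipsilateral pairs (prior 0.75) and
1.774 for contralateral pairs (prior 0.145).
"""

from __future__ import annotations

import logging
import math

from .likelihood import LRResult
from .model import ClonalityLabel, ClonalityParams, ParameterError

logger = logging.getLogger("methclonal")


def _check_prior(prior: float) -> None:
    if not (0.0 < prior < 1.0):
        raise ParameterError(
            f"prior probability must be strictly inside (0, 1), got {prior}"
        )


def posterior_log_ratio(lr: float, prior: float) -> float:
    """ln(prior odds of recurrence) + LR."""
    _check_prior(prior)
    return math.log(prior / (1.0 - prior)) + lr


def lr_decision_threshold(prior: float) -> float:
    """The LR value above which PLR > 0, i.e. -ln(prior/(1-prior))."""
    _check_prior(prior)
    return -math.log(prior / (1.0 - prior))


def classify_bayesian(result: LRResult, params: ClonalityParams) -> LRResult:
    """Fill PLR and the Bayesian label on a pair result (in place).

    Degenerate results (no informative gene) are left unlabelled. A PLR of
    exactly 0 is classified DE_NOVO — the conservative clinical call — with
    a logged warning.
    """
    if result.degenerate:
        logger.warning(
            "pair %r is degenerate; Bayesian label left unset", result.patient_id
        )
        return result
    prior = params.prior_recurrence[result.laterality]
    result.PLR = posterior_log_ratio(result.LR, prior)
    if result.PLR > 0:
        result.bayesian_label = ClonalityLabel.RECURRENT
    else:
        if result.PLR == 0:
            logger.warning(
                "pair %r has PLR exactly 0; tie classified as de novo",
                result.patient_id,
            )
        result.bayesian_label = ClonalityLabel.DE_NOVO
    return result
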