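"""Per-gene joint methylation probabilities and the summed log-odds ratio.

For each panel gene the joint call of (primary, second) has an explicit
probability under each hypothesis. Writing M for methylated, U for
unmethylated and p for the gene's background methylation probability:

Under non-recurrence (independent tumours)::

              U (second)     M (second)
  U (primary) (1-p)^2        p(1-p)
  M (primary) p(1-p)         p^2

Under recurrence, with loss probability gamma and gain probability
g*gamma (g = gain_multiplier, default 2)::

              U (second)         M (second)
  U (primary) (1-g*gamma)(1-p)   g*gamma*(1-p)
  M (primary) gamma*p            (1-gamma)*p

The pair statistic is the natural-log likelihood ratio summed over the
informative genes:

  LR = sum_i ln Pr(x_i | R) / Pr(x_i | R-bar)

Genes where either tumour is uninformative are skipped (they contribute 0,
i.e. the likelihood is that of the observed data only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    ClonalityLabel,
    ClonalityParams,
    GenePanel,
    Laterality,
    MethylationStatus,
    ParameterError,
    TumourPair,
)

logger = logging.getLogger("methclonal")

_M = MethylationStatus.METHYLATED
_U = MethylationStatus.UNMETHYLATED
_NA = MethylationStatus.UNINFORMATIVE


@dataclass
class GeneContribution:
    """One gene's summand in the pair log-odds ratio."""

    gene: str
    primary_status: MethylationStatus
    second_status: MethylationStatus
    p_used: float
    log_ratio: float
    skipped: bool


@dataclass
class LRResult:
    """Per-pair statistic with classification fields filled in later stages."""

    patient_id: str
    laterality: Laterality
    contributions: list[GeneContribution]
    n_informative: int
    LR: float
    PLR: Optional[float] = None
    bayesian_label: Optional[ClonalityLabel] = None
    empirical_p: Optional[float] = None
    empirical_label: Optional[ClonalityLabel] = None

    @property
    def degenerate(self) -> bool:
        """True when no gene was informative; LR is 0 by convention."""
        return self.n_informative == 0


def _check_measured(primary: MethylationStatus, second: MethylationStatus) -> None:
    if primary is _NA or second is _NA:
        raise ParameterError(
            "joint probabilities are defined only for measured statuses; "
            "callers must skip uninformative genes"
        )


def joint_prob_nonrecurrence(
    primary: MethylationStatus, second: MethylationStatus, p: float
) -> float:
    """Probability of the joint call when the tumours are independent."""
    _check_measured(primary, second)
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p must be in [0, 1], got {p}")
    if primary is _U:
        return (1.0 - p) ** 2 if second is _U else p * (1.0 - p)
    return p * (1.0 - p) if second is _U else p * p


def joint_prob_recurrence(
    primary: MethylationStatus,
    second: MethylationStatus,
    p: float,
    gamma: float,
    gain_multiplier: float = 2.0,
) -> float:
    """Probability of the joint call when the second tumour is clonal."""
    _check_measured(primary, second)
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p must be in [0, 1], got {p}")
    gain = gain_multiplier * gamma
    if gamma < 0 or gain > 1.0:
        raise ParameterError(
            f"invalid loss/gain probabilities: gamma={gamma}, gain={gain}"
        )
    if primary is _U:
        return (1.0 - gain) * (1.0 - p) if second is _U else gain * (1.0 - p)
    return gamma * p if second is _U else (1.0 - gamma) * p


def gene_log_ratio(
    gene: str,
    primary: MethylationStatus,
    second: MethylationStatus,
    p: float,
    params: ClonalityParams,
) -> GeneContribution:
    """One gene's ln Pr(x|R)/Pr(x|R-bar), or a skipped zero contribution.

    ``p`` must already be clamped to [epsilon, 1-epsilon] so both joint
    probabilities are strictly positive and the log is finite.
    """
    if primary is _NA or second is _NA:
        return GeneContribution(gene, primary, second, p, 0.0, skipped=True)
    num = joint_prob_recurrence(primary, second, p, params.gamma, params.gain_multiplier)
    den = joint_prob_nonrecurrence(primary, second, p)
    return GeneContribution(gene, primary, second, p, math.log(num / den), skipped=False)


def pair_log_ratio(
    pair: TumourPair, panel: GenePanel, params: ClonalityParams
) -> LRResult:
    """Summed log-odds ratio for one tumour pair over the panel.

    A pair with no informative gene is degenerate: LR is reported as 0 and
    all classification fields stay unset (downstream classifiers refuse it).
    """
    pair.primary.validate_against(panel)
    pair.second.validate_against(panel)
    p_eff = panel.effective_p(params.epsilon)
    contributions = [
        gene_log_ratio(
            g, pair.primary.calls[g], pair.second.calls[g], p_eff[g], params
        )
        for g in panel.genes
    ]
    n_inf = sum(not c.skipped for c in contributions)
    lr = sum(c.log_ratio for c in contributions if not c.skipped)
    if n_inf == 0:
        logger.warning(
            "pair %r has no informative gene; result is degenerate", pair.patient_id
        )
    return LRResult(
        patient_id=pair.patient_id,
        laterality=pair.laterality,
        contributions=contributions,
        n_informative=n_inf,
        LR=lr,
    )


# ---------------------------------------------------------------------------
# Vectorized path used for the large cross-pairing null. Calls are encoded as
# integer codes: 0 = unmethylated, 1 = methylated, 2 = uninformative.

CODE_OF_STATUS = {_U: 0, _M: 1, _NA: 2}
STATUS_OF_CODE = {v: k for k, v in CODE_OF_STATUS.items()}


def encode_calls(profiles: Sequence[dict[str, MethylationStatus]], panel: GenePanel) -> np.ndarray:
    """Stack per-sample call maps into an (n_samples, n_genes) int8 code matrix."""
    out = np.empty((len(profiles), len(panel)), dtype=np.int8)
    for i, calls in enumerate(profiles):
        for j, g in enumerate(panel.genes):
            out[i, j] = CODE_OF_STATUS[calls[g]]
    return out


def log_ratio_table(panel: GenePanel, params: ClonalityParams) -> np.ndarray:
    """Per-gene 2x2 log-ratio lookup, shape (n_genes, 2, 2).

    ``table[g, a, b]`` is the log ratio for primary code a and second code b
    (0 = unmethylated, 1 = methylated) at gene g's clamped frequency.
    """
    p_eff = panel.effective_p(params.epsilon)
    table = np.empty((len(panel), 2, 2))
    for j, g in enumerate(panel.genes):
        for a, sa in ((0, _U), (1, _M)):
            for b, sb in ((0, _U), (1, _M)):
                table[j, a, b] = gene_log_ratio(g, sa, sb, p_eff[g], params).log_ratio
    return table


def lr_from_codes(
    primary_codes: np.ndarray, second_codes: np.ndarray, table: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """LR and informative-gene count for row-aligned code matrices.

    Both inputs have shape (n_pairs, n_genes); genes coded 2 in either row
    are skipped. Returns (lr, n_informative), each of length n_pairs.
    """
    a = primary_codes
    b = second_codes
    valid = (a != 2) & (b != 2)
    ai = np.clip(a, 0, 1)
    bi = np.clip(b, 0, 1)
    gidx = np.arange(a.shape[1])[None, :]
    per_gene = table[gidx, ai, bi]
    lr = np.where(valid, per_gene, 0.0).sum(axis=1)
    return lr, valid.sum(axis=1)


def cross_lr_matrix(
    codes: np.ndarray, table: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All ordered pairings' LR over a tumour code matrix.

    ``codes`` has shape (n_tumours, n_genes). Returns (lr, n_informative)
    matrices of shape (n_tumours, n_tumours) where entry (i, j) treats
    tumour i as primary and tumour j as second.
    """
    n, g = codes.shape
    lr = np.zeros((n, n))
    ninf = np.zeros((n, n), dtype=np.int32)
    ai = np.clip(codes, 0, 1)
    for j in range(g):
        valid = (codes[:, j] != 2)[:, None] & (codes[:, j] != 2)[None, :]
        per = table[j][ai[:, j][:, None], ai[:, j][None, :]]
        lr += np.where(valid, per, 0.0)
        ninf += valid
    return lr, ninf
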