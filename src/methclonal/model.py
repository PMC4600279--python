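"""Domain types for methylation-based tumour clonality inference.

The analysis operates on *binary* promoter-methylation calls over a fixed
marker panel. A second tumour is either a recurrence of the primary
(clonally related, label RECURRENT) or an independent new primary
(DE_NOVO). Each marker gene ``i`` carries a background probability
``p_i`` of being methylated in a breast tumour, and a clonally related
second tumour loses methylation at a marker with probability ``gamma``
and gains it with probability ``gain_multiplier * gamma``.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

logger = logging.getLogger("methclonal")
logger.addHandler(logging.NullHandler())


class MethClonalError(Exception):
    """Base class for package errors."""


class InputValidationError(MethClonalError, ValueError):
    """A data file or cell failed validation."""


class ParameterError(MethClonalError, ValueError):
    """A model parameter is outside its valid range."""


class MethylationStatus(enum.Enum):
    """Per-gene methylation call.

    UNINFORMATIVE marks a marker that could not be scored (failed
    amplification or irreproducible melt); it is never treated as a
    measured state.
    """

    METHYLATED = "M"
    UNMETHYLATED = "U"
    UNINFORMATIVE = "NA"


class Laterality(enum.Enum):
    IPSILATERAL = "ipsilateral"
    CONTRALATERAL = "contralateral"


class TumourRole(enum.Enum):
    PRIMARY = "primary"
    SECOND = "second"


class ClonalityLabel(enum.Enum):
    RECURRENT = "recurrent"
    DE_NOVO = "de_novo"


# Marker-panel background methylation frequencies observed in a 29-pair
# breast-tumour cohort (fraction of tumours methylated per gene).
COHORT_FREQUENCIES: dict[str, float] = {
    "RASSF1A": 0.64,
    "TWIST1": 0.61,
    "CDH13": 0.51,
    "APC": 0.50,
    "MAL": 0.35,
    "GSTP1": 0.30,
    "WIF1": 0.26,
    "RARB": 0.19,
    "BRCA1": 0.02,
    "CDKN2A": 0.02,
    "TP73": 0.02,
    "CDH1": 0.00,
    "MGMT": 0.00,
}

# Literature-reported breast-cancer methylation frequencies where available;
# genes without a published consensus fall back to the cohort values.
LITERATURE_OVERRIDES: dict[str, float] = {
    "RASSF1A": 0.71,
    "CDH13": 0.49,
    "RARB": 0.21,
    "TWIST1": 0.26,
    "WIF1": 0.65,
    "CDH1": 0.28,
}


@dataclass(frozen=True)
class GenePanel:
    """Ordered marker list with per-gene background methylation probability.

    Parameters
    ----------
    genes
        Marker names in a fixed order (the order of report columns).
    p
        Map gene -> background probability of methylation, each in [0, 1].
    source_label
        Free-text provenance of the frequencies.
    """

    genes: tuple[str, ...]
    p: Mapping[str, float]
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise InputValidationError("empty panel")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise InputValidationError(f"duplicate gene(s) in panel: {dupes}")
        for g in self.genes:
            if g not in self.p:
                raise InputValidationError(f"panel gene {g!r} has no frequency")
            v = float(self.p[g])
            if not (0.0 <= v <= 1.0):
                raise InputValidationError(
                    f"frequency for gene {g!r} out of range [0, 1]: {v}"
                )
        object.__setattr__(self, "_effective_cache", {})

    def __len__(self) -> int:
        return len(self.genes)

    def effective_p(self, epsilon: float) -> dict[str, float]:
        """Background probabilities clamped to [epsilon, 1 - epsilon].

        Observed frequencies of exactly 0 (or 1) would make one of the
        likelihood denominators vanish; clamping keeps every per-gene log
        ratio finite. Clamped genes are logged once per call.
        """
        if not (0.0 < epsilon < 0.5):
            raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")
        cache: dict[float, dict[str, float]] = getattr(self, "_effective_cache")
        if epsilon in cache:
            return cache[epsilon]
        out: dict[str, float] = {}
        clamped = []
        for g in self.genes:
            raw = float(self.p[g])
            eff = min(max(raw, epsilon), 1.0 - epsilon)
            if eff != raw:
                clamped.append(g)
            out[g] = eff
        if clamped:
            logger.warning(
                "clamped background frequency to [%g, %g] for gene(s): %s",
                epsilon, 1.0 - epsilon, ", ".join(clamped),
            )
        cache[epsilon] = out
        return out


def default_panel(name: str = "cohort") -> GenePanel:
    """Return one of the two shipped frequency sets.

    ``"cohort"`` uses the frequencies observed in the 29-pair study cohort;
    ``"literature-partial"`` substitutes published breast-cancer frequencies
    for the six genes with a literature consensus, keeping cohort values for
    the rest.
    """
    genes = tuple(COHORT_FREQUENCIES)
    if name == "cohort":
        return GenePanel(genes, dict(COHORT_FREQUENCIES), source_label="cohort-observed")
    if name == "literature-partial":
        p = dict(COHORT_FREQUENCIES)
        p.update(LITERATURE_OVERRIDES)
        return GenePanel(genes, p, source_label="literature-partial")
    raise ParameterError(
        f"unknown panel name {name!r}; expected 'cohort' or 'literature-partial'"
    )


def call_methylation_status(
    percent: Optional[float],
    threshold: float = 10.0,
    *,
    sample: str = "?",
    gene: str = "?",
) -> MethylationStatus:
    """Convert a methylation percentage into a binary call.

    A missing measurement (None or NaN) is UNINFORMATIVE; a percentage
    strictly above ``threshold`` is METHYLATED ("above" read strictly, so
    the boundary value itself is UNMETHYLATED); anything else UNMETHYLATED.
    """
    if not (0.0 <= threshold < 100.0):
        raise ParameterError(f"call threshold must be in [0, 100), got {threshold}")
    if percent is None or (isinstance(percent, float) and math.isnan(percent)):
        return MethylationStatus.UNINFORMATIVE
    value = float(percent)
    if not (0.0 <= value <= 100.0):
        raise InputValidationError(
            f"methylation percentage {value} out of range [0, 100] "
            f"for sample {sample!r}, gene {gene!r}"
        )
    if value > threshold:
        return MethylationStatus.METHYLATED
    return MethylationStatus.UNMETHYLATED


@dataclass
class TumourProfile:
    """One tumour's methylation calls over the panel.

    ``percents`` holds the raw assay percentages when they are available;
    in that case the binary calls must be consistent with
    :func:`call_methylation_status`.
    """

    sample_id: str
    patient_id: str
    role: TumourRole
    calls: dict[str, MethylationStatus]
    percents: Optional[dict[str, float]] = None

    def validate_against(self, panel: GenePanel) -> None:
        missing = [g for g in panel.genes if g not in self.calls]
        if missing:
            raise InputValidationError(
                f"sample {self.sample_id!r} lacks calls for panel gene(s): {missing}"
            )


@dataclass
class TumourPair:
    """A patient's primary tumour and second tumour."""

    patient_id: str
    laterality: Laterality
    primary: TumourProfile
    second: TumourProfile

    def __post_init__(self) -> None:
        if self.primary.role is not TumourRole.PRIMARY:
            raise InputValidationError(
                f"pair {self.patient_id!r}: primary profile has role {self.primary.role}"
            )
        if self.second.role is not TumourRole.SECOND:
            raise InputValidationError(
                f"pair {self.patient_id!r}: second profile has role {self.second.role}"
            )
        if not (self.primary.patient_id == self.second.patient_id == self.patient_id):
            raise InputValidationError(
                f"pair {self.patient_id!r}: profiles carry a different patient_id"
            )


@dataclass
class ClonalityParams:
    """Model and decision parameters.

    Attributes
    ----------
    gamma
        Probability a methylated marker in the primary is unmethylated in a
        clonally related second tumour (loss on progression).
    gain_multiplier
        Methylation gain is modelled at ``gain_multiplier * gamma``
        (default 2, reflecting that gain is the more likely direction
        during tumour progression).
    prior_recurrence
        Prior probability that the second tumour is a recurrence, per
        laterality. Defaults 0.75 (ipsilateral) and 0.145 (contralateral),
        taken from molecular (aCGH/LOH/TP53) literature.
    call_threshold
        Percentage above which a marker is called methylated.
    alpha
        Significance level for the empirical test.
    epsilon
        Clamping bound applied to background frequencies p_i.
    """

    gamma: float = 0.05
    gain_multiplier: float = 2.0
    prior_recurrence: dict[Laterality, float] = field(
        default_factory=lambda: {
            Laterality.IPSILATERAL: 0.75,
            Laterality.CONTRALATERAL: 0.145,
        }
    )
    call_threshold: float = 10.0
    alpha: float = 0.05
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ParameterError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.gain_multiplier <= 0:
            raise ParameterError(
                f"gain_multiplier must be positive, got {self.gain_multiplier}"
            )
        if self.gain_multiplier * self.gamma > 1.0:
            raise ParameterError(
                "gain probability gain_multiplier*gamma exceeds 1: "
                f"{self.gain_multiplier} * {self.gamma}"
            )
        for lat in (Laterality.IPSILATERAL, Laterality.CONTRALATERAL):
            pr = self.prior_recurrence.get(lat)
            if pr is None or not (0.0 < pr < 1.0):
                raise ParameterError(
                    f"prior_recurrence[{lat.value}] must be in (0, 1), got {pr}"
                )
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.epsilon < 0.5):
            raise ParameterError(f"epsilon must be in (0, 0.5), got {self.epsilon}")
        if not (0.0 <= self.call_threshold < 100.0):
            raise ParameterError(
                f"call_threshold must be in [0, 100), got {self.call_threshold}"
            )
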