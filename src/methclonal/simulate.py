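"""Synthetic cohorts of paired binary methylation profiles.

The generator emulates the generative structure the likelihood model
assumes, with known ground-truth clonality:

* primary tumour: each gene methylated independently with its background
  probability p_i;
* clonally related second tumour: a methylated marker stays methylated
  with probability 1 - gamma, an unmethylated marker gains methylation
  with probability gain_multiplier * gamma;
* unrelated second tumour: independent Bernoulli(p_i);
* finally each call is independently masked uninformative with a fixed
  dropout rate, emulating failed assays.

A cohort draws, per patient in order: the clonality indicator, the primary
gene calls, the second-tumour gene calls, then the masking indicators —
all from one seeded stream, so a fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ClonalityLabel,
    GenePanel,
    Laterality,
    ParameterError,
    TumourPair,
    TumourProfile,
    TumourRole,
    default_panel,
)

_CODE_TO_STATUS = None  # set lazily to avoid import cycle at module load


def _status_of_code():
    global _CODE_TO_STATUS
    if _CODE_TO_STATUS is None:
        from .likelihood import STATUS_OF_CODE

        _CODE_TO_STATUS = STATUS_OF_CODE
    return _CODE_TO_STATUS


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the study design the model was built for: 16
    ipsilateral and 13 contralateral pairs, true recurrence rates 0.75 and
    0.145, loss rate gamma = 0.05 with gain at 2*gamma, and a 5 % assay
    dropout rate.
    """

    n_ipsilateral: int = 16
    n_contralateral: int = 13
    recurrence_rate: dict[Laterality, float] = field(
        default_factory=lambda: {
            Laterality.IPSILATERAL: 0.75,
            Laterality.CONTRALATERAL: 0.145,
        }
    )
    panel: GenePanel = field(default_factory=default_panel)
    gamma: float = 0.05
    gain_multiplier: float = 2.0
    uninformative_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ipsilateral < 0 or self.n_contralateral < 0:
            raise ParameterError("pair counts must be non-negative")
        if self.n_ipsilateral + self.n_contralateral == 0:
            raise ParameterError("at least one pair must be requested")
        if not (0.0 <= self.gamma <= 1.0):
            raise ParameterError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.gain_multiplier * self.gamma > 1.0 or self.gain_multiplier < 0:
            raise ParameterError("gain probability gain_multiplier*gamma must be in [0, 1]")
        if not (0.0 <= self.uninformative_rate < 1.0):
            raise ParameterError(
                f"uninformative_rate must be in [0, 1), got {self.uninformative_rate}"
            )
        for lat, r in self.recurrence_rate.items():
            if not (0.0 <= r <= 1.0):
                raise ParameterError(
                    f"recurrence_rate[{lat.value}] must be in [0, 1], got {r}"
                )


def _simulate_call_codes(
    rng: np.random.Generator,
    p: np.ndarray,
    n_pairs: int,
    clonal: np.ndarray,
    gamma: float,
    gain_multiplier: float,
    uninformative_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized engine: (primary, second) code matrices, shape (n_pairs, G).

    Codes: 0 unmethylated, 1 methylated, 2 uninformative. Draw order within
    the stream: primary calls, second calls, masking (primary then second).
    """
    gain = gain_multiplier * gamma
    primary = (rng.random((n_pairs, p.size)) < p[None, :]).astype(np.int8)
    u = rng.random((n_pairs, p.size))
    # clonal: methylated retains with prob 1-gamma, unmethylated gains with prob gain
    clonal_second = np.where(primary == 1, u < 1.0 - gamma, u < gain).astype(np.int8)
    independent_second = (u < p[None, :]).astype(np.int8)
    second = np.where(clonal[:, None], clonal_second, independent_second)
    if uninformative_rate > 0:
        primary = primary.copy()
        mask_p = rng.random((n_pairs, p.size)) < uninformative_rate
        mask_s = rng.random((n_pairs, p.size)) < uninformative_rate
        primary[mask_p] = 2
        second = second.copy()
        second[mask_s] = 2
    return primary, second


def _profiles_from_codes(
    patient_id: str,
    laterality: Laterality,
    panel: GenePanel,
    primary_codes: np.ndarray,
    second_codes: np.ndarray,
) -> TumourPair:
    status = _status_of_code()
    primary = TumourProfile(
        sample_id=f"{patient_id}A",
        patient_id=patient_id,
        role=TumourRole.PRIMARY,
        calls={g: status[int(primary_codes[j])] for j, g in enumerate(panel.genes)},
    )
    second = TumourProfile(
        sample_id=f"{patient_id}B",
        patient_id=patient_id,
        role=TumourRole.SECOND,
        calls={g: status[int(second_codes[j])] for j, g in enumerate(panel.genes)},
    )
    return TumourPair(patient_id=patient_id, laterality=laterality, primary=primary, second=second)


def simulate_pair(
    panel: GenePanel,
    clonal: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    patient_id: str = "sim1",
    laterality: Laterality = Laterality.IPSILATERAL,
) -> tuple[TumourPair, ClonalityLabel]:
    """Draw one tumour pair with known clonality from the generative model."""
    p = np.array([panel.p[g] for g in panel.genes], dtype=float)
    prim, sec = _simulate_call_codes(
        rng,
        p,
        1,
        np.array([clonal]),
        config.gamma,
        config.gain_multiplier,
        config.uninformative_rate,
    )
    pair = _profiles_from_codes(patient_id, laterality, panel, prim[0], sec[0])
    truth = ClonalityLabel.RECURRENT if clonal else ClonalityLabel.DE_NOVO
    return pair, truth


def simulate_cohort(
    config: SimulationConfig, *, rng: Optional[np.random.Generator] = None
) -> tuple[list[TumourPair], dict[str, ClonalityLabel]]:
    """Draw a full cohort plus its ground-truth clonality labels.

    Patients are generated ipsilateral block first (ids ipsi1, ipsi2, ...)
    then contralateral (contra1, ...); each patient consumes the stream in
    the documented order, so a fixed seed reproduces the cohort exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pairs: list[TumourPair] = []
    truth: dict[str, ClonalityLabel] = {}
    blocks = (
        (Laterality.IPSILATERAL, "ipsi", config.n_ipsilateral),
        (Laterality.CONTRALATERAL, "contra", config.n_contralateral),
    )
    for laterality, prefix, count in blocks:
        rate = config.recurrence_rate[laterality]
        for k in range(1, count + 1):
            clonal = bool(rng.random() < rate)
            pair, label = simulate_pair(
                config.panel,
                clonal,
                config,
                rng,
                patient_id=f"{prefix}{k}",
                laterality=laterality,
            )
            pairs.append(pair)
            truth[pair.patient_id] = label
    return pairs, truth
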