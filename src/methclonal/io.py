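"""Readers and writers for panel, cohort, reference and results tables.

All files are plain TSV with a header row. Cohort tables come in two
shapes:

* wide — one row per tumour sample: ``patient_id, sample_id, laterality,
  role`` then one column per panel gene holding either a methylation
  percentage (0-100) or a status token M / U / NA;
* long — one row per sample x gene: ``patient_id, sample_id, laterality,
  role, gene, value`` with the same cell convention.

Empty cells and NA are uninformative. Laterality tokens are
"ipsilateral" / "contralateral" (case-insensitive); anything else is an
error, never a guess.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .likelihood import LRResult
from .model import (
    ClonalityLabel,
    ClonalityParams,
    GenePanel,
    InputValidationError,
    Laterality,
    MethylationStatus,
    TumourPair,
    TumourProfile,
    TumourRole,
    call_methylation_status,
)

PathLike = Union[str, Path]

_STATUS_TOKENS = {
    "M": MethylationStatus.METHYLATED,
    "U": MethylationStatus.UNMETHYLATED,
    "NA": MethylationStatus.UNINFORMATIVE,
}
_LABEL_TOKENS = {
    "recurrent": ClonalityLabel.RECURRENT,
    "de_novo": ClonalityLabel.DE_NOVO,
}


def load_panel(path: PathLike) -> GenePanel:
    """Read a gene-panel TSV with columns ``gene``, ``frequency`` [, ``source``]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "frequency"):
        if col not in df.columns:
            raise InputValidationError(f"panel file {path} lacks column {col!r}")
    if len(df) == 0:
        raise InputValidationError("empty panel")
    genes: list[str] = []
    p: dict[str, float] = {}
    for idx, row in df.iterrows():
        gene = row["gene"].strip()
        if gene in p:
            raise InputValidationError(f"duplicate gene {gene!r} in panel (row {idx + 2})")
        try:
            freq = float(row["frequency"])
        except ValueError:
            raise InputValidationError(
                f"non-numeric frequency {row['frequency']!r} for gene {gene!r} "
                f"(row {idx + 2})"
            ) from None
        if not (0.0 <= freq <= 1.0):
            raise InputValidationError(
                f"frequency {freq} out of range [0, 1] for gene {gene!r} (row {idx + 2})"
            )
        genes.append(gene)
        p[gene] = freq
    source = df["source"].iloc[0] if "source" in df.columns else str(path)
    return GenePanel(tuple(genes), p, source_label=source)


def write_panel(panel: GenePanel, path: PathLike) -> None:
    pd.DataFrame(
        {"gene": panel.genes, "frequency": [panel.p[g] for g in panel.genes]}
    ).to_csv(path, sep="\t", index=False)


def _parse_cell(
    cell: str, params: ClonalityParams, sample: str, gene: str
) -> tuple[MethylationStatus, Optional[float]]:
    """One cohort cell -> (status, percent-or-None)."""
    token = cell.strip()
    if token == "" or token.upper() in ("NA", "NAN", "X"):
        return MethylationStatus.UNINFORMATIVE, None
    upper = token.upper()
    if upper in _STATUS_TOKENS:
        return _STATUS_TOKENS[upper], None
    try:
        percent = float(token)
    except ValueError:
        raise InputValidationError(
            f"cannot interpret cell {cell!r} for sample {sample!r}, gene {gene!r}: "
            "expected a percentage or M/U/NA"
        ) from None
    if math.isnan(percent):
        return MethylationStatus.UNINFORMATIVE, None
    status = call_methylation_status(
        percent, params.call_threshold, sample=sample, gene=gene
    )
    return status, percent


def _parse_laterality(token: str, patient_id: str) -> Laterality:
    t = token.strip().lower()
    for lat in Laterality:
        if t == lat.value:
            return lat
    raise InputValidationError(
        f"unknown laterality token {token!r} for patient {patient_id!r}"
    )


def _parse_role(token: str, sample_id: str) -> TumourRole:
    t = token.strip().lower()
    for role in TumourRole:
        if t == role.value:
            return role
    raise InputValidationError(f"unknown role token {token!r} for sample {sample_id!r}")


_META_COLS = ("patient_id", "sample_id", "laterality", "role")


def load_cohort(
    path: PathLike, panel: GenePanel, params: ClonalityParams
) -> list[TumourPair]:
    """Read a cohort TSV (wide or long) into tumour pairs.

    The shape is detected from the header: a ``gene``/``value`` column pair
    means long format, otherwise every non-metadata column must be a panel
    gene. Each patient must contribute exactly one primary and one second
    tumour; genes absent for a sample are uninformative.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _META_COLS:
        if col not in df.columns:
            raise InputValidationError(f"cohort file {path} lacks column {col!r}")
    long_format = "gene" in df.columns and "value" in df.columns

    # sample_id -> (patient_id, laterality, role, {gene: cell})
    samples: dict[str, tuple[str, Laterality, TumourRole, dict[str, str]]] = {}

    if long_format:
        for _, row in df.iterrows():
            gene = row["gene"].strip()
            if gene not in panel.p:
                raise InputValidationError(f"unknown gene {gene!r} in cohort file")
            sid = row["sample_id"]
            if sid not in samples:
                samples[sid] = (
                    row["patient_id"],
                    _parse_laterality(row["laterality"], row["patient_id"]),
                    _parse_role(row["role"], sid),
                    {},
                )
            samples[sid][3][gene] = row["value"]
    else:
        gene_cols = [c for c in df.columns if c not in _META_COLS]
        unknown = [c for c in gene_cols if c not in panel.p]
        if unknown:
            raise InputValidationError(f"unknown gene column(s) in cohort file: {unknown}")
        for _, row in df.iterrows():
            sid = row["sample_id"]
            if sid in samples:
                raise InputValidationError(f"duplicate sample_id {sid!r} in cohort file")
            samples[sid] = (
                row["patient_id"],
                _parse_laterality(row["laterality"], row["patient_id"]),
                _parse_role(row["role"], sid),
                {g: row[g] for g in gene_cols},
            )

    # group by patient preserving first-appearance order
    by_patient: dict[str, list[tuple[str, Laterality, TumourRole, dict[str, str]]]] = {}
    for sid, (pid, lat, role, cells) in samples.items():
        by_patient.setdefault(pid, []).append((sid, lat, role, cells))

    pairs: list[TumourPair] = []
    for pid, entries in by_patient.items():
        if len(entries) != 2:
            raise InputValidationError(
                f"patient {pid!r} has {len(entries)} tumour sample(s); expected exactly 2"
            )
        roles = {role for _, _, role, _ in entries}
        if roles != {TumourRole.PRIMARY, TumourRole.SECOND}:
            raise InputValidationError(
                f"patient {pid!r} must have one primary and one second tumour"
            )
        lateralities = {lat for _, lat, _, _ in entries}
        if len(lateralities) != 1:
            raise InputValidationError(
                f"patient {pid!r} has inconsistent laterality across samples"
            )
        profiles: dict[TumourRole, TumourProfile] = {}
        for sid, lat, role, cells in entries:
            calls: dict[str, MethylationStatus] = {}
            percents: dict[str, float] = {}
            for g in panel.genes:
                if g in cells:
                    status, percent = _parse_cell(cells[g], params, sid, g)
                    calls[g] = status
                    if percent is not None:
                        percents[g] = percent
                else:
                    calls[g] = MethylationStatus.UNINFORMATIVE
            profiles[role] = TumourProfile(
                sample_id=sid,
                patient_id=pid,
                role=role,
                calls=calls,
                percents=percents or None,
            )
        pairs.append(
            TumourPair(
                patient_id=pid,
                laterality=lateralities.pop(),
                primary=profiles[TumourRole.PRIMARY],
                second=profiles[TumourRole.SECOND],
            )
        )
    if not pairs:
        raise InputValidationError(f"cohort file {path} contains no samples")
    return pairs


def write_cohort(pairs: Sequence[TumourPair], panel: GenePanel, path: PathLike) -> None:
    """Write a cohort in wide format with M/U/NA status tokens."""
    rows = []
    for pair in pairs:
        for t in (pair.primary, pair.second):
            row = {
                "patient_id": pair.patient_id,
                "sample_id": t.sample_id,
                "laterality": pair.laterality.value,
                "role": t.role.value,
            }
            for g in panel.genes:
                row[g] = t.calls[g].value
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(
    results: Sequence[LRResult],
    path: PathLike,
    *,
    decimals: int = 4,
) -> None:
    """Write one TSV row per pair, with per-gene contribution columns.

    Unset fields (degenerate pairs, skipped stages) are written as empty
    cells; skipped genes' contributions are written as NA.
    """
    if not results:
        raise InputValidationError("no results to write")

    def num(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.{decimals}f}"

    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "laterality": r.laterality.value,
            "n_informative_genes": r.n_informative,
            "LR": f"{r.LR:.{decimals}f}",
            "PLR": num(r.PLR),
            "bayesian_label": r.bayesian_label.value if r.bayesian_label else "",
            "empirical_p": num(r.empirical_p),
            "empirical_label": r.empirical_label.value if r.empirical_label else "",
        }
        for c in r.contributions:
            row[f"contrib_{c.gene}"] = "NA" if c.skipped else f"{c.log_ratio:.{decimals}f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference(path: PathLike) -> dict[str, ClonalityLabel]:
    """Read a two-column reference labelling: ``patient_id``, ``label``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "label"):
        if col not in df.columns:
            raise InputValidationError(f"reference file {path} lacks column {col!r}")
    out: dict[str, ClonalityLabel] = {}
    for idx, row in df.iterrows():
        token = row["label"].strip().lower()
        if token not in _LABEL_TOKENS:
            raise InputValidationError(
                f"unknown label {row['label']!r} for patient {row['patient_id']!r} "
                f"(row {idx + 2}); expected recurrent or de_novo"
            )
        out[row["patient_id"]] = _LABEL_TOKENS[token]
    if not out:
        raise InputValidationError(f"reference file {path} is empty")
    return out


def write_reference(labels: Mapping[str, ClonalityLabel], path: PathLike) -> None:
    pd.DataFrame(
        {"patient_id": list(labels), "label": [v.value for v in labels.values()]}
    ).to_csv(path, sep="\t", index=False)


_CONFIG_KEYS = {
    "gamma",
    "gain_multiplier",
    "prior_ipsilateral",
    "prior_contralateral",
    "call_threshold",
    "alpha",
    "epsilon",
    "seed",
}


def load_config(path: PathLike) -> tuple[ClonalityParams, Optional[int]]:
    """Read a flat key->value YAML config into parameters plus optional seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputValidationError(f"config file {path} must be a flat mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise InputValidationError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for key in ("gamma", "gain_multiplier", "call_threshold", "alpha", "epsilon"):
        if key in raw:
            kwargs[key] = float(raw[key])
    priors = {
        Laterality.IPSILATERAL: float(raw.get("prior_ipsilateral", 0.75)),
        Laterality.CONTRALATERAL: float(raw.get("prior_contralateral", 0.145)),
    }
    seed = int(raw["seed"]) if "seed" in raw else None
    return ClonalityParams(prior_recurrence=priors, **kwargs), seed
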