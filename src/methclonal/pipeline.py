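"""End-to-end analysis: LR per pair, Bayesian labels, empirical p-values.

The library entry point is :func:`analyze_cohort`, which takes in-memory
pairs; :func:`run_analysis` wraps it with file I/O, a run manifest, and
summary lines for the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .bayes import classify_bayesian
from .concordance import ConfusionTable, PredictiveValues, build_confusion, predictive_values
from .empirical import NullDistribution, build_null_distribution, classify_empirical
from .io import load_cohort, load_config, load_panel, load_reference, write_results
from .likelihood import LRResult, pair_log_ratio
from .model import (
    ClonalityLabel,
    ClonalityParams,
    GenePanel,
    Laterality,
    TumourPair,
    default_panel,
)

logger = logging.getLogger("methclonal")

PathLike = Union[str, Path]


def analyze_cohort(
    pairs: Sequence[TumourPair],
    panel: GenePanel,
    params: ClonalityParams,
    *,
    run_empirical: bool = True,
    exclude_self_from_null: bool = False,
) -> tuple[list[LRResult], Optional[NullDistribution]]:
    """Score every pair: LR, PLR + Bayesian label, and empirical p + label.

    With ``exclude_self_from_null`` each pair is tested against a null
    rebuilt without its own patient's tumours (stricter independence, at
    the cost of one null per patient); the default pools all patients.
    """
    results = [pair_log_ratio(pair, panel, params) for pair in pairs]
    for r in results:
        classify_bayesian(r, params)
    null: Optional[NullDistribution] = None
    if run_empirical:
        null = build_null_distribution(pairs, panel, params)
        for pair, r in zip(pairs, results):
            if exclude_self_from_null:
                own_null = build_null_distribution(
                    pairs, panel, params, exclude_patient=pair.patient_id
                )
                classify_empirical(r, own_null, params)
            else:
                classify_empirical(r, null, params)
    return results, null


def recurrent_fractions(
    results: Sequence[LRResult], which: str
) -> dict[Laterality, Optional[float]]:
    """Fraction of labelled pairs called recurrent, per laterality.

    ``which`` selects ``"bayesian"`` or ``"empirical"`` labels; lateralities
    with no labelled pair map to None.
    """
    attr = {"bayesian": "bayesian_label", "empirical": "empirical_label"}[which]
    out: dict[Laterality, Optional[float]] = {}
    for lat in Laterality:
        labelled = [
            r for r in results if r.laterality is lat and getattr(r, attr) is not None
        ]
        if not labelled:
            out[lat] = None
            continue
        rec = sum(
            getattr(r, attr) is ClonalityLabel.RECURRENT for r in labelled
        )
        out[lat] = rec / len(labelled)
    return out


@dataclass
class RunManifest:
    """Record of one analysis run: inputs, resolved parameters, counts."""

    cohort_path: str
    panel_source: str
    params: dict
    n_pairs: int
    n_ipsilateral: int
    n_contralateral: int
    null_size: Optional[int]
    null_comparisons: Optional[int]
    null_degenerate_dropped: Optional[int]
    n_degenerate_pairs: int
    version: str = __version__
    seed: Optional[int] = None
    outputs: dict = field(default_factory=dict)

    def write(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _params_dict(params: ClonalityParams) -> dict:
    return {
        "gamma": params.gamma,
        "gain_multiplier": params.gain_multiplier,
        "prior_ipsilateral": params.prior_recurrence[Laterality.IPSILATERAL],
        "prior_contralateral": params.prior_recurrence[Laterality.CONTRALATERAL],
        "call_threshold": params.call_threshold,
        "alpha": params.alpha,
        "epsilon": params.epsilon,
    }


def summary_lines(
    results: Sequence[LRResult],
    null: Optional[NullDistribution],
    concord: Optional[tuple[ConfusionTable, PredictiveValues]] = None,
) -> list[str]:
    """Human-readable run summary; fractions reported to whole percents."""
    lines = [f"pairs analysed: {len(results)}"]
    if null is not None:
        lines.append(
            f"empirical null: {len(null)} LRs from {null.n_comparisons} "
            f"cross-patient pairings ({null.n_degenerate_dropped} degenerate dropped)"
        )
    for which in ("bayesian", "empirical"):
        if which == "empirical" and null is None:
            continue
        fracs = recurrent_fractions(results, which)
        parts = []
        for lat in Laterality:
            f = fracs[lat]
            parts.append(
                f"{lat.value} {'n/a' if f is None else format(f, '.0%')}"
            )
        lines.append(f"recurrent fraction ({which}): " + ", ".join(parts))
    if concord is not None:
        table, pv = concord
        lines.append(
            f"concordance vs reference (n={table.total}): "
            f"tp={table.tp} fn={table.fn} fp={table.fp} tn={table.tn}"
        )

        def fmt(x: Optional[float]) -> str:
            return "undefined" if x is None else f"{x:.2f}"

        lines.append(
            f"Sn={fmt(pv.sensitivity)} Sp={fmt(pv.specificity)} "
            f"PPV={fmt(pv.ppv)} NPV={fmt(pv.npv)}"
        )
    return lines


def run_analysis(
    cohort_path: PathLike,
    *,
    panel: Union[GenePanel, PathLike, None] = None,
    frequencies: str = "cohort",
    config_path: Optional[PathLike] = None,
    params: Optional[ClonalityParams] = None,
    out_path: PathLike = "results.tsv",
    manifest_path: Optional[PathLike] = None,
    null_out: Optional[PathLike] = None,
    reference_path: Optional[PathLike] = None,
    reference_labels: str = "bayesian",
    skip_empirical: bool = False,
    exclude_self_from_null: bool = False,
) -> tuple[list[LRResult], RunManifest, list[str]]:
    """File-level pipeline: load, score, classify, write results + manifest.

    Returns the results, the manifest, and the summary lines (the CLI prints
    the latter). ``panel`` may be a GenePanel, a path to a panel TSV, or
    None, in which case ``frequencies`` names a shipped set.
    """
    seed: Optional[int] = None
    if params is None:
        if config_path is not None:
            params, seed = load_config(config_path)
        else:
            params = ClonalityParams()
    if isinstance(panel, GenePanel):
        panel_obj = panel
    elif panel is not None:
        panel_obj = load_panel(panel)
    else:
        panel_obj = default_panel(frequencies)

    pairs = load_cohort(cohort_path, panel_obj, params)
    results, null = analyze_cohort(
        pairs,
        panel_obj,
        params,
        run_empirical=not skip_empirical,
        exclude_self_from_null=exclude_self_from_null,
    )
    write_results(results, out_path)

    concord = None
    if reference_path is not None:
        reference = load_reference(reference_path)
        attr = {"bayesian": "bayesian_label", "empirical": "empirical_label"}[
            reference_labels
        ]
        predicted = {
            r.patient_id: getattr(r, attr)
            for r in results
            if getattr(r, attr) is not None
        }
        table = build_confusion(predicted, reference)
        concord = (table, predictive_values(table))

    if null is not None and null_out is not None:
        pd.DataFrame({"LR": null.values}).to_csv(null_out, sep="\t", index=False)

    manifest = RunManifest(
        cohort_path=str(cohort_path),
        panel_source=panel_obj.source_label,
        params=_params_dict(params),
        n_pairs=len(results),
        n_ipsilateral=sum(r.laterality is Laterality.IPSILATERAL for r in results),
        n_contralateral=sum(r.laterality is Laterality.CONTRALATERAL for r in results),
        null_size=len(null) if null is not None else None,
        null_comparisons=null.n_comparisons if null is not None else None,
        null_degenerate_dropped=(
            null.n_degenerate_dropped if null is not None else None
        ),
        n_degenerate_pairs=sum(r.degenerate for r in results),
        seed=seed,
        outputs={"results": str(out_path)},
    )
    if null_out is not None and null is not None:
        manifest.outputs["null"] = str(null_out)
    if manifest_path is not None:
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = str(manifest_path)

    return results, manifest, summary_lines(results, null, concord)
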