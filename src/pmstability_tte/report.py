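"""End-to-end orchestration: standardise -> calibrate/load the core model
-> simulate follow-up if absent -> unit information -> precision records
per candidate sample size -> instability metrics, subgroup and risk-stratum
summaries -> plots and a reproducibility manifest.

All outputs are plain CSV/JSON (plus PNG figures); identical config + seed
gives byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import CalibrationTarget, calibrate, standardised_equal_weight_model
from .cohort import Cohort, summarise_followup
from .errors import StateError
from .information import unit_information
from .metrics import ThresholdSpec, attach_metrics, summarise_instability
from .model import CoreModel
from .plots import classification_instability_plot, prediction_instability_plot
from .precision import SampleSizeSpec, cohort_required_n, precision_records
from .simulate import CensoringScheme, with_simulated_followup

logger = logging.getLogger("pmstability_tte")

__all__ = ["RunConfig", "run_assess", "run_size"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end assessment or sizing run.

    Exactly one model source must be given: an explicit ``model``, or
    ``weights`` + ``target`` (calibration), or ``equal_weights=True``
    (standardised equal-weight specification).
    """

    cohort: Cohort
    horizon: float
    n_values: tuple[int, ...] = (355,)
    model: CoreModel | None = None
    weights: dict[str, float] | None = None
    target: CalibrationTarget | None = None
    equal_weights: bool = False
    zero_weight: tuple[str, ...] = ()
    censoring: CensoringScheme | None = None
    threshold: float = 0.2
    level: float = 0.95
    draws: int = 1000
    seed: int = 0
    subgroup: str | None = None
    risk_stratum_max: float = 0.3
    size_spec: SampleSizeSpec | None = None
    out_dir: Path = Path("pmstability_out")
    make_plots: bool = True

    def __post_init__(self) -> None:
        sources = sum(
            [self.model is not None, self.weights is not None, self.equal_weights]
        )
        if sources != 1:
            raise ValueError(
                "give exactly one model source: model, weights+target, or equal_weights"
            )
        if self.model is None and self.target is None:
            raise ValueError("calibration requires a target (C-index, overall risk)")
        if any(n <= 0 for n in self.n_values):
            raise ValueError("candidate sample sizes must be positive integers")
        self.out_dir = Path(self.out_dir)


def _resolve_model(config: RunConfig) -> tuple[Cohort, CoreModel, dict]:
    cohort = config.cohort
    diag: dict = {}
    if config.model is not None:
        model = config.model
    elif config.equal_weights:
        # the returned model carries the standardisation constants, so the
        # raw cohort can be scored directly
        result = standardised_equal_weight_model(
            cohort, config.target, config.horizon, config.zero_weight
        )
        model = result.model
        diag = {"achieved_c": result.achieved_c, "achieved_risk": result.achieved_risk}
    else:
        result = calibrate(cohort, config.weights, config.target, config.horizon)
        model = result.model
        diag = {"achieved_c": result.achieved_c, "achieved_risk": result.achieved_risk}
    if not cohort.has_followup:
        if config.censoring is None:
            raise StateError(
                "cohort has no follow-up and no censoring scheme was declared"
            )
        logger.info("simulating follow-up (seed=%d)", config.seed)
        cohort = with_simulated_followup(cohort, model, config.censoring, config.seed)
    return cohort, model, diag


def _manifest(config: RunConfig, extra: dict) -> dict:
    cfg = {
        "horizon": config.horizon,
        "n_values": list(config.n_values),
        "threshold": config.threshold,
        "level": config.level,
        "draws": config.draws,
        "seed": config.seed,
        "subgroup": config.subgroup,
        "risk_stratum_max": config.risk_stratum_max,
        "version": __version__,
    }
    cfg.update(extra)
    return cfg


def run_assess(config: RunConfig) -> dict:
    """Option A end to end: per-n precision records, instability summaries
    (overall, per subgroup, per true-risk stratum), plots and a manifest.

    Returns a dict with the summary frames and output paths.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cohort, model, diag = _resolve_model(config)
    followup = summarise_followup(cohort)
    info = unit_information(cohort, model)
    spec = ThresholdSpec(config.threshold, config.horizon)

    summaries = []
    paths: dict[str, str] = {}
    for n in config.n_values:
        logger.info("assessing candidate n=%d", n)
        records = precision_records(cohort, model, info, n, config.level)
        records = attach_metrics(records, spec, config.draws, config.seed)
        if config.subgroup is not None:
            if cohort.subgroups is None or config.subgroup not in cohort.subgroups:
                raise StateError(f"no subgroup column named {config.subgroup!r}")
            records[config.subgroup] = cohort.subgroups[config.subgroup].to_numpy()
        rec_path = out / f"precision_records_n{n}.csv"
        records.to_csv(rec_path, index=False)
        paths[f"records_n{n}"] = str(rec_path)

        summary = summarise_instability(records, by=config.subgroup)
        summary.insert(0, "n_development", n)
        summary.insert(1, "stratum", "all risks")
        low = records[records["risk_true"] <= config.risk_stratum_max]
        if not low.empty:
            s_low = summarise_instability(low, by=config.subgroup)
            s_low.insert(0, "n_development", n)
            s_low.insert(1, "stratum", f"true risk <= {config.risk_stratum_max}")
            summary = pd.concat([summary, s_low], ignore_index=True)
        summaries.append(summary)

        if config.make_plots:
            paths[f"prediction_plot_n{n}"] = str(
                prediction_instability_plot(
                    records, out / f"prediction_instability_n{n}.png",
                    title=f"n = {n}",
                )
            )
            paths[f"classification_plot_n{n}"] = str(
                classification_instability_plot(
                    records, config.threshold,
                    out / f"classification_instability_n{n}.png",
                    title=f"n = {n}",
                )
            )

    summary_all = pd.concat(summaries, ignore_index=True)
    summary_path = out / "instability_summary.csv"
    summary_all.to_csv(summary_path, index=False)
    paths["summary"] = str(summary_path)

    manifest = _manifest(
        config,
        {
            "model": model.to_dict(),
            "calibration": diag,
            "followup": dataclasses.asdict(followup),
            "information_condition": info.condition,
            "outputs": paths,
        },
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return {
        "cohort": cohort,
        "model": model,
        "information": info,
        "summary": summary_all,
        "paths": paths,
    }


def run_size(config: RunConfig) -> dict:
    """Option B end to end: per-individual required n and the overall
    recommendation (max over the subset with true risk below the stratum
    cap), written as CSV + JSON."""
    if config.size_spec is None:
        raise ValueError("run_size needs a SampleSizeSpec in config.size_spec")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cohort, model, diag = _resolve_model(config)
    info = unit_information(cohort, model)
    records, overall = cohort_required_n(
        info,
        cohort,
        model,
        config.size_spec,
        subset=lambda r: r["risk_true"] <= config.risk_stratum_max,
    )
    rec_path = out / "required_n_records.csv"
    records.to_csv(rec_path, index=False)
    result = {
        "overall_n": overall,
        "subset": f"true risk <= {config.risk_stratum_max}",
        "bands": list(config.size_spec.bands),
        "target_widths": list(config.size_spec.target_widths),
        "n_distribution": {
            "min": float(records["n_required"].min()),
            "median": float(records["n_required"].median()),
            "max": float(records["n_required"].max()),
        },
    }
    (out / "required_n.json").write_text(json.dumps(result, indent=2), encoding="utf-8")
    return {"records": records, "overall_n": overall, "result": result, "model": model}
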