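"""End-to-end antibody-validation workflow.

Runs the validation stages in their bench order on synthetic samples with
known ground truth:

1. **titration** — stained/isotype pairs across antibody amounts, stain
   index per amount, optimal-amount selection;
2. **self_blocking** — pre-incubation with the antigen itself under the two
   standard conditions (300-fold excess, 37 °C, 1 h and 600-fold excess,
   RT, 2 h);
3. **cross_blocking** — pre-incubation with related proteins (600-fold, RT,
   2 h) and specificity classification;
4. **expression** — stain-index map across cell types with
   detected/marginal/not_detected calls;
5. **physiological** — two-condition contrasts (expression knock-down,
   neuronal vs non-neuronal enrichment) via normalized MFI, plus an
   image-based contrast through the Li-threshold quantification.

Every stage draws its random stream from the config seed through a spawned
seed tree, so re-running the same config is bit-identical.  The report
bundle echoes every threshold and seed used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytometry_io import EventTable
from .errors import ConfigError, CytovalError
from .gating import (
    GateHierarchy,
    apply_hierarchy,
    qc_min_events,
    scatter_hierarchy,
    viability_hierarchy,
)
from .stain_metrics import (
    BlockingCondition,
    StainSample,
    compute_stain_statistics,
    measure_blocking,
)
from .synthetic import (
    FLUOR_CHANNEL,
    BindingModel,
    BlockingTruth,
    ICCImageSpec,
    PAPER_BINDING_MODELS,
    PAPER_BLOCKING_TRUTHS,
    generate_blocking_experiment,
    generate_icc_image,
    generate_stain_pair,
    generate_titration_series,
    make_pair_specs,
)
from .image_quant import batch_quantify
from .validation import (
    AntibodyAssessment,
    OptimalAmountPolicy,
    TitrationSeries,
    assess_antibody,
    classify_expression,
    evaluate_titration,
    rank_antibodies,
    select_optimal_amount,
    summarize_blocking_panel,
)

log = logging.getLogger("cytoval")

ALL_STAGES = ("titration", "self_blocking", "cross_blocking", "expression", "physiological")

#: per-clone, per-cell-type ground-truth stain indices for the expression map
PAPER_EXPRESSION_SI: dict[str, dict[str, float | None]] = {
    "2A7": {"HEK": 20.38, "hiPSC": 17.32, "fibroblast": 1.70, "T_cell": 4.46},
    "LB509": {"HEK": 3.36, "hiPSC": 4.77, "fibroblast": 6.31, "T_cell": 5.37},
    "MJFR1": {"HEK": 9.74, "hiPSC": 3.64, "fibroblast": None, "T_cell": 1.36},
}


@dataclass(frozen=True)
class AntibodyJob:
    name: str
    model: BindingModel
    amounts: tuple[float, ...]
    recommended: float
    blocking_truth: BlockingTruth
    blockers: tuple[str, ...] = ("aSyn_monomer", "bSyn", "gSyn", "tubulin")
    expression_si: Mapping[str, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class WorkflowConfig:
    seed: int
    output_dir: Path
    antibodies: tuple[AntibodyJob, ...]
    stages: tuple[str, ...] = ALL_STAGES
    strategy: str = "scatter_only"
    fsc_h_min: float = 7.0e4
    debris_fsc_h_min: float = 3.0e4
    viability_threshold: float = 500.0
    singlet_band: tuple[float, float] = (0.8, 1.25)
    n_events: int = 20_000
    normalized_form: str = "ratio"
    theta: float = 0.75
    self_threshold: float = 0.85
    cross_threshold: float = 0.40
    detect_threshold: float = 1.5
    floor: float = 0.5
    physiological_contrasts: tuple[dict, ...] = ()
    icc_inside_means: tuple[float, float] = (50.0, 70.0)


#: default two-condition contrasts: an expression knock-down and a
#: neuronal-enrichment comparison, encoded as live-fluorescence means
DEFAULT_CONTRASTS = (
    {"name": "knockdown", "mean_a": 23_600.0, "mean_b": 16_800.0, "mean_iso": 2_000.0,
     "form": "ratio"},
    {"name": "neuronal_vs_nonneuronal", "mean_a": 30_000.0, "mean_b": 10_000.0,
     "mean_iso": 2_000.0, "form": "difference"},
)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> WorkflowConfig:
    """Parse and validate a YAML/dict workflow configuration."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(path_or_dict)
    _require(isinstance(raw, dict) and raw, "empty or non-mapping configuration")
    _require("seed" in raw, "configuration must set a seed (synthetic stages)")
    seed = int(raw["seed"])
    out = Path(raw.get("output_dir", "cytoval_out"))

    jobs = []
    for entry in raw.get("antibodies", []):
        _require(isinstance(entry, dict) and "name" in entry, "antibody entry needs a name")
        name = str(entry["name"])
        preset = entry.get("preset")
        if preset is not None:
            _require(preset in PAPER_BINDING_MODELS, f"unknown preset {preset!r}")
            model = PAPER_BINDING_MODELS[preset]["model"]
            amounts = tuple(entry.get("amounts", PAPER_BINDING_MODELS[preset]["amounts"]))
            recommended = float(
                entry.get("recommended", PAPER_BINDING_MODELS[preset]["recommended"])
            )
            truth = PAPER_BLOCKING_TRUTHS[preset]
            expr = PAPER_EXPRESSION_SI[preset]
        else:
            m = entry.get("model")
            _require(isinstance(m, dict), f"antibody {name!r} needs a preset or a model")
            model = BindingModel(
                bmax=float(m["bmax"]),
                kd=float(m["kd"]),
                slope=float(m.get("slope", 0.0)),
                background=float(m.get("background", 2000.0)),
                cv=float(m.get("cv", 0.5)),
            )
            amounts = tuple(float(a) for a in entry["amounts"])
            recommended = float(entry["recommended"])
            truth = BlockingTruth(dict(entry.get("blocking", {"aSyn_monomer": 1.0})))
            expr = dict(entry.get("expression_si", {}))
        _require(len(amounts) >= 2, f"antibody {name!r}: need >= 2 titration amounts")
        jobs.append(
            AntibodyJob(
                name=name,
                model=model,
                amounts=amounts,
                recommended=recommended,
                blocking_truth=truth,
                blockers=tuple(entry.get("blockers", ("aSyn_monomer", "bSyn", "gSyn", "tubulin"))),
                expression_si=expr,
            )
        )
    _require(bool(jobs), "configuration lists no antibodies")

    stages = tuple(raw.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    _require(not unknown, f"unknown stages {sorted(unknown)}")

    gating = raw.get("gating", {})
    thresholds = raw.get("thresholds", {})
    return WorkflowConfig(
        seed=seed,
        output_dir=out,
        antibodies=tuple(jobs),
        stages=stages,
        strategy=gating.get("strategy", "scatter_only"),
        fsc_h_min=float(gating.get("fsc_h_min", 7.0e4)),
        debris_fsc_h_min=float(gating.get("debris_fsc_h_min", 3.0e4)),
        viability_threshold=float(gating.get("viability_threshold", 500.0)),
        singlet_band=tuple(gating.get("singlet_band", (0.8, 1.25))),
        n_events=int(raw.get("n_events", 20_000)),
        normalized_form=raw.get("metrics", {}).get("normalized_form", "ratio"),
        theta=float(thresholds.get("theta", 0.75)),
        self_threshold=float(thresholds.get("self_threshold", 0.85)),
        cross_threshold=float(thresholds.get("cross_threshold", 0.40)),
        detect_threshold=float(thresholds.get("detect_threshold", 1.5)),
        floor=float(thresholds.get("floor", 0.5)),
        physiological_contrasts=tuple(raw.get("physiological", DEFAULT_CONTRASTS)),
        icc_inside_means=tuple(raw.get("icc_inside_means", (50.0, 70.0))),
    )


def build_hierarchy(cfg: WorkflowConfig) -> GateHierarchy:
    r_lo, r_hi = cfg.singlet_band
    if cfg.strategy == "viability_dye":
        # the scatter rectangle only removes debris here; dead cells are
        # excluded by the dye threshold
        return viability_hierarchy(
            "LiveDead-A", cfg.viability_threshold, cfg.debris_fsc_h_min, r_lo, r_hi
        )
    return scatter_hierarchy(cfg.fsc_h_min, 1.0e9, r_lo, r_hi)


def gate_table(table: EventTable, hierarchy: GateHierarchy) -> EventTable:
    pop = apply_hierarchy(table, hierarchy)
    return table.subset(pop.final_mask)


def _gated_sample(sample: StainSample, hierarchy: GateHierarchy) -> StainSample:
    return StainSample(
        antibody_events=gate_table(sample.antibody_events, hierarchy),
        isotype_events=gate_table(sample.isotype_events, hierarchy),
        channel=sample.channel,
        amount_ug=sample.amount_ug,
        antibody=sample.antibody,
    )


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_titration_stage(
    job: AntibodyJob, cfg: WorkflowConfig, hierarchy: GateHierarchy, seed: int
) -> dict:
    samples, truth = generate_titration_series(
        job.model, job.amounts, seed, antibody=job.name, n_events=cfg.n_events
    )
    points = []
    for amount, sample in samples:
        gated = _gated_sample(sample, hierarchy)
        stats = compute_stain_statistics(gated, form=cfg.normalized_form)
        points.append((amount, stats))
    series = TitrationSeries(
        antibody=job.name, points=tuple(points), recommended_amount=job.recommended
    )
    table = evaluate_titration(series)
    chosen = select_optimal_amount(
        series,
        OptimalAmountPolicy(theta=cfg.theta),
        iso_ratio_by_amount=dict(zip(table["amount_ug"], table["ratio_mfi_iso"])),
    )
    return {
        "table": table,
        "chosen_amount": chosen,
        "true_si": truth["true_si"],
        "series": series,
    }


def run_blocking_stage(
    job: AntibodyJob,
    cfg: WorkflowConfig,
    hierarchy: GateHierarchy,
    seed: int,
    conditions: Sequence[BlockingCondition],
) -> list:
    ss = np.random.SeedSequence(seed)
    measurements = []
    for cond, child in zip(conditions, ss.spawn(len(conditions))):
        tables, k_eff = generate_blocking_experiment(
            job.blocking_truth,
            cond,
            _child_seed(child),
            n_events=cfg.n_events,
            antibody=job.name,
        )
        gated = {label: gate_table(t, hierarchy) for label, t in tables.items()}
        m = measure_blocking(
            gated["stained"],
            gated[f"blocked:{cond.blocker}"],
            gated["no-stain"],
            FLUOR_CHANNEL,
            cond,
            cell_type="hiPSC",
        )
        measurements.append((m, k_eff))
    return measurements


def run_expression_stage(
    job: AntibodyJob, cfg: WorkflowConfig, hierarchy: GateHierarchy, seed: int
) -> dict:
    iso_mean, cv = 2000.0, 0.5
    ss = np.random.SeedSequence(seed)
    si_map: dict[str, float | None] = {}
    cells = list(job.expression_si)
    for cell, child in zip(cells, ss.spawn(max(len(cells), 1))):
        true_si = job.expression_si[cell]
        if true_si is None:
            ab_mean = iso_mean  # no detectable specific signal
        else:
            ab_mean = iso_mean + 2 * (iso_mean * cv) * true_si
        specs = make_pair_specs(
            ab_mean, iso_mean, cv=cv, n_events=cfg.n_events, cell_type=cell,
            antibody=job.name,
        )
        sample, _ = generate_stain_pair(*specs, _child_seed(child))
        stats = compute_stain_statistics(_gated_sample(sample, hierarchy))
        si_map[cell] = stats.si
    classes, order = classify_expression(si_map, cfg.detect_threshold, cfg.floor)
    return {"si": si_map, "classes": classes, "order": order, "true_si": dict(job.expression_si)}


def run_physiological_stage(cfg: WorkflowConfig, hierarchy: GateHierarchy, seed: int) -> list[dict]:
    out = []
    ss = np.random.SeedSequence(seed)
    contrasts = list(cfg.physiological_contrasts)
    children = ss.spawn(len(contrasts) + 1)
    for contrast, child in zip(contrasts, children):
        sub = child.spawn(2)
        values = []
        for mean_key, s in zip(("mean_a", "mean_b"), sub):
            specs = make_pair_specs(
                float(contrast[mean_key]), float(contrast["mean_iso"]),
                n_events=cfg.n_events,
            )
            sample, _ = generate_stain_pair(*specs, _child_seed(s))
            stats = compute_stain_statistics(
                _gated_sample(sample, hierarchy), form=contrast.get("form", "ratio")
            )
            values.append(stats.normalized_mfi)
        if contrast.get("form", "ratio") == "difference":
            # normalized MFI is the specific component itself
            truth_ratio = (float(contrast["mean_a"]) - float(contrast["mean_iso"])) / (
                float(contrast["mean_b"]) - float(contrast["mean_iso"])
            )
        else:
            truth_ratio = float(contrast["mean_a"]) / float(contrast["mean_b"])
        out.append(
            {
                "name": contrast["name"],
                "normalized_mfi_a": values[0],
                "normalized_mfi_b": values[1],
                "measured_fold": values[0] / values[1] if values[1] else float("nan"),
                "form": contrast.get("form", "ratio"),
                "true_fold": truth_ratio,
            }
        )
    # image-based contrast through the Li-threshold quantification
    lo, hi = cfg.icc_inside_means
    img_seeds = children[-1].spawn(2)
    imgs = [
        generate_icc_image(ICCImageSpec(target_inside=float(v)), _child_seed(s))[0]
        for v, s in zip((hi, lo), img_seeds)
    ]
    results = batch_quantify(imgs, policy="constant_from_reference", reference_index=0)
    out.append(
        {
            "name": "icc_contrast",
            "mean_gray_a": results[0].mean_gray,
            "mean_gray_b": results[1].mean_gray,
            "measured_fold": results[0].mean_gray / results[1].mean_gray,
            "true_fold": hi / lo,
            "form": "mean_gray_ratio",
        }
    )
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

SELF_CONDITIONS = (
    BlockingCondition("aSyn_monomer", 300, "37C", 1.0),
    BlockingCondition("aSyn_monomer", 600, "RT", 2.0),
)


def run_validation(config: WorkflowConfig | str | Path | Mapping) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the report dict; writes ``report.json``, per-stage CSVs and a
    run log under the configured output directory.  Aborts with the failing
    stage's name while preserving partial outputs.
    """
    cfg = config if isinstance(config, WorkflowConfig) else load_config(config)
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("cytoval %s; seed=%d; stages=%s", __version__, cfg.seed, ",".join(cfg.stages))
    log.info(
        "thresholds: theta=%.3g self=%.3g cross=%.3g detect=%.3g floor=%.3g",
        cfg.theta, cfg.self_threshold, cfg.cross_threshold, cfg.detect_threshold, cfg.floor,
    )

    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "thresholds": {
            "theta": cfg.theta,
            "self_threshold": cfg.self_threshold,
            "cross_threshold": cfg.cross_threshold,
            "detect_threshold": cfg.detect_threshold,
            "floor": cfg.floor,
        },
        "gating": {
            "strategy": cfg.strategy,
            "fsc_h_min": cfg.fsc_h_min,
            "singlet_band": list(cfg.singlet_band),
        },
        "antibodies": {},
    }
    hierarchy = build_hierarchy(cfg)
    root = np.random.SeedSequence(cfg.seed)
    ab_seeds = root.spawn(len(cfg.antibodies) + 1)

    stage = "setup"
    try:
        profiles = {}
        for job, ab_ss in zip(cfg.antibodies, ab_seeds):
            entry: dict[str, Any] = {}
            s_tit, s_self, s_cross, s_expr = (_child_seed(c) for c in ab_ss.spawn(4))
            if "titration" in cfg.stages:
                stage = f"titration[{job.name}]"
                res = run_titration_stage(job, cfg, hierarchy, s_tit)
                res["table"].to_csv(outdir / f"titration_{job.name}.csv", index=False)
                entry["titration"] = {
                    "chosen_amount": res["chosen_amount"],
                    "si_by_amount": dict(
                        zip(res["table"]["amount_ug"], res["table"]["si"])
                    ),
                    "true_si": res["true_si"],
                }
                log.info("%s: chosen amount %.3g ug", job.name, res["chosen_amount"])

            measurements = []
            if "self_blocking" in cfg.stages:
                stage = f"self_blocking[{job.name}]"
                measurements += run_blocking_stage(job, cfg, hierarchy, s_self, SELF_CONDITIONS)
            if "cross_blocking" in cfg.stages:
                stage = f"cross_blocking[{job.name}]"
                cross_conditions = [
                    BlockingCondition(b, 600, "RT", 2.0)
                    for b in job.blockers
                    if b != "aSyn_monomer"
                ]
                measurements += run_blocking_stage(job, cfg, hierarchy, s_cross, cross_conditions)
            if measurements:
                profile = summarize_blocking_panel([m for m, _ in measurements], job.name)
                profiles[job.name] = profile
                profile.to_frame().to_csv(outdir / f"blocking_{job.name}.csv", index=False)
                entry["blocking"] = {
                    "efficiencies": {
                        b: profile.mean_efficiency(b) for b in profile.blockers()
                    },
                    "true_kappa": {m.condition.blocker: k for m, k in measurements},
                }

            if "expression" in cfg.stages and job.expression_si:
                stage = f"expression[{job.name}]"
                res = run_expression_stage(job, cfg, hierarchy, s_expr)
                entry["expression"] = res
            report["antibodies"][job.name] = entry

        if profiles:
            stage = "assessment"
            assessments = []
            for job in cfg.antibodies:
                if job.name not in profiles:
                    continue
                si_map = report["antibodies"][job.name].get("expression", {}).get("si")
                assessments.append(
                    assess_antibody(
                        profiles[job.name],
                        si_map,
                        cfg.self_threshold,
                        cfg.cross_threshold,
                        cfg.detect_threshold,
                        cfg.floor,
                    )
                )
            ranked = rank_antibodies(assessments)
            report["ranking"] = [a.antibody for a in ranked]
            report["assessments"] = {
                a.antibody: {
                    "specific": a.specific,
                    "cross_reactive_with": sorted(a.cross_reactive_with),
                    "mean_self_blocking": a.mean_self_blocking,
                }
                for a in ranked
            }
            log.info("ranking: %s", report["ranking"])

        if "physiological" in cfg.stages:
            stage = "physiological"
            report["physiological"] = run_physiological_stage(
                cfg, hierarchy, _child_seed(ab_seeds[-1])
            )
    except CytovalError as exc:
        log.error("stage %s failed: %s", stage, exc)
        _write_report(report, outdir)
        log.removeHandler(handler)
        handler.close()
        raise ConfigError(f"stage {stage} failed: {exc}") from exc

    _write_report(report, outdir)
    log.removeHandler(handler)
    handler.close()
    return report


def _write_report(report: dict, outdir: Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_default)
    )


def ranking_replication(seed: int, n_events: int = 20_000) -> list[str]:
    """One seeded replication of the three-clone specificity ranking.

    Generates the full blocking panel (two self-blocking conditions plus
    three related-protein blockers) for each emulated clone from its
    ground-truth κ table, runs gating + blocking measurement + assessment,
    and returns the resulting ranking.
    """
    from .synthetic import PAPER_BLOCKING_TRUTHS, generate_blocking_experiment

    hierarchy = scatter_hierarchy(7.0e4, 1.0e9)
    ss = np.random.SeedSequence(seed)
    assessments = []
    conditions = list(SELF_CONDITIONS) + [
        BlockingCondition(b, 600, "RT", 2.0) for b in ("bSyn", "gSyn", "tubulin")
    ]
    for ab, child in zip(sorted(PAPER_BLOCKING_TRUTHS), ss.spawn(len(PAPER_BLOCKING_TRUTHS))):
        truth = PAPER_BLOCKING_TRUTHS[ab]
        measurements = []
        for cond, cseed in zip(conditions, child.spawn(len(conditions))):
            tables, _ = generate_blocking_experiment(
                truth, cond, _child_seed(cseed), n_events=n_events, antibody=ab
            )
            gated = {label: gate_table(t, hierarchy) for label, t in tables.items()}
            measurements.append(
                measure_blocking(
                    gated["stained"],
                    gated[f"blocked:{cond.blocker}"],
                    gated["no-stain"],
                    FLUOR_CHANNEL,
                    cond,
                    cell_type="hiPSC",
                )
            )
        assessments.append(assess_antibody(summarize_blocking_panel(measurements, ab)))
    return [a.antibody for a in rank_antibodies(assessments)]
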