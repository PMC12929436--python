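"""End-to-end orchestration: simulate -> fit -> contrasts -> qpcr -> energy.

``run_pipeline`` executes the enabled stages in order from a single
``RunConfig`` (YAML-loadable), writes per-stage CSV/JSON artifacts plus a
consolidated ``report.md``, and is byte-reproducible for a given config and
seed (no timestamps in any output).  A stage failure is recorded with
context and downstream stages that depend on it are skipped; the result's
``ok`` flag is False iff any stage errored.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import io as ptio
from .contrasts import contrasts_frame, photoperiod_contrasts
from .energy import EnergyScenario, energy_report
from .model import (
    FLAT,
    FULL,
    FitConfig,
    VARIANTS,
    Classification,
    ModelFit,
    classify_response,
    compare_variants,
    recommend_photoperiod,
    select_best_per_genotype,
)
from .qpcr import compare_expression, relative_expression
from .synth import (
    DesignSpec,
    default_ct_effects,
    default_design,
    generate_ct_table,
    generate_phenotypes,
)
from .types import CANONICAL_GENOTYPES, ValidationError

__all__ = ["RunConfig", "StageResult", "PipelineResult", "run_pipeline"]

STAGES = ("simulate", "fit", "contrasts", "qpcr", "energy")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 42
    outdir: str = "photothermal_out"
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # simulate
    phenotypes_path: Optional[str] = None  # load instead of simulating
    replicates: int = 5
    repetitions: int = 2
    photoperiods_h: Sequence[float] = (16.0, 18.0, 20.0, 22.0, 24.0)
    repetition_shift: float = 0.0
    # fit
    variants: Sequence[str] = ("full", "flat")
    criterion: str = "bic"
    near_zero_band: float = 2.0
    conservative_default_h: float = 22.0
    # contrasts
    contrast_pairs: Sequence[Tuple[float, float]] = ((16.0, 20.0), (20.0, 22.0))
    alpha: float = 0.05
    # qpcr
    ct_path: Optional[str] = None
    reference_gene: str = "HvTubA"
    # energy
    baseline_photoperiod_h: float = 22.0
    tariff_per_kwh: float = 0.22
    facility_area_sqft: Optional[float] = 10000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.contrast_pairs, (list, tuple)):
            cfg.contrast_pairs = [tuple(p) for p in cfg.contrast_pairs]
        missing = set(cfg.stages) - set(STAGES)
        if missing:
            raise ValidationError(f"unknown stages: {sorted(missing)}")
        for s in STAGES:
            cfg.stages.setdefault(s, True)
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": dict(self.stages),
            "phenotypes_path": self.phenotypes_path,
            "replicates": self.replicates,
            "repetitions": self.repetitions,
            "photoperiods_h": list(self.photoperiods_h),
            "repetition_shift": self.repetition_shift,
            "variants": list(self.variants),
            "criterion": self.criterion,
            "near_zero_band": self.near_zero_band,
            "conservative_default_h": self.conservative_default_h,
            "contrast_pairs": [list(p) for p in self.contrast_pairs],
            "alpha": self.alpha,
            "ct_path": self.ct_path,
            "reference_gene": self.reference_gene,
            "baseline_photoperiod_h": self.baseline_photoperiod_h,
            "tariff_per_kwh": self.tariff_per_kwh,
            "facility_area_sqft": self.facility_area_sqft,
        }


@dataclass
class StageResult:
    name: str
    status: str  # "ok" | "failed" | "skipped" | "disabled"
    detail: str = ""
    artifacts: List[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    outdir: Path
    stages: List[StageResult]
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.stages)

    def stage(self, name: str) -> StageResult:
        return next(s for s in self.stages if s.name == name)


def _fit_stage(records, cfg: RunConfig, outdir: Path, warnings: List[str]):
    fit_cfg = FitConfig(criterion=cfg.criterion)
    variants = [VARIANTS[name] for name in cfg.variants]
    comparison = compare_variants(records, variants, fit_cfg)
    for name, err in comparison.errors.items():
        warnings.append(f"fit: variant {name!r} failed: {err}")

    # per-genotype selection drives classification and recommendation
    per_geno = select_best_per_genotype(records, (FULL, FLAT), fit_cfg)
    photoperiods = sorted({r.photoperiod_h for r in records})
    tested_range = (photoperiods[0], photoperiods[-1])
    classifications: Dict[str, Classification] = {}
    for geno, best in per_geno.items():
        classifications.update(
            classify_response(best, tested_range, cfg.near_zero_band)
        )
    recommendations = {
        geno: recommend_photoperiod(
            geno, classifications, per_geno, photoperiods,
            cfg.conservative_default_h,
        )
        for geno in per_geno
    }
    for rec in recommendations.values():
        if rec.warning:
            warnings.append(f"fit: {rec.genotype}: {rec.warning}")

    payload = {
        "tested_range_h": list(tested_range),
        "variant_comparison": [f.to_dict() for f in comparison.ranked],
        "variant_errors": comparison.errors,
        "per_genotype": {
            geno: {
                "selected_variant": best.variant.name,
                "fit": best.to_dict(),
                "classification": classifications[geno].category.value,
                "classification_note": classifications[geno].note,
                "recommended_photoperiod_h": recommendations[geno].photoperiod_h,
                "recommendation_provenance": recommendations[geno].provenance,
                "recommendation_warning": recommendations[geno].warning,
            }
            for geno, best in per_geno.items()
        },
    }
    (outdir / "fit.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    curves = comparison.best.curve_frame(p_min=0.0, p_max=24.0, step=0.1)
    curves.to_csv(outdir / "fitted_curves.csv", index=False,
                  lineterminator="\n")
    return comparison, per_geno, classifications, recommendations


def _energy_stage(cfg: RunConfig, recommendations, outdir: Path):
    reduced_set = sorted({
        rec.photoperiod_h for rec in recommendations.values()
        if rec.photoperiod_h < cfg.baseline_photoperiod_h
    }) if recommendations else []
    if not reduced_set:
        reduced_set = [16.0, 20.0]
    reports = []
    for reduced in reduced_set:
        scenario = EnergyScenario(
            reduced_photoperiod_h=reduced,
            baseline_photoperiod_h=cfg.baseline_photoperiod_h,
            tariff_per_kwh=cfg.tariff_per_kwh,
            facility_area_sqft=cfg.facility_area_sqft,
        )
        reports.append(energy_report(scenario))
    payload = {"scenarios": reports}
    (outdir / "energy.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    return reports


def _df_md(df) -> str:
    """Render a DataFrame as a GitHub pipe table (no extra dependency)."""
    cols = [str(c) for c in df.columns]
    fmt = lambda v: f"{v:.4g}" if isinstance(v, float) else str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def _report_md(cfg, results, fit_bundle, contrast_df, expr_df, expr_omitted,
               energy_reports, warnings) -> str:
    lines = ["# Photothermal pipeline report", ""]
    cfg_echo = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    lines += ["## Configuration", "", "```json",
              json.dumps(cfg_echo, indent=2, sort_keys=True), "```", ""]
    if fit_bundle is not None:
        _, per_geno, classifications, recommendations = fit_bundle
        lines += [
            "## Photoperiod response parameters",
            "",
            "| genotype | variant | I (°Cd) | S (°Cd/h) | T (h) | sigma (°Cd)"
            " | class | recommended P (h) |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for geno in sorted(per_geno):
            best = per_geno[geno]
            e = best.estimates[geno].params
            t_txt = (f"{e.threshold:.2f}"
                     if best.estimates[geno].threshold_identifiable
                     else "n.i.")
            lines.append(
                f"| {geno} | {best.variant.name} | {e.intrinsic_earliness:.1f}"
                f" | {e.sensitivity:.2f} | {t_txt} | {e.sigma:.1f} | "
                f"{classifications[geno].category.value} | "
                f"{recommendations[geno].photoperiod_h:g} |"
            )
        lines.append("")
    if contrast_df is not None and not contrast_df.empty:
        lines += ["## Photoperiod contrasts", "", _df_md(contrast_df), ""]
    if expr_df is not None:
        lines += ["## Expression comparisons", ""]
        if expr_omitted:
            lines += [f"Omitted expression cells: {len(expr_omitted)} "
                      "(undetected target or reference)", ""]
        if not expr_df.empty:
            lines += [_df_md(expr_df), ""]
    if energy_reports:
        lines += ["## Energy ledger", ""]
        for rep in energy_reports:
            sc = rep["scenario"]
            cost = rep.get("facility_cost_saving_reported_nearest_1000")
            cost_txt = (f"; facility saving {sc['currency']}{cost:,.0f}/yr "
                        "(nearest 1,000)" if cost is not None else "")
            lines.append(
                f"- {sc['baseline_photoperiod_h']:g} h -> "
                f"{sc['reduced_photoperiod_h']:g} h: "
                f"{rep['fractional_saving_pct']}% of daily lighting, "
                f"{rep['annual_fixture_saving_kwh_reported']:g} kWh/yr per "
                f"fixture{cost_txt}"
            )
        lines.append("")
    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    lines += ["## Stage status", ""]
    lines += [f"- {s.name}: {s.status}"
              + (f" ({s.detail})" if s.detail else "") for s in results]
    lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: List[StageResult] = []
    warnings: List[str] = []
    records = None
    fit_bundle = None
    contrast_df = None
    expr_df = None
    expr_omitted: List[str] = []
    energy_reports = None

    # --- simulate / load -------------------------------------------------
    if cfg.stages.get("simulate", True) or cfg.phenotypes_path:
        try:
            if cfg.phenotypes_path:
                records = ptio.read_phenotypes(cfg.phenotypes_path)
                genotypes = ptio.read_genotype_specs(cfg.phenotypes_path)
                detail = f"loaded {len(records)} records"
            else:
                design = default_design(
                    seed=cfg.seed,
                    replicates=cfg.replicates,
                    repetitions=cfg.repetitions,
                    photoperiods_h=tuple(cfg.photoperiods_h),
                    repetition_shift=cfg.repetition_shift,
                )
                records = generate_phenotypes(design)
                genotypes = CANONICAL_GENOTYPES
                detail = f"simulated {len(records)} records"
            ptio.write_phenotypes(outdir / "phenotypes.csv", records, genotypes)
            results.append(StageResult("simulate", "ok", detail,
                                       ["phenotypes.csv"]))
        except Exception as exc:  # noqa: BLE001 — stage boundary
            results.append(StageResult("simulate", "failed",
                                       f"{exc}\n{traceback.format_exc()}"))
    else:
        results.append(StageResult("simulate", "disabled"))

    # --- fit --------------------------------------------------------------
    if not cfg.stages.get("fit", True):
        results.append(StageResult("fit", "disabled"))
    elif records is None:
        results.append(StageResult("fit", "skipped", "no phenotype records"))
    else:
        try:
            fit_bundle = _fit_stage(records, cfg, outdir, warnings)
            results.append(StageResult(
                "fit", "ok",
                f"best variant: {fit_bundle[0].best.variant.name}",
                ["fit.json", "fitted_curves.csv"],
            ))
        except Exception as exc:  # noqa: BLE001
            results.append(StageResult("fit", "failed",
                                       f"{exc}\n{traceback.format_exc()}"))

    # --- contrasts ----------------------------------------------------------
    if not cfg.stages.get("contrasts", True):
        results.append(StageResult("contrasts", "disabled"))
    elif records is None:
        results.append(StageResult("contrasts", "skipped",
                                   "no phenotype records"))
    else:
        try:
            cres = photoperiod_contrasts(records, cfg.contrast_pairs,
                                         cfg.alpha)
            contrast_df = contrasts_frame(cres)
            contrast_df.to_csv(outdir / "contrasts.csv", index=False,
                               lineterminator="\n")
            skipped = [c for c in cres if c.skipped]
            for c in skipped:
                warnings.append(
                    f"contrasts: {c.genotype} {c.pair}: {c.reason}")
            results.append(StageResult("contrasts", "ok",
                                       f"{len(cres)} contrasts",
                                       ["contrasts.csv"]))
        except Exception as exc:  # noqa: BLE001
            results.append(StageResult("contrasts", "failed",
                                       f"{exc}\n{traceback.format_exc()}"))

    # --- qpcr ---------------------------------------------------------------
    if not cfg.stages.get("qpcr", True):
        results.append(StageResult("qpcr", "disabled"))
    else:
        try:
            if cfg.ct_path:
                ct_records = ptio.read_ct(cfg.ct_path)
            else:
                genes, ct_genos, ct_pps, effects = default_ct_effects()
                ct_records = generate_ct_table(
                    genes, ct_genos, ct_pps, effects, seed=cfg.seed,
                )
            ptio.write_ct(outdir / "ct.csv", ct_records)
            values, expr_omitted = relative_expression(
                ct_records, cfg.reference_gene)
            for line in expr_omitted:
                warnings.append(f"qpcr: omitted {line}")
            genos = sorted({v.genotype for v in values})
            pairs = [(a, b) for i, a in enumerate(genos)
                     for b in genos[i + 1:]]
            expr_df = compare_expression(values, pairs, cfg.alpha)
            expr_rows = [
                {
                    "gene": v.gene, "genotype": v.genotype,
                    "photoperiod_h": v.photoperiod_h, "zt": v.zt,
                    "bio_rep": v.bio_rep, "rel_expr": v.rel_expr,
                    "delta_ct": v.delta_ct,
                }
                for v in values
            ]
            import pandas as pd  # local alias for the frame build
            pd.DataFrame(expr_rows).to_csv(
                outdir / "expression.csv", index=False, lineterminator="\n")
            expr_df.to_csv(outdir / "expression_tests.csv", index=False,
                           lineterminator="\n")
            n_untestable = int(expr_df["untestable"].sum()) if not expr_df.empty else 0
            if n_untestable:
                warnings.append(
                    f"qpcr: {n_untestable} comparison cells untestable "
                    "(fewer than 2 detected bio reps in a group)")
            results.append(StageResult(
                "qpcr", "ok",
                f"{len(values)} expression values, "
                f"{len(expr_df)} comparisons",
                ["ct.csv", "expression.csv", "expression_tests.csv"],
            ))
        except Exception as exc:  # noqa: BLE001
            results.append(StageResult("qpcr", "failed",
                                       f"{exc}\n{traceback.format_exc()}"))

    # --- energy -------------------------------------------------------------
    if not cfg.stages.get("energy", True):
        results.append(StageResult("energy", "disabled"))
    else:
        try:
            recommendations = fit_bundle[3] if fit_bundle else {}
            energy_reports = _energy_stage(cfg, recommendations, outdir)
            results.append(StageResult("energy", "ok",
                                       f"{len(energy_reports)} scenarios",
                                       ["energy.json"]))
        except Exception as exc:  # noqa: BLE001
            results.append(StageResult("energy", "failed",
                                       f"{exc}\n{traceback.format_exc()}"))

    report = _report_md(cfg, results, fit_bundle, contrast_df, expr_df,
                        expr_omitted, energy_reports, warnings)
    (outdir / "report.md").write_text(report, encoding="utf-8")
    return PipelineResult(outdir=outdir, stages=results, warnings=warnings)
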