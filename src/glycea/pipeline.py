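"""End-to-end pipeline: configuration -> cohort -> metrics -> costs ->
group statistics -> CEA -> PSA -> report tables and a JSON manifest.

The manifest is deterministic for a given configuration and seed (no
timestamps or machine state), so two identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from glycea import defaults
from glycea.cea import CostEffectivenessModel
from glycea.cohort import CohortSpec, cohort_to_frame, generate_cohort, generate_cost_items
from glycea.costing import (
    TariffCatalog, cost_items_to_frame, cost_records_to_frame,
    arm_cost_summary, default_catalog, patient_total_cost,
)
from glycea.group_stats import compare_groups, iptw_adjust, subgroup_table
from glycea.metrics import zone_grid_counts
from glycea.psa import PsaConfig, export_ce_plane, run_psa

logger = logging.getLogger("glycea")

STAGES = ("simulate", "metrics", "cost", "stats", "cea", "psa", "report")


@dataclass
class RunConfig:
    """Pipeline configuration (loadable from YAML or JSON)."""

    out_dir: str = "glycea_out"
    seed: int = 0
    cohort_csv: Optional[str] = None        # load instead of simulating
    cohort_spec: dict = field(default_factory=dict)  # CohortSpec overrides
    catalog_path: Optional[str] = None      # default placeholder catalog if None
    timepoints: Tuple[str, str] = ("M0", "M12")
    psa_n_sims: int = 10_000
    psa_uncertainty_scale: str = "sd"
    iptw_covariates: Tuple[str, ...] = ("age", "bmi",)
    run_iptw: bool = True
    run_psa: bool = True

    def __post_init__(self):
        if self.cohort_csv is None and self.cohort_spec is None:
            raise ValueError("either cohort_csv or cohort_spec must be provided")
        if self.seed is None and (self.run_psa or self.cohort_csv is None):
            raise ValueError("a seed is required when stochastic stages run")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        p = str(path)
        with open(path) as fh:
            if p.endswith((".yaml", ".yml")):
                import yaml
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        d = d or {}
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if "iptw_covariates" in d:
            d["iptw_covariates"] = tuple(d["iptw_covariates"])
        return cls(**d)

    def spec(self) -> CohortSpec:
        overrides = dict(self.cohort_spec)
        overrides.setdefault("seed", self.seed)
        return CohortSpec.from_dict(overrides)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, stages: Optional[List[str]] = None) -> dict:
    """Execute the pipeline and write report outputs; returns the manifest.

    ``stages`` restricts execution to a prefix of the stage order (later
    stages depend on earlier ones and are pulled in automatically by
    requesting them).  On failure, files written in this run are removed
    and a :class:`StageError` names the failing stage.
    """
    wanted = set(stages or STAGES)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    manifest: dict = {"seed": config.seed, "stages": sorted(wanted)}
    ctx: dict = {}

    def emit_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        manifest.setdefault("outputs", []).append(name)

    def run_stage(name, fn):
        if name not in wanted:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:
            for p in written:
                p.unlink(missing_ok=True)
            raise StageError(name, e) from e
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    def _need_cohort():
        if "cohort" in ctx:
            return
        if config.cohort_csv:
            ctx["cohort"] = pd.read_csv(config.cohort_csv)
        else:
            ctx["spec"] = config.spec()
            ctx["cohort"] = cohort_to_frame(generate_cohort(ctx["spec"]))

    def st_simulate():
        _need_cohort()
        emit_csv("cohort.csv", ctx["cohort"])

    def st_metrics():
        _need_cohort()
        cohort = ctx["cohort"]
        grids = []
        for arm in cohort["arm"].unique():
            for tp in config.timepoints:
                g = zone_grid_counts(cohort[cohort["arm"] == arm], tp)
                grids.append({"arm": arm, "timepoint": tp, "n": g["n"],
                              **{f"zone_{z}": c for z, c in g["counts"].items()},
                              "cde_count": g["cde_count"],
                              "cde_fraction": g["cde_fraction"]})
        df = pd.DataFrame(grids)
        ctx["zone_grid"] = df
        emit_csv("zone_grid.csv", df)
        manifest["zone_grid"] = df.to_dict(orient="records")

    def st_cost():
        _need_cohort()
        spec = ctx.get("spec") or config.spec()
        catalog = (TariffCatalog.from_file(config.catalog_path)
                   if config.catalog_path else default_catalog())
        cohort = ctx["cohort"]
        arm_of = dict(cohort.drop_duplicates("patient_id")[
            ["patient_id", "arm"]].itertuples(index=False))
        items, records = [], []
        for arm in (spec.intervention_label, spec.comparator_label):
            arm_items = generate_cost_items(arm, catalog, spec, config.seed)
            items.extend(arm_items)
            per_pat: Dict[str, list] = {}
            for it in arm_items:
                per_pat.setdefault(it.patient_id, []).append(it)
            for pid, its in per_pat.items():
                records.append(patient_total_cost(
                    its, catalog, arm=arm_of.get(pid, arm), patient_id=pid))
        ctx["cost_records"] = records
        costs_df = cost_records_to_frame(records)
        ctx["costs"] = costs_df
        emit_csv("cost_items.csv", cost_items_to_frame(items))
        emit_csv("patient_costs.csv", costs_df)
        summary_rows = []
        for arm in (spec.intervention_label, spec.comparator_label):
            n, mean, sd, total = arm_cost_summary(records, arm)
            summary_rows.append({"arm": arm, "n": n, "mean_eur": mean,
                                 "sd_eur": sd, "total_eur": total})
        df = pd.DataFrame(summary_rows)
        emit_csv("cost_summary.csv", df)
        manifest["cost_summary"] = df.to_dict(orient="records")

    def st_stats():
        _need_cohort()
        spec = ctx.get("spec") or config.spec()
        cohort = ctx["cohort"]
        arms = (spec.intervention_label, spec.comparator_label)
        tables = []
        for metric in ("tir", "gri"):
            for tp in config.timepoints:
                tables.append(subgroup_table(cohort, metric, tp, *arms))
        df = pd.concat(tables, ignore_index=True)
        emit_csv("outcome_tables.csv", df)
        # baseline characteristics comparison (Table-1 analog)
        base = cohort[cohort["timepoint"] == config.timepoints[0]]
        rows = []
        for col in ("age", "bmi", "tir", "gri"):
            x = base[base["arm"] == arms[0]][col]
            y = base[base["arm"] == arms[1]][col]
            r = compare_groups(x, y)
            rows.append({"parameter": col,
                         f"mean_{arms[0]}": r.mean_x, f"sd_{arms[0]}": r.sd_x,
                         f"mean_{arms[1]}": r.mean_y, f"sd_{arms[1]}": r.sd_y,
                         "pvalue": r.pvalue, "test": r.test_name})
        emit_csv("baseline_table.csv", pd.DataFrame(rows))
        if config.run_iptw:
            merged = ctx.get("costs")
            cohort_iptw = cohort
            outcomes = ["tir", "gri"]
            if merged is not None:
                cohort_iptw = cohort.merge(
                    merged[["patient_id", "total_eur"]], on="patient_id")
                cohort_iptw = cohort_iptw.rename(columns={"total_eur": "cost"})
                outcomes.append("cost")
            covs = [c for c in config.iptw_covariates if c in cohort_iptw.columns]
            res = iptw_adjust(cohort_iptw, covs, outcomes=outcomes,
                              timepoint=config.timepoints[-1],
                              intervention=spec.intervention_label)
            manifest["iptw"] = {
                "smd_unweighted": res.smd_unweighted,
                "smd_weighted": res.smd_weighted,
                "weighted_summaries": res.weighted_summaries.to_dict(orient="records"),
            }
            emit_csv("iptw_summaries.csv", res.weighted_summaries)

    def st_cea():
        _need_cohort()
        spec = ctx.get("spec") or config.spec()
        if "costs" not in ctx:
            st_cost()
        model = CostEffectivenessModel.from_dataframe(
            ctx["cohort"], ctx["costs"],
            spec.intervention_label, spec.comparator_label,
            timepoint=config.timepoints[-1])
        ctx["model"] = model
        res = model.fit()
        ctx["cea"] = res
        manifest["cea"] = res.to_dict()
        emit_csv("cea_table.csv", res.to_frame())

    def st_psa():
        if "model" not in ctx:
            st_cea()
        psa_cfg = PsaConfig(n_sims=config.psa_n_sims,
                            uncertainty_scale=config.psa_uncertainty_scale,
                            seed=config.seed)
        res = run_psa(ctx["model"].intervention, ctx["model"].comparator, psa_cfg)
        ctx["psa"] = res
        manifest["psa"] = res.to_summary_dict()
        emit_csv("ce_plane.csv", export_ce_plane(res))

    def st_report():
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)

    run_stage("simulate", st_simulate)
    run_stage("metrics", st_metrics)
    run_stage("cost", st_cost)
    run_stage("stats", st_stats)
    run_stage("cea", st_cea)
    if config.run_psa:
        run_stage("psa", st_psa)
    run_stage("report", st_report)
    return manifest
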