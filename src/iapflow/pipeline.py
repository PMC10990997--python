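"""Pipeline stages: quantify (files → flow table) and analyze (flow table → report).

File dialects (CSV, comma-separated, UTF-8, header row mandatory):

* arterial: ``animal_id,time_s,conc_nci_ml`` — or ``animal_id,time_s,cpm``
  with optional ``efficiency`` / ``quench_index`` columns, converted via
  the quench configuration;
* standards: ``standard_id,activity_nci_g,od``;
* ROI: ``animal_id,region,od`` (long format, ≥ 8 rows per animal-region);
* animals: ``animal_id,strain,treatment`` (attaches group labels);
* flows (quantify output): one row per animal × region with QC columns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import calibration as cal
from . import study_stats as st
from .config import PipelineConfig
from .errors import NonIdentifiableError, ValidationError
from .kinetics import REGIONS, ArterialCurve, KineticParams, invert_flow
from .synthetic import STRAINS, TREATMENTS, standards_from_table

__all__ = [
    "kinetic_params",
    "arterial_curves",
    "quantify",
    "analyze",
    "write_report",
]

logger = logging.getLogger(__name__)


def kinetic_params(config: PipelineConfig) -> KineticParams:
    k = config.kinetics
    return KineticParams(partition_coefficient=k.partition_coefficient, m=k.m,
                         decapitation_time_s=k.decap_time_s)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{what} table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{what} table is empty")


def arterial_curves(
    arterial: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> dict[str, ArterialCurve]:
    """Arterial input function per animal, from concentrations or raw counts."""
    config = config or PipelineConfig()
    _require_columns(arterial, ["animal_id", "time_s"], "arterial")
    if "conc_nci_ml" not in arterial.columns and "cpm" not in arterial.columns:
        raise ValidationError("arterial table needs a conc_nci_ml or cpm column")
    curves: dict[str, ArterialCurve] = {}
    quench = (config.quench.a, config.quench.b)
    for animal_id, sub in arterial.groupby("animal_id", sort=True):
        sub = sub.sort_values("time_s")
        if "conc_nci_ml" in sub.columns:
            conc = sub.conc_nci_ml.to_numpy(float)
        else:
            conc = np.array([
                cal.counts_to_concentration(
                    cal.BloodSampleCounts(
                        animal_id=str(animal_id),
                        time_s=float(row.time_s),
                        cpm=float(row.cpm),
                        efficiency=(float(row.efficiency)
                                    if "efficiency" in sub.columns
                                    and np.isfinite(row.efficiency) else None),
                        quench_index=(float(row.quench_index)
                                      if "quench_index" in sub.columns else None),
                    ),
                    quench_coefficients=quench,
                )
                for row in sub.itertuples()
            ])
        curves[str(animal_id)] = ArterialCurve(sub.time_s.to_numpy(float), conc)
    return curves


def quantify(
    arterial: pd.DataFrame,
    standards: pd.DataFrame,
    roi: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    animals: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One blood-flow value per animal × region, with QC columns.

    Calibrates each region's density readings, inverts the kinetic model
    against the animal's arterial curve, and returns a tidy table.  A
    saturated tissue concentration flags its row ``non_identifiable``
    (flow NaN) and the pipeline continues; a missing arterial curve for
    any ROI animal aborts with a validation error naming the animals.
    """
    config = config or PipelineConfig()
    _require_columns(standards, ["activity_nci_g", "od"], "standards")
    _require_columns(roi, ["animal_id", "region", "od"], "roi")
    curves = arterial_curves(arterial, config)
    missing = sorted(set(roi.animal_id.astype(str)) - set(curves))
    if missing:
        raise ValidationError(f"no arterial curve for animals: {missing}")

    curve_fit = cal.fit_calibration(
        standards_from_table(standards),
        mode=config.calibration.mode,
        extrapolation=config.calibration.extrapolation,
    )
    params = kinetic_params(config)
    logger.info("quantify: calibration mode=%s, lambda=%s, m=%s, T=%ss",
                config.calibration.mode, params.partition_coefficient,
                params.m, params.decapitation_time_s)

    rows = []
    for (animal_id, region), sub in roi.groupby(["animal_id", "region"], sort=True):
        densities = cal.RegionDensitySet(region=str(region),
                                         readings=sub.od.to_numpy(float))
        activity = cal.region_activity(densities, curve_fit,
                                       min_readings=config.calibration.min_readings)
        row = {
            "animal_id": str(animal_id),
            "region": str(region),
            "ci_nci_g": activity.activity,
            "ci_sd_nci_g": activity.sd,
            "n_readings": activity.n,
            "calibration_mode": config.calibration.mode,
        }
        try:
            inv = invert_flow(activity.activity, curves[str(animal_id)], params,
                              full_output=True)
            row.update(flow_ml_g_min=inv.flow_ml_g_min, iterations=inv.iterations,
                       residual=inv.residual, flag="ok")
        except NonIdentifiableError as exc:
            logger.warning("animal %s region %s: %s", animal_id, region, exc)
            row.update(flow_ml_g_min=np.nan, iterations=0, residual=np.nan,
                       flag="non_identifiable")
        rows.append(row)
    flows = pd.DataFrame(rows)
    if animals is not None:
        _require_columns(animals, ["animal_id", "strain", "treatment"], "animals")
        flows = flows.merge(animals.astype({"animal_id": str}), on="animal_id",
                            how="left")
    return flows


def _effects_dict(result: st.GroupComparisonResult) -> list[dict]:
    return [{"name": e.name, "F": e.F, "df_num": e.df_num, "df_den": e.df_den,
             "p": e.p} for e in result.effects]


def _tukey_records(result: st.GroupComparisonResult) -> list[dict]:
    if result.tukey is None:
        return []
    out = result.tukey.copy()
    out["significant"] = out.significant.astype(bool)
    return out.to_dict(orient="records")


def analyze(
    flows: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    blots: Optional[pd.DataFrame] = None,
) -> dict:
    """Group summaries, per-region 2×2 ANOVA + Tukey, percent differences.

    Expects the tidy flow table from :func:`quantify` with ``strain`` and
    ``treatment`` columns attached.  Returns a JSON-serializable report;
    an input containing a single group yields summaries only, with a
    warning recorded in the report.
    """
    config = config or PipelineConfig()
    _require_columns(flows, ["animal_id", "region", "flow_ml_g_min"], "flows")
    bad_regions = sorted(set(flows.region) - set(REGIONS))
    if bad_regions:
        raise ValidationError(f"unknown regions: {bad_regions}")
    have_groups = {"strain", "treatment"} <= set(flows.columns)
    if have_groups:
        bad = sorted(set(flows.strain) - set(STRAINS))
        if bad:
            raise ValidationError(f"unknown strains: {bad}")
        bad = sorted(set(flows.treatment) - set(TREATMENTS))
        if bad:
            raise ValidationError(f"unknown treatments: {bad}")

    report: dict = {
        "alpha": config.stats.alpha,
        "layout": config.stats.layout,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "warnings": [],
        "regions": {},
    }
    usable = flows[flows.flow_ml_g_min.notna()]
    n_dropped = len(flows) - len(usable)
    if n_dropped:
        report["warnings"].append(
            f"{n_dropped} non-identifiable rows excluded from statistics")

    if not have_groups or usable.groupby(["strain", "treatment"]).ngroups < 2:
        report["warnings"].append(
            "single study group: summaries only, ANOVA skipped")
        for region, sub in usable.groupby("region"):
            summaries = st.summarize({"all": sub.flow_ml_g_min.to_numpy(float)},
                                     units="ml/g/min")
            report["regions"][region] = {
                "summaries": [vars(s) for s in summaries]}
        return report

    for region in [r for r in REGIONS if r in set(usable.region)]:
        sub = usable[usable.region == region]
        groups = {
            f"{s}:{t}": g.flow_ml_g_min.to_numpy(float)
            for (s, t), g in sub.groupby(["strain", "treatment"])
        }
        entry: dict = {
            "summaries": [dict(vars(s), units="ml/g/min")
                          for s in st.summarize(groups)],
        }
        try:
            result = st.two_way_anova_tukey(sub, "flow_ml_g_min",
                                            alpha=config.stats.alpha)
            entry["anova"] = _effects_dict(result)
            entry["tukey"] = _tukey_records(result)
            entry["anova_warnings"] = result.warnings
        except ValidationError as exc:
            entry["anova"] = []
            entry["tukey"] = []
            report["warnings"].append(f"{region}: ANOVA skipped ({exc})")
        means = {name: float(np.mean(v)) for name, v in groups.items()}
        pct = {}
        for label, ref, comp in (
            ("mutant_vehicle_vs_control_vehicle", "control:vehicle", "mutant:vehicle"),
            ("mutant_inhibitor_vs_mutant_vehicle", "mutant:vehicle", "mutant:inhibitor"),
            ("control_inhibitor_vs_control_vehicle", "control:vehicle",
             "control:inhibitor"),
        ):
            if ref in means and comp in means:
                pct[label] = st.percent_difference(means[ref], means[comp])
        entry["percent_difference"] = pct
        report["regions"][region] = entry

    if config.stats.layout == "group_by_region":
        work = usable.copy()
        work["group"] = work.strain + ":" + work.treatment
        result = st.two_way_anova_tukey(work, "flow_ml_g_min",
                                        alpha=config.stats.alpha,
                                        factors=("group", "region"))
        report["group_by_region"] = {
            "anova": _effects_dict(result),
            "tukey": _tukey_records(result),
        }

    if blots is not None:
        per_marker = st.blot_normalize_and_test(blots, alpha=config.stats.alpha)
        report["blots"] = {
            marker: {
                "anova": _effects_dict(res),
                "tukey": _tukey_records(res),
                "summaries": [dict(vars(s), units="ratio")
                              for s in res.summaries],
            }
            for marker, res in per_marker.items()
        }
    return report


def write_report(report: dict, outdir) -> tuple[Path, Path]:
    """Write the JSON report and a TSV of the mean ± SEM summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = []
    for region, entry in report.get("regions", {}).items():
        for s in entry.get("summaries", []):
            rows.append({"region": region, **s})
    tsv_path = outdir / "summaries.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    return json_path, tsv_path
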