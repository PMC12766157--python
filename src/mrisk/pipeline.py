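"""End-to-end orchestration: eligibility → life tables → cure fits → risk.

One call runs the three-step workflow on a case listing and a rate table,
writes every intermediate and final table as CSV, and records a manifest
with the configuration hash, input digests, per-stage timings and every
warning (non-convergence, boundary cure fractions, deconvolution
residuals).  Estimation itself is deterministic; the seed matters only to
the cohort simulator.

Strata are stages; age group and period of diagnosis can enter the cure
model as categorical covariates (one life table per covariate pattern).
Stage-IV survival — smoothed by its own cure-model fit, which is what
allows extrapolation to the 15-year horizon — supplies the post-recurrence
curve via the power transform with r.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .cure_model import (CureModelFit, CureModelSpec, fit_mixture_cure,
                         fit_summary_frame, predict_rs, select_family, su)
from .io_formats import (CaseRecord, PopulationRateTable, RunConfig,
                         age_band_label, period_label)
from .recurrence_risk import (RESIDUAL_FLAG_THRESHOLD, build_t2_survival,
                              conditional_risk_table, deconvolve_t1,
                              format_percent, mr_risk_curve,
                              sensitivity_over_r)
from .relative_survival import GroupedLifeTable, build_lifetable

logger = logging.getLogger("mrisk")

__version__ = "0.1.0"


@dataclass
class StratumStatus:
    stratum: str
    status: str          # ok | fallback-weibull | skipped
    note: str = ""


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config_hash: str
    input_digests: dict[str, str]
    seed: int
    version: str = __version__
    family_used: str = ""
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    strata: list[StratumStatus] = field(default_factory=list)
    failure: str | None = None

    @property
    def all_ok(self) -> bool:
        return self.failure is None and all(
            s.status == "ok" for s in self.strata)

    def write(self, path: Path) -> None:
        payload = asdict(self)
        payload["all_ok"] = self.all_ok
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()


def _pattern_of(rec: CaseRecord, config: RunConfig) -> dict[str, str] | None:
    """Covariate pattern of a record, or None if outside all bands/periods."""
    pattern: dict[str, str] = {}
    if "age_group" in config.covariates:
        lab = age_band_label(rec.age_dx, config.age_bands)
        if lab is None:
            return None
        pattern["age_group"] = lab
    if "period" in config.covariates:
        lab = period_label(rec.year_dx, config.periods)
        if lab is None:
            return None
        pattern["period"] = lab
    return pattern


def _covariate_levels(config: RunConfig) -> dict[str, list[str]]:
    levels: dict[str, list[str]] = {}
    if "age_group" in config.covariates:
        levels["age_group"] = [f"{lo}-{hi}" for lo, hi in config.age_bands]
    if "period" in config.covariates:
        levels["period"] = [f"{lo}-{hi}" for lo, hi in config.periods]
    return levels


def _fit_stage(tables: list[tuple[dict, GroupedLifeTable]], family: str,
               levels: dict[str, list[str]], stage: str) -> CureModelFit:
    present: dict[str, list[str]] = {}
    for name, levs in levels.items():
        seen = {pat[name] for pat, _ in tables}
        present[name] = [l for l in levs if l in seen]
    spec = CureModelSpec(family=family, covariates=present)
    return fit_mixture_cure(tables, spec, stratum=stage)


def run_pipeline(config_path: str | Path, outdir: str | Path,
                 overrides: dict | None = None) -> RunManifest:
    """Run the full method from a YAML config; returns the manifest.

    The config names the case listing and rate table and mirrors
    :class:`~mrisk.io_formats.RunConfig`.  On a fatal stage error the
    manifest is written with the failure recorded before the exception
    propagates.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with config_path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    config = iof.run_config_from_dict(raw)

    case_path = config_path.parent / raw["case_listing"]
    rate_path = config_path.parent / raw["rate_table"]
    manifest = RunManifest(
        config_hash=_config_hash(raw),
        input_digests={"case_listing": _sha256(case_path),
                       "rate_table": _sha256(rate_path)},
        seed=config.seed,
    )
    manifest_path = outdir / "manifest.json"
    try:
        _run_stages(config, case_path, rate_path, outdir, manifest)
    except Exception as exc:
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest


def _run_stages(config: RunConfig, case_path: Path, rate_path: Path,
                outdir: Path, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    parsed = iof.read_case_listing(case_path)
    for row_no, msg in parsed.errors:
        manifest.warnings.append(f"case row {row_no}: {msg}")
    rate_table = iof.read_rate_table(rate_path)
    eligible, tally = iof.apply_eligibility(parsed.records,
                                            max_age_dx=config.max_age_dx)
    pd.DataFrame(
        [{"reason": k, "n": v} for k, v in tally.counts.items()]
        + [{"reason": "eligible", "n": tally.n_eligible}]
    ).to_csv(outdir / "exclusions.csv", index=False)
    manifest.timings["eligibility"] = round(time.perf_counter() - t0, 3)

    # --- life tables per stratum (stage, or stage × profile) × pattern ----
    # stage IV is always pooled across profiles: it only feeds the
    # post-recurrence survival curve and would be sparse if split.
    t0 = time.perf_counter()
    if config.profiles:
        early = tuple(f"{s}/{p}" for s in config.stages
                      for p in config.profiles)
    else:
        early = tuple(config.stages)
    all_strata = early + ("IV",)
    groups: dict[str, dict[tuple, tuple[dict, list[CaseRecord]]]] = {
        s: {} for s in all_strata}
    for rec in eligible:
        if rec.stage == "IV":
            stratum_id = "IV"
        elif config.profiles:
            stratum_id = f"{rec.stage}/{rec.profile}"
        else:
            stratum_id = rec.stage
        if stratum_id not in groups:
            continue
        pattern = _pattern_of(rec, config)
        if pattern is None:
            continue
        key = tuple(sorted(pattern.items()))
        groups[stratum_id].setdefault(key, (pattern, []))[1].append(rec)

    levels = _covariate_levels(config)
    lifetables: dict[str, list[tuple[dict, GroupedLifeTable]]] = {}
    lt_dir = outdir / "lifetables"
    lt_dir.mkdir(exist_ok=True)
    for stage in all_strata:
        tables = []
        for key, (pattern, recs) in sorted(groups[stage].items()):
            label = stage + ("|" + ";".join(f"{k}={v}" for k, v in
                                            sorted(pattern.items()))
                             if pattern else "")
            try:
                lt = build_lifetable(
                    recs, rate_table, config.interval_width,
                    config.max_horizon, stratum=label,
                    birthday_offset=config.birthday_offset)
            except ValueError as exc:
                manifest.warnings.append(f"lifetable {label}: {exc}")
                continue
            fname = (label.replace("|", "_").replace(";", "_")
                     .replace("=", "-").replace("/", "-") + ".csv")
            lt.write_csv(lt_dir / fname)
            tables.append((pattern, lt))
        if tables:
            lifetables[stage] = tables
        else:
            manifest.strata.append(StratumStatus(stage, "skipped",
                                                 "no subjects"))
    manifest.timings["lifetables"] = round(time.perf_counter() - t0, 3)
    if "IV" not in lifetables:
        raise ValueError("no stage IV subjects: post-recurrence survival "
                         "cannot be constructed")

    # --- cure models, both families, family selection --------------------
    t0 = time.perf_counter()
    fits_by_family: dict[str, dict[str, CureModelFit]] = {}
    families = (("weibull", "loglogistic") if config.cure_family == "auto"
                else (config.cure_family,))
    for family in families:
        fits_by_family[family] = {}
        for stage, tables in lifetables.items():
            try:
                fits_by_family[family][stage] = _fit_stage(
                    tables, family, levels, stage)
            except Exception as exc:
                manifest.warnings.append(
                    f"cure fit {family}/{stage} failed: {exc}")
    if config.cure_family == "auto":
        selection = select_family(fits_by_family)
        family_used = selection.family
        for s in selection.triggering_strata:
            manifest.warnings.append(
                f"log-logistic non-convergence in stratum {s}: "
                f"table-wide Weibull fall-back")
        selection.report.to_csv(outdir / "family_selection.csv", index=False)
    else:
        family_used = config.cure_family
    fits = fits_by_family.get(family_used, {})
    manifest.family_used = family_used
    fallback = (config.cure_family == "auto" and family_used == "weibull"
                and bool(selection.triggering_strata))
    for stage, fit in fits.items():
        if not fit.converged:
            manifest.warnings.append(f"{family_used} fit for stratum {stage} "
                                     f"did not converge")
        for pf in fit.patterns:
            if pf.boundary:
                manifest.warnings.append(
                    f"boundary cure fraction in {stage} {pf.pattern}")
    fit_summary_frame(fits).to_csv(outdir / "fit_summary.csv", index=False)
    manifest.timings["cure_models"] = round(time.perf_counter() - t0, 3)

    if "IV" not in fits or not fits["IV"].converged:
        raise ValueError("stage IV cure-model fit unavailable; cannot build "
                         "post-recurrence survival")

    # --- recurrence risk --------------------------------------------------
    t0 = time.perf_counter()
    step = float(config.deconv_step)
    grid = np.arange(0.0, config.max_horizon + step, step)
    grid_iv = np.arange(0.0, config.max_horizon + step / 2.0, step / 2.0)
    horizons = (60.0, 120.0, 180.0)

    risk_rows, cond_frames, sens_frames, curve_frames = [], [], [], []
    for stage in early:
        if stage not in fits:
            manifest.strata.append(StratumStatus(stage, "skipped",
                                                 "no usable cure fit"))
            continue
        fit = fits[stage]
        status = "fallback-weibull" if fallback else "ok"
        note = ""
        for pf in fit.patterns:
            label = stage + ("|" + ";".join(
                f"{k}={v}" for k, v in sorted(pf.pattern.items()))
                if pf.pattern else "")
            try:
                iv_pattern = _match_iv_pattern(fits["IV"], pf.pattern)
                s_iv = predict_rs(fits["IV"], grid_iv, iv_pattern)
                s_iv = np.minimum.accumulate(np.clip(s_iv, 0.0, 1.0))
                s_iv[0] = 1.0
                s_star = su(fit.family, grid, pf.lam, pf.gamma)
                model = build_t2_survival(grid_iv, s_iv, config.r_default)
                deconv = deconvolve_t1(s_star, model, grid=grid)
                if deconv.unstable:
                    manifest.warnings.append(
                        f"deconvolution unstable for {label}: residual "
                        f"{deconv.residual:.4f} > {RESIDUAL_FLAG_THRESHOLD}")
                curve = mr_risk_curve(pf.c, deconv, stratum=label,
                                      r=config.r_default)
                cond = conditional_risk_table(curve)
                cond_frames.append(cond)
                row = {"stratum": label, "family": fit.family, "c": pf.c,
                       "r": config.r_default,
                       "deconv_residual": deconv.residual,
                       "unstable": deconv.unstable}
                for t in horizons:
                    row[f"P_{int(t)}m"] = curve.at(t)
                for _, crow in cond.iterrows():
                    row[f"q_{int(crow['from_years'])}_{int(crow['to_years'])}y"] = \
                        crow["conditional_risk"]
                risk_rows.append(row)
                curve_frames.append(pd.DataFrame({
                    "stratum": label, "t_months": grid, "s1": curve.s1,
                    "cum_risk": curve.cumulative,
                    "recurrence_free": curve.recurrence_free}))
                sens = sensitivity_over_r(
                    s_star, grid_iv, s_iv, pf.c, config.r_grid,
                    config.r_default, stratum=label, grid=grid)
                sens_frames.append(sens)
            except Exception as exc:
                status, note = "skipped", f"{label}: {exc}"
                manifest.warnings.append(f"risk step failed for {label}: {exc}")
        manifest.strata.append(StratumStatus(stage, status, note))
    manifest.strata.append(StratumStatus(
        "IV", "ok", "post-recurrence survival input"))

    pd.DataFrame(risk_rows).to_csv(outdir / "risk_table.csv", index=False)
    if cond_frames:
        pd.concat(cond_frames, ignore_index=True).to_csv(
            outdir / "conditional_risks.csv", index=False)
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(
            outdir / "risk_curves.csv", index=False)
    if sens_frames:
        pd.concat(sens_frames, ignore_index=True).to_csv(
            outdir / "sensitivity_r.csv", index=False)
    manifest.timings["recurrence_risk"] = round(time.perf_counter() - t0, 3)


def _match_iv_pattern(iv_fit: CureModelFit, pattern: dict[str, str]
                      ) -> dict[str, str]:
    """Stage-IV pattern matching an early-stage pattern, if fitted."""
    try:
        iv_fit.pattern_fit(pattern)
        return pattern
    except KeyError:
        # fall back to the stage-IV reference pattern
        return iv_fit.patterns[0].pattern


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def make_report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run (one-decimal percentages).

    Cumulative risk at 5/10/15 years and conditional risks per 5-year
    interval per stratum, plus the r-sensitivity appendix.  Skipped strata
    render as explicit gaps.
    """
    outdir = Path(outdir)
    risk = pd.read_csv(outdir / "risk_table.csv")
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = ["Metastatic recurrence risk (net of other-cause mortality)",
             "=" * 60, ""]
    lines.append(f"{'stratum':<34}{'5y':>7}{'10y':>7}{'15y':>7}"
                 f"{'q0-5':>7}{'q5-10':>7}{'q10-15':>8}")
    for _, row in risk.iterrows():
        lines.append(
            f"{row['stratum']:<34}"
            f"{format_percent(row['P_60m']):>7}"
            f"{format_percent(row['P_120m']):>7}"
            f"{format_percent(row['P_180m']):>7}"
            f"{format_percent(row['q_0_5y']):>7}"
            f"{format_percent(row['q_5_10y']):>7}"
            f"{format_percent(row['q_10_15y']):>8}")
    for st in manifest["strata"]:
        if st["status"] == "skipped":
            lines.append(f"{st['stratum']:<34}{'— (skipped: ' + (st['note'] or 'no estimate') + ')'}")
        elif st["status"] == "fallback-weibull":
            lines.append(f"[{st['stratum']}] log-logistic fall-back to Weibull")
    sens_path = outdir / "sensitivity_r.csv"
    if sens_path.exists():
        sens = pd.read_csv(sens_path)
        lines += ["", "Sensitivity to r (cumulative risk, %):", "-" * 60]
        lines.append(f"{'stratum':<34}{'r':>6}{'5y':>7}{'10y':>7}{'15y':>7}")
        for _, row in sens.iterrows():
            lines.append(f"{row['stratum']:<34}{row['r']:>6.2f}"
                         f"{format_percent(row['P_60m']):>7}"
                         f"{format_percent(row['P_120m']):>7}"
                         f"{format_percent(row['P_180m']):>7}")
    report = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report)
    return report
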