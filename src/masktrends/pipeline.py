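"""End-to-end orchestration: simulate → assign → evaluate → aggregate → fit.

Runs the full surveillance pipeline from a single config: generate the
synthetic inputs, filter and county-resolve the tweet stream, build the
classifier threshold table and pick the operating threshold, aggregate to
the county-week mask-posting panel, screen counties against the
power-analysis sample-size floor, fit the multilevel binomial models,
compute the mandate marginal-effect curve, and validate the national
series against the synthetic survey. Every stage's outputs are written
under ``output_dir`` together with a manifest (seed, parameters, file
hashes) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import (
    GeneratorParams,
    generate_all,
    params_from_dict,
    params_to_dict,
)
from .temporal_mandate import build_weeks
from .geo_assign import assign_all
from .detection_eval import threshold_table, select_threshold, rows_to_frame, roc
from .metrics import (
    user_week_rollup,
    county_week_metric,
    national_series,
    first_difference,
    pearson_correlation,
    build_panel,
)
from .study_design import PowerSpec, eligible_counties
from .inference import (
    MaskMandateGLMM,
    compare_models,
    marginal_effect_curve,
)

log = logging.getLogger("masktrends")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    threshold_policy: str = "select"  # "select" or "fixed"
    fixed_threshold: float = 0.9
    candidate_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    f1_tolerance: float = 0.01
    power: PowerSpec = field(default_factory=PowerSpec)
    model: str = "both"  # "interaction", "main", or "both"
    gop_grid: tuple[float, float, float] = (15.0, 85.0, 1.0)  # start, stop, step
    output_dir: str = "masktrends_run"
    log_level: str = "INFO"
    plots: bool = False

    def __post_init__(self) -> None:
        if self.threshold_policy not in ("select", "fixed"):
            raise ValueError("threshold_policy must be 'select' or 'fixed'")
        if self.model not in ("interaction", "main", "both"):
            raise ValueError("model must be 'interaction', 'main', or 'both'")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "generator" in kwargs:
        kwargs["generator"] = params_from_dict(kwargs["generator"])
    if "power" in kwargs:
        kwargs["power"] = PowerSpec(**kwargs["power"])
    for key in ("candidate_thresholds", "gop_grid"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.generator
    weeks = build_weeks(params.start_date, params.n_weeks)

    files = _simulate(params, outdir)
    tweets = pd.read_csv(files["tweets"], dtype={"fips": "string", "city_id": "string"})
    counties = pd.read_csv(files["gazetteer"], dtype={"fips": "string"})
    overlaps = pd.read_csv(files["city_overlap"], dtype={"fips": "string"})
    covariates = pd.read_csv(files["covariates"], dtype={"fips": "string"})
    survey = pd.read_csv(files["survey"])

    assigned, assign_report = _assign(tweets, overlaps, weeks, outdir)
    thr_frame, threshold, auc = _detect_eval(assigned, config, outdir)
    rollup, county_metrics, national = _aggregate(assigned, threshold, outdir)
    panel, eligible = _screen(
        rollup, county_metrics, counties, covariates, config.power, outdir
    )
    fits, comparison = _fit(panel, config, outdir)
    margins = _margins(fits, config, outdir)
    report = _report(
        config, assign_report, thr_frame, threshold, auc, national, survey,
        eligible, fits, comparison, margins, outdir,
    )
    _manifest(config, files, outdir)
    if config.plots:
        _plots(national, survey, margins, outdir)
    return report


@_stage("simulate")
def _simulate(params: GeneratorParams, outdir: Path) -> dict[str, Path]:
    return generate_all(params, outdir / "inputs")


@_stage("assign")
def _assign(tweets, overlaps, weeks, outdir: Path):
    from .metrics import assign_weeks

    assigned, report = assign_all(tweets, overlaps)
    assigned = assign_weeks(assigned, weeks)
    assigned.to_csv(outdir / "assigned.csv", index=False)
    (outdir / "assign_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return assigned, report


@_stage("detect-eval")
def _detect_eval(assigned, config: PipelineConfig, outdir: Path):
    images = assigned.loc[assigned["has_image"].astype(bool)]
    scores = images["score"].astype(float).values
    truth = images["true_label"].astype(int).values
    rows = threshold_table(scores, truth, config.candidate_thresholds)
    frame = rows_to_frame(rows)
    frame.to_csv(outdir / "threshold_table.csv", index=False)
    curve = roc(scores, truth)
    pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
        outdir / "roc_points.csv", index=False
    )
    if config.threshold_policy == "fixed":
        threshold = config.fixed_threshold
    else:
        threshold = select_threshold(rows, config.f1_tolerance)
    return frame, threshold, curve.auc


@_stage("aggregate")
def _aggregate(assigned, threshold: float, outdir: Path):
    rollup = user_week_rollup(assigned, threshold)
    county = county_week_metric(rollup)
    national = national_series(rollup)
    county.to_csv(outdir / "county_week_metrics.csv", index=False)
    national.to_csv(outdir / "national_series.csv", index=False)
    return rollup, county, national


@_stage("power-screen")
def _screen(rollup, county_metrics, counties, covariates, power: PowerSpec, outdir: Path):
    users_per_county = rollup.groupby("fips")["user_id"].nunique()
    eligible = eligible_counties(users_per_county, power.n_required)
    panel = build_panel(county_metrics, counties, covariates)
    panel = panel.loc[panel["fips"].isin(eligible)]
    panel = panel.loc[panel["n_image_users"].notna() & (panel["n_image_users"] > 0)]
    panel.to_csv(outdir / "panel.csv", index=False)
    return panel, eligible


@_stage("fit")
def _fit(panel, config: PipelineConfig, outdir: Path):
    fits = {}
    if config.model in ("interaction", "both"):
        fits["interaction"] = MaskMandateGLMM.from_panel(panel, interaction=True).fit()
    if config.model in ("main", "both"):
        fits["main"] = MaskMandateGLMM.from_panel(panel, interaction=False).fit()
    for name, res in fits.items():
        if not res.converged:
            raise RuntimeError(f"{name} model did not converge")
        (outdir / f"fit_{name}.json").write_text(json.dumps(res.to_dict(), indent=2))
    comparison = compare_models(fits) if len(fits) > 1 else None
    if comparison is not None:
        comparison.to_csv(outdir / "model_comparison.csv")
    return fits, comparison


@_stage("margins")
def _margins(fits, config: PipelineConfig, outdir: Path):
    if "interaction" not in fits:
        return None
    start, stop, step = config.gop_grid
    grid = np.arange(start, stop + step / 2, step)
    curve = marginal_effect_curve(fits["interaction"], grid)
    frame = curve.to_frame()
    frame.to_csv(outdir / "margins.csv", index=False)
    return frame


@_stage("report")
def _report(
    config, assign_report, thr_frame, threshold, auc, national, survey,
    eligible, fits, comparison, margins, outdir: Path,
):
    merged = national.merge(survey, on="week_index", how="inner")
    r, p, n = pearson_correlation(merged["proportion"], merged["pct_mask"])
    rd, pd_, nd = pearson_correlation(
        first_difference(merged["proportion"]), first_difference(merged["pct_mask"])
    )
    report = {
        "package_version": __version__,
        "seed": config.generator.seed,
        "geo_assignment": assign_report.to_dict(),
        "threshold_table": thr_frame.to_dict(orient="records"),
        "selected_threshold": threshold,
        "roc_auc": auc,
        "power": config.power.to_dict(),
        "eligibility_cutoff_users": config.power.n_required,
        "n_eligible_counties": len(eligible),
        "national_series": national.to_dict(orient="records"),
        "survey_correlation": {"r": r, "p": p, "n": n},
        "survey_correlation_first_diff": {"r": rd, "p": pd_, "n": nd},
        "fits": {name: res.to_dict() for name, res in fits.items()},
        "model_comparison": None
        if comparison is None
        else comparison.to_dict(orient="index"),
        "marginal_effects": None if margins is None else margins.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (outdir / "report.txt").write_text(_text_report(report, fits))
    return report


def _text_report(report: dict, fits) -> str:
    lines = [
        f"masktrends pipeline report (v{report['package_version']}, seed {report['seed']})",
        "",
        f"geotag filter: dropped {report['geo_assignment']['drop']['n_dropped']} of "
        f"{report['geo_assignment']['drop']['n_input']} tweets "
        f"({report['geo_assignment']['drop']['drop_fraction']:.1%}) above city precision",
        f"multi-county city share: {report['geo_assignment']['multi_county_share']:.1%}",
        f"selected decision threshold: {report['selected_threshold']} "
        f"(ROC AUC {report['roc_auc']:.3f})",
        f"eligibility: >= {report['eligibility_cutoff_users']} unique image users; "
        f"{report['n_eligible_counties']} counties eligible",
        f"survey correlation: r={report['survey_correlation']['r']:.3f} "
        f"(N={report['survey_correlation']['n']}); first differences "
        f"r={report['survey_correlation_first_diff']['r']:.3f}",
        "",
    ]
    for name, res in fits.items():
        lines += [f"--- {name} model ---", res.summary(), ""]
    return "\n".join(lines)


def _manifest(config: PipelineConfig, files: dict[str, Path], outdir: Path) -> None:
    manifest = {
        "package_version": __version__,
        "seed": config.generator.seed,
        "generator_params": params_to_dict(config.generator),
        "input_hashes": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _plots(national, survey, margins, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(national["week_index"], 100 * national["proportion"], "o-", label="image stream")
    ax1.set_xlabel("study week")
    ax1.set_ylabel("% users posting a mask image")
    ax2 = ax1.twinx()
    ax2.plot(survey["week_index"], survey["pct_mask"], "s--", color="tab:orange", label="survey")
    ax2.set_ylabel("% survey respondents wearing a mask")
    fig.tight_layout()
    fig.savefig(outdir / "national_vs_survey.png", dpi=120)
    plt.close(fig)

    if margins is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(margins["gop_vote_2016"], margins["effect"])
        ax.fill_between(
            margins["gop_vote_2016"], margins["ci_low"], margins["ci_high"], alpha=0.3
        )
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("county GOP vote share (2016, %)")
        ax.set_ylabel("mandate effect on mask-posting proportion")
        fig.tight_layout()
        fig.savefig(outdir / "marginal_effects.png", dpi=120)
        plt.close(fig)
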