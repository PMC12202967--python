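"""Configuration, logging, and the simulate -> analyze -> report pipeline.

``run_analyze`` turns per-subject input files into tidy per-subject result
CSVs (midline values, proportion ratios, smile attributes); subjects that
fail validation are skipped with a logged, machine-readable reason and
listed in an exclusions file. ``run_report`` rolls the per-subject results
up into cohort summary tables with per-sex columns and test p-values.

The ``smileframe`` CLI exposes the three stages; exit code 0 on success,
2 on input-validation failure, 1 on internal error.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Literal

import click
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import beauty_frame as bf
from . import cohort_stats as cs
from . import facial_proportions as fp
from . import smile_framework as sf
from .errors import EmptyCohortError, SchemaError, SmileframeError
from .landmark_model import (
    read_demographics_file,
    read_landmark_file,
    read_smile_observations_file,
    read_tooth_file,
    validate_for,
)
from .synthetic_cohort import CohortParameters, generate_cohort

logger = logging.getLogger("smileframe")


class AnalysisConfig(BaseModel):
    """Tunable analysis settings with validated defaults."""

    classification_tol: float = Field(
        0.0, ge=0, description="RFV/RCV dead band around 1 for side calls"
    )
    flatness_tol: float = Field(
        sf.DEFAULT_FLATNESS_TOL, ge=0,
        description="curvature (px^-1) below which a smile curve is flat",
    )
    lip_tol_frac: float = Field(
        sf.DEFAULT_LIP_TOL_FRAC, ge=0, lt=1,
        description="lip-curvature dead band as fraction of frame height",
    )
    dp_definition: Literal["as_printed", "width_over_length"] = "as_printed"
    percent_decimals: int = Field(cs.PERCENT_DECIMALS, ge=0)
    ratio_decimals: int = Field(cs.RATIO_DECIMALS, ge=0)
    p_decimals: int = Field(cs.P_DECIMALS, ge=0)
    log_level: str = "INFO"


def load_config(path=None) -> AnalysisConfig:
    """Load a YAML config file (missing file/keys fall back to defaults)."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------

RFV_COLUMNS = [f"rfv{i}" for i in range(1, 6)]
RCV_COLUMNS = [f"rcv{i}" for i in range(1, 5)]

SMILE_ATTRIBUTES = {
    "arc": sf.SMILE_ARC_LEVELS,
    "lip_curvature": sf.LIP_CURVATURE_LEVELS,
    "smile_line": sf.SMILE_LINE_LEVELS,
    "smile_width": sf.SMILE_WIDTH_LEVELS,
    "tooth_shape": sf.TOOTH_SHAPE_LEVELS,
}


def analyze_cohort(
    landmark_sets,
    teeth,
    smile_obs: pd.DataFrame,
    config: AnalysisConfig | None = None,
):
    """Run the full analysis on in-memory inputs.

    Returns ``(rfv_df, ratios_df, smile_df, exclusions_df)``; each subject
    lands either in all three result frames or in the exclusions frame.
    """
    config = config or AnalysisConfig()
    by_subject: dict[str, dict] = {}
    for lset in landmark_sets:
        by_subject.setdefault(lset.subject_id, {})[lset.view] = lset
    teeth_by_id = {t.subject_id: t for t in teeth}
    obs_by_id = {
        str(r.subject_id): r for r in smile_obs.itertuples(index=False)
    }

    rfv_rows, ratio_rows, smile_rows, excl_rows = [], [], [], []
    for sid in by_subject:
        views = by_subject[sid]
        reasons = []
        rest = views.get("frontal_rest")
        smile = views.get("frontal_smile")
        if rest is None:
            reasons.append("missing_view:frontal_rest")
        else:
            rep = validate_for(rest, "proportions")
            if not rep.ok:
                reasons.append("invalid_proportions:" + ";".join(rep.reasons))
        if smile is None:
            reasons.append("missing_view:frontal_smile")
        else:
            for kind in ("frame", "smile"):
                rep = validate_for(smile, kind)
                if not rep.ok:
                    reasons.append(f"invalid_{kind}:" + ";".join(rep.reasons))
        if sid not in teeth_by_id:
            reasons.append("missing_tooth_measurement")
        if sid not in obs_by_id:
            reasons.append("missing_smile_observation")
        if reasons:
            logger.info("excluded subject=%s reasons=%s", sid, "|".join(reasons))
            excl_rows.append({"subject_id": sid, "reasons": "|".join(reasons)})
            continue

        frame = bf.build_frame(smile)
        rfv = bf.compute_rfv(frame, smile)
        rcv = bf.compute_rcv(frame, smile)
        row = {"subject_id": sid, **rfv.as_dict(), **rcv.as_dict()}
        for col in RFV_COLUMNS:
            row[f"side_{col}"] = bf.classify_side(
                row[col], config.classification_tol
            )
        rfv_rows.append(row)

        ratios = fp.compute_ratios(fp.measure_distances(rest))
        for name, value in ratios.ratios.items():
            ratio_rows.append({
                "subject_id": sid, "ratio": name, "value": value,
                "golden_percent": ratios.golden_percents[name],
            })

        obs_row = obs_by_id[sid]
        obs = sf.SmileLineObservation(
            exposure_fraction=float(obs_row.exposure_fraction),
            gingival_display=str(obs_row.gingival_display),
        )
        assessment = sf.assess_smile(
            smile, frame, obs, int(obs_row.last_visible_tooth),
            teeth_by_id[sid],
            flatness_tol=config.flatness_tol,
            lip_tol_frac=config.lip_tol_frac,
            dp_definition=config.dp_definition,
        )
        smile_rows.append({
            "subject_id": sid,
            "arc": assessment.arc,
            "lip_curvature": assessment.lip_curvature,
            "smile_line": assessment.smile_line,
            "smile_width": assessment.smile_width,
            "dp_percent": assessment.dp_percent,
            "tooth_shape": assessment.tooth_shape,
            "wl_ratio": assessment.wl_ratio,
            "wl_golden_percent": assessment.wl_golden_percent,
        })

    if not rfv_rows:
        raise EmptyCohortError("no subject passed validation")
    return (
        pd.DataFrame(rfv_rows),
        pd.DataFrame(ratio_rows),
        pd.DataFrame(smile_rows),
        pd.DataFrame(excl_rows, columns=["subject_id", "reasons"]),
    )


def run_analyze(
    landmark_path,
    tooth_path,
    demographics_path,
    smile_obs_path,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> dict[str, Path]:
    """File-level analyze stage; writes the per-subject result CSVs."""
    landmark_sets = read_landmark_file(landmark_path, "csv")
    teeth = read_tooth_file(tooth_path)
    read_demographics_file(demographics_path)  # validated here, used by report
    smile_obs = read_smile_observations_file(smile_obs_path)
    rfv_df, ratios_df, smile_df, excl_df = analyze_cohort(
        landmark_sets, teeth, smile_obs, config
    )
    outdir = Path(outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rfv": outdir / "rfv.csv",
        "ratios": outdir / "ratios.csv",
        "smile": outdir / "smile.csv",
        "exclusions": outdir / "exclusions.csv",
    }
    rfv_df.to_csv(paths["rfv"], index=False)
    ratios_df.to_csv(paths["ratios"], index=False)
    smile_df.to_csv(paths["smile"], index=False)
    excl_df.to_csv(paths["exclusions"], index=False)
    return paths


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


def run_report(
    analyze_dir,
    demographics_path,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> dict[str, Path]:
    """Roll per-subject results up into cohort summary tables + JSON."""
    config = config or AnalysisConfig()
    analyze_dir = Path(analyze_dir)
    for name in ("rfv.csv", "ratios.csv", "smile.csv"):
        if not (analyze_dir / name).exists():
            raise SchemaError(f"missing analyze output file {name!r}")
    rfv_df = pd.read_csv(analyze_dir / "rfv.csv", dtype={"subject_id": str})
    ratios_df = pd.read_csv(analyze_dir / "ratios.csv", dtype={"subject_id": str})
    smile_df = pd.read_csv(analyze_dir / "smile.csv", dtype={"subject_id": str})
    demo = read_demographics_file(demographics_path)

    rfv_df = rfv_df.merge(demo[["subject_id", "sex"]], on="subject_id")
    smile_df = smile_df.merge(demo[["subject_id", "sex"]], on="subject_id")
    ratios_wide = ratios_df.pivot(
        index="subject_id", columns="ratio", values="value"
    ).reset_index().merge(demo[["subject_id", "sex"]], on="subject_id")

    proportion_table = cs.build_continuous_table(
        ratios_wide, list(fp.RATIO_DEFINITIONS),
        golden_reference=fp.GOLDEN_RATIO,
    )
    midline_table = cs.build_continuous_table(
        rfv_df, RFV_COLUMNS + RCV_COLUMNS
    )
    smile_table = cs.build_categorical_table(smile_df, SMILE_ATTRIBUTES)

    rfv_sets = [
        bf.RFVSet(**{c: row[c] for c in RFV_COLUMNS})
        for _, row in rfv_df.iterrows()
    ]
    hierarchy = bf.landmark_hierarchy(rfv_sets)

    outdir = Path(outdir or analyze_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proportions_summary": outdir / "proportions_summary.csv",
        "midline_summary": outdir / "midline_summary.csv",
        "smile_summary": outdir / "smile_summary.csv",
        "summary_json": outdir / "summary.json",
    }
    cs.round_for_display(proportion_table).to_csv(
        paths["proportions_summary"], index=False
    )
    cs.round_for_display(midline_table).to_csv(
        paths["midline_summary"], index=False
    )
    cs.round_for_display(smile_table).to_csv(
        paths["smile_summary"], index=False
    )
    summary = {
        "n_subjects": int(rfv_df.shape[0]),
        "n_female": int((rfv_df["sex"] == "female").sum()),
        "n_male": int((rfv_df["sex"] == "male").sum()),
        "landmark_hierarchy": ", ".join(hierarchy),
        "rfv_means": {c: float(rfv_df[c].mean()) for c in RFV_COLUMNS},
        "rcv_means": {c: float(rfv_df[c].mean()) for c in RCV_COLUMNS},
    }
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return paths


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


def _configure_logging(level: str) -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s %(message)s",
    )


@click.group()
def cli():
    """Facial midline, golden-proportion and smile-framework analysis."""


@cli.command()
@click.option("--params", type=click.Path(exists=True), default=None,
              help="YAML overriding generator parameters")
@click.option("--n", type=int, default=None, help="number of subjects")
@click.option("--seed", type=int, default=None, help="random seed")
@click.option("--out", type=click.Path(), required=True,
              help="output directory")
def simulate(params, n, seed, out):
    """Generate a synthetic cohort with ground truth."""
    overrides = {}
    if params is not None:
        with open(params) as fh:
            overrides = yaml.safe_load(fh) or {}
    p = CohortParameters(**overrides)
    cohort = generate_cohort(p, n=n, seed=seed)
    paths = cohort.write(out)
    click.echo(
        f"wrote {len(cohort.ground_truth)} subjects to {paths['landmarks'].parent}"
    )


@cli.command()
@click.option("--landmarks", type=click.Path(exists=True), required=True)
@click.option("--teeth", type=click.Path(exists=True), required=True)
@click.option("--demographics", type=click.Path(exists=True), required=True)
@click.option("--smile-obs", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--out", type=click.Path(), required=True)
def analyze(landmarks, teeth, demographics, smile_obs, config_path, out):
    """Per-subject midline, proportion and smile analysis."""
    config = load_config(config_path)
    _configure_logging(config.log_level)
    paths = run_analyze(
        landmarks, teeth, demographics, smile_obs, config, outdir=out
    )
    click.echo(f"wrote {', '.join(str(p) for p in paths.values())}")


@cli.command()
@click.option("--analyze-dir", type=click.Path(exists=True), required=True)
@click.option("--demographics", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--out", type=click.Path(), default=None)
def report(analyze_dir, demographics, config_path, out):
    """Cohort summary tables with per-sex comparisons."""
    config = load_config(config_path)
    _configure_logging(config.log_level)
    paths = run_report(analyze_dir, demographics, config, outdir=out)
    click.echo(f"wrote {', '.join(str(p) for p in paths.values())}")


def main(argv=None) -> int:
    """Console entry point with the documented exit-code contract."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show()
        return 2
    except click.Abort:
        return 1
    except (SchemaError, EmptyCohortError, SmileframeError) as exc:
        click.echo(f"validation error: {exc}", err=True)
        return 2
    except Exception as exc:  # pragma: no cover - defensive
        click.echo(f"internal error: {exc}", err=True)
        return 1


if __name__ == "__main__":
    sys.exit(main())
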