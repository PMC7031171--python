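"""End-to-end pipeline: recordings -> metrics -> reliability -> group stats.

``process_recording`` turns one raw recording into its fatigue fits,
aggregate outcomes, imbalance parameters and trunk-angle QC metrics.
``run_pipeline`` drives a whole (synthetic or on-disk) cohort through the
stages, caches every intermediate as tidy CSV, and finishes with the
cohort-level reliability and mixed-model analyses.  Outputs are
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fatigue import FatigueSummary, fit_mf_regression, summarize_fatigue
from .imbalance import ImbalanceSummary, imbalance_summary, ratio_series, symmetric_transform
from .io import METRIC_COLUMNS, write_metrics
from .kinematics import KinematicsConfig, TrunkAngleSeries, angle_from_accel
from .preprocess import PreprocessConfig, preprocess_channel
from .reliability import dependability, estimate_variance_components
from .spectral import MFSeries, SpectralConfig, compute_mf_series
from .synth import AngleProfile, ChannelSpec, generate_recording
from .types import (
    CANONICAL_CHANNELS,
    LEVELS,
    REPORT_LEVELS,
    ContractionRecording,
    RecordingMeta,
    channel_label,
)


@dataclass
class SimulateConfig:
    """Cohort synthesis block of a pipeline run.

    Group slope means follow the age split of the study conditions
    (young/old normalised slopes around -0.21 / -0.12 %/s); onsets use
    the per-level defaults with between-subject scatter.
    """

    n_subjects_per_cell: int = 3
    n_days: int = 2
    duration_s: float = 30.0
    slope_mean: dict = field(
        default_factory=lambda: {"young": -0.21, "old": -0.12}
    )
    slope_subject_sd: float = 0.05
    slope_day_sd: float = 0.01
    onset_subject_sd_hz: float = 8.0
    onset_day_sd_hz: float = 2.0
    asymmetry_log_sd: float = 0.03
    angle_onset_deg: float = 23.0
    angle_drift_deg_s: float = 0.05


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    imbalance_transform: str = "percent_diff"
    reliability_metric: str = "slope_norm_side_mean"
    recordings: list | None = None  # stems of on-disk recordings, else simulate

    def validate(self, semg_fs: float = 2000.0) -> None:
        self.preprocess.validate(semg_fs)
        self.spectral.validate()

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {}
        for key in ("seed", "out_dir", "imbalance_transform", "reliability_metric", "recordings"):
            if key in cfg:
                known[key] = cfg[key]
        if "simulate" in cfg:
            known["simulate"] = SimulateConfig(**cfg["simulate"])
        if "preprocess" in cfg:
            known["preprocess"] = PreprocessConfig(**cfg["preprocess"])
        if "spectral" in cfg:
            known["spectral"] = SpectralConfig(**cfg["spectral"])
        if "kinematics" in cfg:
            known["kinematics"] = KinematicsConfig(**cfg["kinematics"])
        unknown = set(cfg) - {
            "seed", "out_dir", "imbalance_transform", "reliability_metric",
            "recordings", "simulate", "preprocess", "spectral", "kinematics",
        }
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        rc = cls(**known)
        rc.validate()
        return rc


@dataclass
class RecordingResult:
    """All per-recording outputs."""

    meta: RecordingMeta
    mf_series: dict[str, MFSeries]
    summary: FatigueSummary
    imbalance: ImbalanceSummary
    kinematics: TrunkAngleSeries


def process_recording(
    rec: ContractionRecording,
    preprocess_cfg: PreprocessConfig | None = None,
    spectral_cfg: SpectralConfig | None = None,
    kinematics_cfg: KinematicsConfig | None = None,
    imbalance_transform: str = "percent_diff",
) -> RecordingResult:
    """Run one recording through preprocessing, MF, fatigue and imbalance."""
    pre = preprocess_cfg or PreprocessConfig()
    spec = spectral_cfg or SpectralConfig()
    kin = kinematics_cfg or KinematicsConfig(
        trim_start=pre.trim_start, analysis_end=pre.analysis_end
    )
    pre.validate(rec.semg_fs)
    spec.validate()

    mf_series: dict[str, MFSeries] = {}
    fits = {}
    for label in CANONICAL_CHANNELS:
        art = preprocess_channel(rec.channel(label), pre)
        series = compute_mf_series(
            art.channel, spec, sample_mask=art.sample_mask, electrode=label
        )
        if not art.usable:
            series.excluded[:] = True
        mf_series[label] = series
        fits[label] = fit_mf_regression(series)
    summary = summarize_fatigue(fits)

    level_R = {}
    for level in REPORT_LEVELS:
        rs = ratio_series(
            mf_series[channel_label(level, "right")],
            mf_series[channel_label(level, "left")],
        )
        level_R[level] = symmetric_transform(rs.values, method=imbalance_transform)
    imb = imbalance_summary(level_R)

    kin_series = angle_from_accel(rec.accel_axis(kin.axis), kin)
    return RecordingResult(
        meta=rec.meta,
        mf_series=mf_series,
        summary=summary,
        imbalance=imb,
        kinematics=kin_series,
    )


def simulate_cohort_recordings(cfg: SimulateConfig, seed: int):
    """Yield (subject metadata, recording) pairs for a synthetic cohort."""
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).spawn(10_000)
    k = 0
    sid = 0
    for age in ("young", "old"):
        for sex in ("male", "female"):
            for _ in range(cfg.n_subjects_per_cell):
                sid += 1
                subject = f"S{sid:03d}"
                slope_subj = cfg.slope_mean[age] + rng.normal(0, cfg.slope_subject_sd)
                onset_subj = {
                    lv: base + rng.normal(0, cfg.onset_subject_sd_hz)
                    for lv, base in {"L5": 117.0, "L2": 101.0, "L1": 85.5}.items()
                }
                asym = float(np.exp(rng.normal(0, cfg.asymmetry_log_sd)))
                for day in range(1, cfg.n_days + 1):
                    slope = min(
                        -0.01, slope_subj + rng.normal(0, cfg.slope_day_sd)
                    )
                    day_shift = rng.normal(0, cfg.onset_day_sd_hz)
                    specs = []
                    for lv in LEVELS:
                        for side in ("left", "right"):
                            onset = onset_subj[lv] + day_shift
                            if side == "right":
                                onset *= asym
                            specs.append(
                                ChannelSpec(
                                    label=channel_label(lv, side),
                                    onset_mf=float(np.clip(onset, 60.0, 200.0)),
                                    normalized_slope=float(slope),
                                )
                            )
                    profile = AngleProfile(
                        onset_deg=cfg.angle_onset_deg + rng.normal(0, 2.0),
                        drift_deg_s=cfg.angle_drift_deg_s,
                    )
                    meta = RecordingMeta(
                        subject_id=subject, age_group=age, sex=sex, test_day=day
                    )
                    rec = generate_recording(
                        specs,
                        profile,
                        duration=cfg.duration_s,
                        seed=seeds[k],
                        meta=meta,
                    )
                    k += 1
                    yield meta, rec


def _fit_rows(result: RecordingResult) -> list[dict]:
    meta = result.meta
    base = {
        "subject": meta.subject_id,
        "age_group": meta.age_group,
        "sex": meta.sex,
        "test_day": meta.test_day,
    }
    rows = []
    for label in CANONICAL_CHANNELS:
        fit = result.summary.fits[label]
        rows.append(
            base
            | {
                "electrode": label,
                "intercept_hz": fit.intercept_hz,
                "slope_hz_s": fit.slope_hz_s,
                "slope_norm": fit.slope_norm,
                "n_points": fit.n_points,
                "r2": fit.r2,
                "usable": fit.usable,
            }
        )
    s = result.summary
    rows.append(
        base
        | {
            "electrode": "all",
            "intercept_hz": s.all_mean_onset_hz,
            "slope_hz_s": np.nan,
            "slope_norm": s.all_mean_slope_norm,
            "n_points": s.n_usable,
            "r2": np.nan,
            "usable": s.n_usable > 0,
        }
    )
    mn = s.most_negative
    rows.append(
        base
        | {
            "electrode": "most_negative",
            "intercept_hz": mn.intercept_hz,
            "slope_hz_s": mn.slope_hz_s,
            "slope_norm": mn.slope_norm,
            "n_points": mn.n_points,
            "r2": mn.r2,
            "usable": mn.usable,
        }
    )
    return rows


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute a full cohort run and write all outputs under ``out_dir``.

    Returns a dict of output DataFrames plus the paths written.  The run
    manifest records every parameter and the package version.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.recordings:
        from .io import read_recording

        pairs = ((None, read_recording(stem)) for stem in config.recordings)
    else:
        pairs = simulate_cohort_recordings(config.simulate, config.seed)

    fit_rows: list[dict] = []
    imb_rows: list[dict] = []
    kin_rows: list[dict] = []
    side_rows: list[dict] = []
    for _, rec in pairs:
        result = process_recording(
            rec,
            config.preprocess,
            config.spectral,
            config.kinematics,
            config.imbalance_transform,
        )
        meta = result.meta
        base = {
            "subject": meta.subject_id,
            "age_group": meta.age_group,
            "sex": meta.sex,
            "test_day": meta.test_day,
        }
        fit_rows.extend(_fit_rows(result))
        imb_rows.append(
            base
            | {f"segmental_{lv}": result.imbalance.segmental[lv] for lv in REPORT_LEVELS}
            | {
                "uncompensated": result.imbalance.uncompensated,
                "compensated": result.imbalance.compensated,
            }
        )
        kin_rows.append(
            base
            | {
                "onset_angle_deg": result.kinematics.onset_angle,
                "drift_rate_deg_s": result.kinematics.drift_rate,
            }
        )
        for side in ("left", "right"):
            slopes = [
                result.summary.fits[channel_label(lv, side)].slope_norm
                for lv in LEVELS
                if result.summary.fits[channel_label(lv, side)].usable
            ]
            if slopes:
                side_rows.append(
                    base | {"side": side, "slope_norm_side_mean": float(np.mean(slopes))}
                )

    fits = pd.DataFrame(fit_rows)
    imb = pd.DataFrame(imb_rows)
    kin = pd.DataFrame(kin_rows)
    sides = pd.DataFrame(side_rows)

    write_metrics(fits, out / "fatigue_fits.csv")
    imb.to_csv(out / "imbalance.csv", index=False, float_format="%.17g")
    kin.to_csv(out / "kinematics.csv", index=False, float_format="%.17g")
    sides.to_csv(out / "side_metrics.csv", index=False, float_format="%.17g")

    outputs: dict = {
        "fatigue_fits": fits,
        "imbalance": imb,
        "kinematics": kin,
        "side_metrics": sides,
        "out_dir": out,
    }

    # cohort-level reliability on the per-side normalised slope
    rel_df = sides.rename(columns={"test_day": "day"})
    if rel_df["day"].nunique() >= 2 or rel_df["side"].nunique() >= 2:
        comp = estimate_variance_components(
            rel_df, value_col="slope_norm_side_mean", method="auto"
        )
        report = dependability(comp)
        rel_table = pd.DataFrame(
            [
                {
                    "metric": "slope_norm_side_mean",
                    **comp.as_dict(),
                    "D": report.D,
                    "sem_abs": report.sem_abs,
                }
            ]
        )
        rel_table.to_csv(out / "reliability.csv", index=False, float_format="%.17g")
        outputs["reliability"] = rel_table

    # group statistics on the "all electrodes" normalised slope
    all_rows = fits[fits["electrode"] == "all"]
    cells = all_rows.groupby(["age_group", "sex"], observed=True)["subject"].nunique()
    if len(cells) >= 2 and (cells >= 2).all():
        from .group_stats import fit_group_model

        res = fit_group_model(all_rows, "slope_norm")
        res.anova.to_csv(out / "stats_anova.csv", index=False, float_format="%.17g")
        res.contrasts.to_csv(
            out / "stats_contrasts.csv", index=False, float_format="%.17g"
        )
        res.emm.to_csv(out / "stats_emm.csv", index=False, float_format="%.17g")
        outputs["group_model"] = res

    manifest = {
        "package": "semgfatigue",
        "version": __version__,
        "seed": config.seed,
        "preprocess": asdict(config.preprocess),
        "spectral": asdict(config.spectral),
        "kinematics": asdict(config.kinematics),
        "imbalance_transform": config.imbalance_transform,
        "simulate": None if config.recordings else asdict(config.simulate),
        "n_recordings": int(len(kin)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest
    return outputs
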