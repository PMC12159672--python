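"""End-to-end pipeline orchestration.

Stages (each writes CSV artifacts plus a JSON manifest under the output
directory, and can be rerun independently):

``simulate``  -> audio/*.wav, truth.csv
``indices``   -> indices.csv (five raw indices + rain metrics per clip)
``qc``        -> qc.csv (rain flag, squared Mahalanobis distance, retained)
``calibrate`` -> scaled_indices.csv, scaling.json, ranking_<resp>.csv,
                 averaged_coefficients_<resp>.csv, inclusion_<resp>.csv,
                 cv_metrics.json
``phenology`` -> gam_predictions.csv (per-index diel/annual smooths)
``propagate`` -> activity_<resp>.csv (propagated activity summaries)
``report``    -> report.json (hour/doy tables, retention, CV metrics)

A single global seed deterministically derives per-stage seeds by stage
name, so stages rerun reproducibly in isolation. All configuration lives
in one YAML file; defaults follow the standard protocol (3-10 kHz band,
Mahalanobis threshold 12, delta-AICc 2, 5x100 CV, k=4 smooths, 1000
Monte Carlo iterations).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from .audio import read_wav
from .gam import CyclicGAM
from .indices import INDEX_COLUMNS, IndexScaler, compute_indices
from .propagate import propagate, summarize
from .qc import MahalanobisScreen, RainClassifier, rain_metrics
from .synth import (
    ActivityModel,
    RecordingSchedule,
    default_activity,
    default_library,
    simulate_corpus,
)

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "indices", "qc", "calibrate", "phenology", "propagate", "report")


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow the standard protocol."""

    output_dir: str = "pipeline_out"
    audio_dir: str = ""  # default: <output_dir>/audio
    seed: int = 0
    # simulation
    sites: list = field(default_factory=lambda: ["T1", "T2", "T3"])
    start_date: str = "2018-01-01"
    end_date: str = "2019-12-31"
    cadence_minutes: int = 10
    day_stride: int = 1
    write_audio: bool = True  # False: stream clips in memory (no WAV files)
    missing_fraction: float = 0.05
    rain_rate: float = 0.08
    fault_rate: float = 0.02
    n_sonotypes: int = 20
    clip_duration: float = 60.0
    sample_rate: float = 44100.0
    noise_floor_db: float = -45.0
    # band & indices
    f_min: float = 3000.0
    f_max: float = 10000.0
    window_length: int = 512
    adi_threshold_db: float = -50.0
    np_peak_threshold: float = 0.01
    # QC
    mahalanobis_threshold: float = 12.0
    rain_safety_factor: float = 0.95
    # calibration
    delta_aicc_max: float = 2.0
    cv_folds: int = 5
    cv_repeats: int = 100
    annotation_fraction: float = 1.0  # share of retained clips "annotated"
    # GAM
    gam_k: int = 4
    lambda_grid: list = field(default_factory=lambda: [-4.0, 6.0, 41])
    # propagation
    n_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    @property
    def audio_path(self) -> Path:
        return Path(self.audio_dir) if self.audio_dir else self.out / "audio"


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2^31."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _manifest(cfg: PipelineConfig, stage: str, outputs: dict[str, int]) -> None:
    cfg.out.mkdir(parents=True, exist_ok=True)
    entry = {
        "stage": stage,
        "seed": stage_seed(cfg.seed, stage),
        "config_sha1": hashlib.sha1(cfg.to_yaml().encode()).hexdigest(),
        "row_counts": outputs,
    }
    with open(cfg.out / f"manifest_{stage}.json", "w") as fh:
        json.dump(entry, fh, indent=2, sort_keys=True)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


# ----------------------------------------------------------------- stages


def _schedule(cfg: PipelineConfig) -> RecordingSchedule:
    return RecordingSchedule(
        sites=tuple(cfg.sites),
        start_date=date.fromisoformat(cfg.start_date),
        end_date=date.fromisoformat(cfg.end_date),
        cadence_minutes=cfg.cadence_minutes,
        missing_fraction=cfg.missing_fraction,
        day_stride=cfg.day_stride,
    )


def stage_simulate(cfg: PipelineConfig) -> pd.DataFrame:
    if not cfg.write_audio:
        raise ValueError(
            "write_audio is false: use the streaming 'all' pipeline (simulate "
            "and indices run fused in memory) or enable write_audio"
        )
    schedule = _schedule(cfg)
    library = default_library(cfg.n_sonotypes)
    activity = default_activity(cfg.n_sonotypes)
    truth = simulate_corpus(
        schedule,
        library,
        activity,
        out_dir=cfg.audio_path,
        rain_rate=cfg.rain_rate,
        fault_rate=cfg.fault_rate,
        seed=stage_seed(cfg.seed, "simulate"),
        duration=cfg.clip_duration,
        sample_rate=cfg.sample_rate,
        noise_floor_db=cfg.noise_floor_db,
    )
    _manifest(cfg, "simulate", {"truth.csv": len(truth)})
    return truth


def index_row(clip, cfg: PipelineConfig) -> dict:
    """Five indices plus rain metrics for one clip (one decode pass)."""
    iv = compute_indices(
        clip,
        f_min=cfg.f_min,
        f_max=cfg.f_max,
        window_length=cfg.window_length,
        adi_threshold=cfg.adi_threshold_db,
        np_peak_threshold=cfg.np_peak_threshold,
    )
    rm = rain_metrics(clip, cfg.window_length)
    row = {
        "clip_id": iv.clip_id,
        "site": clip.site,
        "datetime_iso": clip.timestamp.isoformat() if clip.timestamp else "",
        "hour": clip.timestamp.hour + 1 if clip.timestamp else np.nan,
        "doy": min(clip.timestamp.timetuple().tm_yday, 365)
        if clip.timestamp
        else np.nan,
        "year": clip.timestamp.year if clip.timestamp else np.nan,
        "aci": iv.aci,
        "adi": iv.adi,
        "bi": iv.bi,
        "h": iv.h,
        "np": iv.np_peaks,
        "silent": iv.silent,
        "psd_low": rm.psd_low,
        "psd_mid": rm.psd_mid,
        "snr_low": rm.snr_low,
        "snr_mid": rm.snr_mid,
    }
    return row


def stage_indices(cfg: PipelineConfig, jobs: int = 1) -> pd.DataFrame:
    audio = _require(cfg.audio_path, "simulate")
    paths = sorted(audio.glob("*.wav"))
    if not paths:
        raise FileNotFoundError(f"no WAV files under {audio}")
    if jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=jobs)(
            delayed(lambda p: index_row(read_wav(p), cfg))(p) for p in paths
        )
    else:
        rows = [index_row(read_wav(p), cfg) for p in paths]
    table = pd.DataFrame(rows)
    table.to_csv(cfg.out / "indices.csv", index=False)
    _manifest(cfg, "indices", {"indices.csv": len(table)})
    return table


def stage_stream(cfg: PipelineConfig) -> pd.DataFrame:
    """Fused simulate + indices without writing audio to disk."""
    from .synth import iter_corpus, truth_table

    schedule = _schedule(cfg)
    library = default_library(cfg.n_sonotypes)
    activity = default_activity(cfg.n_sonotypes)
    truths, rows = [], []
    for clip, truth in iter_corpus(
        schedule,
        library,
        activity,
        rain_rate=cfg.rain_rate,
        fault_rate=cfg.fault_rate,
        seed=stage_seed(cfg.seed, "simulate"),
        duration=cfg.clip_duration,
        sample_rate=cfg.sample_rate,
        noise_floor_db=cfg.noise_floor_db,
    ):
        truths.append(truth)
        rows.append(index_row(clip, cfg))
    cfg.audio_path.mkdir(parents=True, exist_ok=True)
    ttab = truth_table(truths)
    ttab.to_csv(cfg.audio_path / "truth.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(cfg.out / "indices.csv", index=False)
    _manifest(cfg, "simulate", {"truth.csv": len(ttab)})
    _manifest(cfg, "indices", {"indices.csv": len(table)})
    return table


def stage_qc(cfg: PipelineConfig) -> pd.DataFrame:
    table = pd.read_csv(_require(cfg.out / "indices.csv", "indices"))
    truth_path = cfg.audio_path / "truth.csv"
    rain_flags = np.zeros(len(table), dtype=bool)
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        known_rain = table["clip_id"].isin(
            truth.loc[truth["rain_flag"], "clip_id"]
        )
        if known_rain.sum() >= 10:
            clf = RainClassifier(safety_factor=cfg.rain_safety_factor).fit(
                table.loc[known_rain, RainClassifier.METRICS]
            )
            rain_flags = clf.predict(table[RainClassifier.METRICS])
    usable = ~table["silent"].astype(bool)
    screen = MahalanobisScreen(threshold=cfg.mahalanobis_threshold).fit(
        table.loc[usable, INDEX_COLUMNS]
    )
    d2 = np.full(len(table), np.inf)
    d2[usable.to_numpy()] = screen.mahalanobis_sq(table.loc[usable, INDEX_COLUMNS])
    qc = table[["clip_id", "psd_low", "psd_mid", "snr_low", "snr_mid"]].copy()
    qc["rain_flag"] = rain_flags
    qc["mahalanobis_sq"] = d2
    qc["qc_label"] = np.where(
        d2 > cfg.mahalanobis_threshold,
        "problematic",
        np.where(rain_flags, "intermediate", "normal"),
    )
    qc["retained"] = (~rain_flags) & (d2 <= cfg.mahalanobis_threshold)
    qc.to_csv(cfg.out / "qc.csv", index=False)
    retained = int(qc["retained"].sum())
    print(
        f"[qc] retained {retained}/{len(qc)} clips "
        f"({100.0 * retained / len(qc):.1f}%)"
    )
    _manifest(cfg, "qc", {"qc.csv": len(qc)})
    return qc


def _retained_scaled(cfg: PipelineConfig) -> tuple[pd.DataFrame, IndexScaler]:
    """Join indices with QC, keep retained clips, scale post-QC."""
    table = pd.read_csv(_require(cfg.out / "indices.csv", "indices"))
    qc = pd.read_csv(_require(cfg.out / "qc.csv", "qc"))
    merged = table.merge(qc[["clip_id", "retained"]], on="clip_id")
    kept = merged[merged["retained"]].reset_index(drop=True)
    scaler = IndexScaler().fit(kept[INDEX_COLUMNS])
    scaled = scaler.transform(kept[INDEX_COLUMNS])
    out = kept[["clip_id", "site", "datetime_iso", "hour", "doy", "year"]].copy()
    out[INDEX_COLUMNS] = scaled
    return out, scaler


def stage_calibrate(cfg: PipelineConfig) -> dict:
    scaled, scaler = _retained_scaled(cfg)
    scaled.to_csv(cfg.out / "scaled_indices.csv", index=False)
    with open(cfg.out / "scaling.json", "w") as fh:
        json.dump(
            {
                c: {"min": float(mn), "max": float(mx)}
                for c, mn, mx in zip(INDEX_COLUMNS, scaler.min_, scaler.max_)
            },
            fh,
            indent=2,
        )
    truth = pd.read_csv(_require(cfg.audio_path / "truth.csv", "simulate"))
    data = scaled.merge(
        truth[["clip_id", "n_sonotypes_15s", "coverage"]], on="clip_id"
    )
    if cfg.annotation_fraction < 1.0:
        rng = np.random.default_rng(stage_seed(cfg.seed, "calibrate"))
        keep = rng.random(len(data)) < cfg.annotation_fraction
        data = data[keep].reset_index(drop=True)
    data["site"] = data["site"].astype(str)
    data["year"] = data["year"].astype(str)
    results = {}
    row_counts = {"scaled_indices.csv": len(scaled)}
    for resp, family, col in (
        ("coverage", "beta_logit", "coverage"),
        ("sonotypes", "poisson_log", "n_sonotypes_15s"),
    ):
        y = data[col].to_numpy(dtype=np.float64)
        if family == "beta_logit":
            y = cal.squeeze_proportions(y)
        ranking = cal.enumerate_models(data, y, family)
        rtab = ranking.table.copy()
        rtab["terms"] = rtab["terms"].map(lambda t: "+".join(t))
        rtab.to_csv(cfg.out / f"ranking_{resp}.csv", index=False)
        averaged = cal.average_models(ranking, data, y, cfg.delta_aicc_max)
        averaged.coef_.rename("coefficient").to_csv(
            cfg.out / f"averaged_coefficients_{resp}.csv"
        )
        averaged.inclusion_counts.rename("n_models").to_csv(
            cfg.out / f"inclusion_{resp}.csv"
        )
        cv = cal.cross_validate(
            data,
            y,
            ranking.best_terms,
            family,
            folds=cfg.cv_folds,
            repeats=cfg.cv_repeats,
            seed=stage_seed(cfg.seed, f"cv_{resp}"),
        )
        results[resp] = {
            "ranking": ranking,
            "averaged": averaged,
            "cv": cv,
            "data": data,
            "y": y,
        }
        row_counts[f"ranking_{resp}.csv"] = len(rtab)
    with open(cfg.out / "cv_metrics.json", "w") as fh:
        json.dump(
            {
                resp: {
                    "rmse_mean": r["cv"].rmse_mean,
                    "rmse_sd": r["cv"].rmse_sd,
                    "mae_mean": r["cv"].mae_mean,
                    "mae_sd": r["cv"].mae_sd,
                }
                for resp, r in results.items()
            },
            fh,
            indent=2,
        )
    _manifest(cfg, "calibrate", row_counts)
    return results


def fit_index_gams(cfg: PipelineConfig) -> dict[str, CyclicGAM]:
    scaled = pd.read_csv(_require(cfg.out / "scaled_indices.csv", "calibrate"))
    scaled["site"] = scaled["site"].astype(str)
    scaled["year"] = scaled["year"].astype(str)
    fits = {}
    for name in INDEX_COLUMNS:
        gam = CyclicGAM(k=cfg.gam_k, lambda_grid=tuple(cfg.lambda_grid))
        fits[name] = gam.fit(scaled, scaled[name].to_numpy())
    return fits


def prediction_grids(cfg: PipelineConfig, scaled: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Diel grid (24 hours x cells at median doy) and annual grid (365 doys)."""
    cells = scaled[["site", "year"]].drop_duplicates().astype(str)
    med_doy = float(scaled["doy"].median())
    med_hour = float(scaled["hour"].median())
    hour_grid = cells.merge(pd.DataFrame({"hour": np.arange(1, 25)}), how="cross")
    hour_grid["doy"] = med_doy
    doy_grid = cells.merge(pd.DataFrame({"doy": np.arange(1, 366)}), how="cross")
    doy_grid["hour"] = med_hour
    return {"hour": hour_grid, "doy": doy_grid}


def stage_phenology(cfg: PipelineConfig) -> pd.DataFrame:
    fits = fit_index_gams(cfg)
    scaled = pd.read_csv(cfg.out / "scaled_indices.csv")
    grids = prediction_grids(cfg, scaled)
    frames = []
    for cycle, grid in grids.items():
        for name, gam in fits.items():
            mean, se = gam.predict_dist(grid)
            g = grid.copy()
            g["cycle"] = cycle
            g["index"] = name
            g["mean"] = mean
            g["se"] = se
            frames.append(g)
    pred = pd.concat(frames, ignore_index=True)
    pred.to_csv(cfg.out / "gam_predictions.csv", index=False)
    _manifest(cfg, "phenology", {"gam_predictions.csv": len(pred)})
    return pred


def _rebuild_averaged(cfg: PipelineConfig, resp: str, family: str, col: str):
    scaled = pd.read_csv(_require(cfg.out / "scaled_indices.csv", "calibrate"))
    truth = pd.read_csv(cfg.audio_path / "truth.csv")
    data = scaled.merge(truth[["clip_id", col]], on="clip_id")
    data["site"] = data["site"].astype(str)
    data["year"] = data["year"].astype(str)
    y = data[col].to_numpy(dtype=np.float64)
    if family == "beta_logit":
        y = cal.squeeze_proportions(y)
    rtab = pd.read_csv(_require(cfg.out / f"ranking_{resp}.csv", "calibrate"))
    rtab["terms"] = rtab["terms"].map(
        lambda s: tuple(s.split("+")) if isinstance(s, str) and s else ()
    )
    ranking = cal.ModelRanking(rtab, family, cal.candidate_terms(), len(y))
    return cal.average_models(ranking, data, y, cfg.delta_aicc_max)


def stage_propagate(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    fits = fit_index_gams(cfg)
    scaled = pd.read_csv(cfg.out / "scaled_indices.csv")
    grids = prediction_grids(cfg, scaled)
    out = {}
    for resp, family, col in (
        ("coverage", "beta_logit", "coverage"),
        ("sonotypes", "poisson_log", "n_sonotypes_15s"),
    ):
        averaged = _rebuild_averaged(cfg, resp, family, col)
        frames = []
        for cycle, grid in grids.items():
            dist = propagate(
                fits,
                averaged,
                grid,
                n_iter=cfg.n_iter,
                seed=stage_seed(cfg.seed, f"propagate_{resp}_{cycle}"),
                response=resp,
            )
            summ = summarize(dist)
            summ["cycle"] = cycle
            frames.append(summ)
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(cfg.out / f"activity_{resp}.csv", index=False)
        out[resp] = table
        _manifest(cfg, "propagate", {f"activity_{resp}.csv": len(table)})
    return out


def stage_report(cfg: PipelineConfig) -> dict:
    qc = pd.read_csv(_require(cfg.out / "qc.csv", "qc"))
    report: dict = {
        "n_clips": int(len(qc)),
        "n_retained": int(qc["retained"].sum()),
        "retention_fraction": float(qc["retained"].mean()),
    }
    cv_path = cfg.out / "cv_metrics.json"
    if cv_path.exists():
        report["cv_metrics"] = json.loads(cv_path.read_text())
    for resp in ("coverage", "sonotypes"):
        path = cfg.out / f"activity_{resp}.csv"
        if not path.exists():
            continue
        act = pd.read_csv(_require(path, "propagate"))
        hourly = (
            act[act["cycle"] == "hour"].groupby("hour")["median"].mean()
        )
        daily = act[act["cycle"] == "doy"].groupby("doy")["median"].mean()
        report[f"{resp}_by_hour"] = {int(k): float(v) for k, v in hourly.items()}
        report[f"{resp}_by_doy"] = {int(k): float(v) for k, v in daily.items()}
    with open(cfg.out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _manifest(cfg, "report", {"report.json": 1})
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "indices": stage_indices,
    "qc": stage_qc,
    "calibrate": stage_calibrate,
    "phenology": stage_phenology,
    "propagate": stage_propagate,
    "report": stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig, **kwargs):
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg.out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](cfg, **kwargs)


def run_all(cfg: PipelineConfig) -> dict:
    if cfg.write_audio:
        stages = STAGES
    else:
        cfg.out.mkdir(parents=True, exist_ok=True)
        stage_stream(cfg)
        stages = STAGES[2:]
    for stage in stages:
        run_stage(stage, cfg)
    return json.loads((cfg.out / "report.json").read_text())
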