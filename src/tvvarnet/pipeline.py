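"""Per-participant pipeline orchestration with reproducible seeds and a manifest.

Stage order: screen (ingest + inclusion rules + segment selection) -> impute
-> standardize -> stationarity test -> bandwidth CV -> tv-VAR fit -> block
bootstrap -> metrics/exports. Every stage writes its outputs under the run
directory; the manifest records the configuration, every seed, and a sha256
checksum of every file so a run can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bandwidth as bw_mod
from . import bootstrap as boot_mod
from . import metrics as metrics_mod
from . import stationarity as stat_mod
from . import tvvar as tvvar_mod
from .datasets import (
    DiaryDataset,
    load_diary_csv,
    screen_inclusion,
    select_longest_segment,
    z_standardize,
)
from .impute import kalman_impute

__all__ = ["RunConfig", "ParticipantExcluded", "run_pipeline", "write_dataset_csv"]


class ParticipantExcluded(RuntimeError):
    """Raised when screening excludes the participant; not a pipeline error."""


@dataclass
class RunConfig:
    """Everything a reproducible per-participant run needs."""

    input_csv: str
    output_dir: str
    date_column: str = "date"
    var_columns: list[str] | None = None
    participant_id: str | None = None
    min_days: int = 130
    max_missing_frac: float = 0.30
    max_gap_days: int = 7
    bandwidth: str | float = "auto"  # "auto" or a fixed value
    candidates: list[float] = field(default_factory=lambda: list(bw_mod.DEFAULT_CANDIDATES))
    n_points: int = 20
    folds: int = 5
    lam: str | float = "auto"
    lam_folds: int = 10
    lam_path: tuple[int, float] = (50, 4.0)
    n_boot: int = 50
    block_length: str | int = "auto"
    stationarity_B: int = 100
    alpha: float = 0.05
    run_stationarity: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in (0, 1]")
        if self.min_days < 2 or self.max_gap_days < 0 or self.n_points < 2:
            raise ValueError("threshold out of documented range")
        self.lam_path = tuple(self.lam_path)  # type: ignore[assignment]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lam_path"] = list(self.lam_path)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_dataset_csv(ds: DiaryDataset, path) -> None:
    """Serialize a dataset in the same wide-CSV dialect the loader reads."""
    df = ds.to_frame()
    df.insert(0, "date", ds.dates.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; return (and write) the run manifest.

    Raises ParticipantExcluded after writing the screening report if the
    inclusion rules fail; any other stage error propagates with partial
    outputs preserved on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(dataclasses.asdict(config))),
                      "stages": {}, "seeds": {"root": config.seed}}
    t0 = time.time()

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p.name) for k, p in files.items()},
            "sha256": {k: _sha256(p) for k, p in files.items()},
            "elapsed_s": round(time.time() - t0, 3),
        }

    # 1. screen: load, inclusion rules, longest analyzable segment
    ds = load_diary_csv(
        config.input_csv, config.date_column, config.var_columns, config.participant_id
    )
    report = screen_inclusion(ds, config.min_days, config.max_missing_frac)
    screen_path = out / "screening.json"
    _dump_json(
        {
            "participant_id": report.participant_id,
            "n_days": report.n_days,
            "missing_frac_per_var": dict(
                zip(ds.var_names, np.round(report.missing_frac_per_var, 6).tolist())
            ),
            "included": report.included,
            "reasons": report.reasons,
        },
        screen_path,
    )
    record("screen", {"screening": screen_path})
    if not report.included:
        _dump_json(manifest, out / "manifest.json")
        raise ParticipantExcluded(
            f"participant {report.participant_id} excluded: {report.reasons}"
        )
    ds = select_longest_segment(ds, config.max_gap_days)

    # 2. impute remaining (short) gaps
    ds = kalman_impute(ds)
    imputed_path = out / "imputed.csv"
    write_dataset_csv(ds, imputed_path)
    record("impute", {"imputed": imputed_path})

    # 3. standardize
    ds, scaling = z_standardize(ds)
    std_path = out / "standardized.csv"
    write_dataset_csv(ds, std_path)
    scaling_path = out / "scaling.json"
    _dump_json(
        {
            "mean": dict(zip(ds.var_names, scaling.mean.tolist())),
            "sd": dict(zip(ds.var_names, scaling.sd.tolist())),
        },
        scaling_path,
    )
    record("standardize", {"standardized": std_path, "scaling": scaling_path})

    # 4. stationarity test
    if config.run_stationarity:
        st = stat_mod.stationarity_test(
            ds,
            [c for c in config.candidates if c < tvvar_mod.STATIONARY_BANDWIDTH],
            B=config.stationarity_B,
            alpha=config.alpha,
            seed=config.seed,
            k=config.folds,
            n_points=config.n_points,
            lam=config.lam,
            lam_folds=config.lam_folds,
            lam_path=config.lam_path,
        )
        st_path = out / "stationarity.json"
        st.to_json(st_path)
        record("stationarity", {"stationarity": st_path})
        manifest["seeds"]["stationarity"] = config.seed

    # 5. bandwidth selection
    if config.bandwidth == "auto":
        cv = bw_mod.cv_select_bandwidth(
            ds,
            config.candidates,
            k=config.folds,
            n_points=config.n_points,
            seed=config.seed,
            lam=config.lam,
            lam_folds=config.lam_folds,
            lam_path=config.lam_path,
        )
        selected_bw = cv.selected
        cv_csv = out / "bandwidth_cv.csv"
        cv.to_frame().to_csv(cv_csv, index=False)
        cv_json = out / "bandwidth.json"
        cv.to_json(cv_json)
        record("bandwidth", {"cv_table": cv_csv, "summary": cv_json})
    else:
        selected_bw = float(config.bandwidth)
        bwp = out / "bandwidth.json"
        _dump_json({"selected": selected_bw, "candidates": None}, bwp)
        record("bandwidth", {"summary": bwp})
    manifest["selected_bandwidth"] = selected_bw

    # 6. final tv-VAR fit
    model = tvvar_mod.fit_tvvar(
        ds,
        selected_bw,
        config.n_points,
        config.lam,
        seed=config.seed,
        lam_folds=config.lam_folds,
        lam_path=config.lam_path,
    )
    model_path = out / "model.json"
    model.to_json(model_path)
    record("fit", {"model": model_path})

    # 7. block bootstrap stability
    ens = boot_mod.bootstrap_tvvar(
        ds,
        selected_bw,
        config.n_points,
        n_boot=config.n_boot,
        block_length=config.block_length,
        seed=config.seed,
        lam=config.lam,
        lam_folds=config.lam_folds,
        lam_path=config.lam_path,
    )
    boot_csv = out / "bootstrap_samples.csv"
    ens.to_frame().to_csv(boot_csv, index=False)
    bands_path = out / "bootstrap_bands.json"
    _dump_json(
        {
            "quantiles": list(ens.quantiles),
            "block_length": ens.block_length,
            "band_low": ens.band_low.tolist(),
            "band_high": ens.band_high.tolist(),
        },
        bands_path,
    )
    record("bootstrap", {"samples": boot_csv, "bands": bands_path})

    # 8. metrics and network exports
    pm = metrics_mod.prediction_errors(model, ds)
    metrics_csv = out / "prediction_metrics.csv"
    pm.to_frame().to_csv(metrics_csv, index=False)
    edges_csv = out / "networks.csv"
    pts = tuple(pt for pt in (2, 10, 19) if pt <= config.n_points) or (1,)
    metrics_mod.export_networks(model, points=pts).to_csv(edges_csv, index=False)
    ranking_csv = out / "edge_variability.csv"
    metrics_mod.edge_variability_ranking(model).to_csv(ranking_csv, index=False)
    summary_path = out / "summary.json"
    _dump_json(
        {
            "participant_id": ds.participant_id,
            "T": ds.T,
            "p": ds.p,
            "selected_bandwidth": selected_bw,
            "mean_r2": pm.mean_r2,
            "mean_rmse": pm.mean_rmse,
        },
        summary_path,
    )
    record(
        "metrics",
        {
            "prediction_metrics": metrics_csv,
            "networks": edges_csv,
            "edge_variability": ranking_csv,
            "summary": summary_path,
        },
    )

    _dump_json(manifest, out / "manifest.json")
    return manifest
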