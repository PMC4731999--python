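"""End-to-end run orchestration: simulate -> preprocess -> analyze -> decode.

A single :class:`RunConfig` (YAML/JSON-serializable) drives every stage with
explicit seeds, producing a deterministic directory of delimited outputs:
ERD role values, PLV group tables, and both decoders' cross-validation
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import generator, preprocessing as pp
from .csp import CSP_BAND, crossval_multicsp
from .ersp import ALPHA_BAND, compute_ersp, erd_by_role
from .paradigm import Limb, SEQUENCE_NAMES, condition_timing, make_schedule
from .plv import initiality_contrast
from .psd import build_features, grouped_svm_rfe
from .stats import report_tables

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "save_epochs", "load_epochs"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all seeds explicit)."""

    condition: int = 2
    n_per_class: int = 20
    seed: int = 0
    output_dir: str = "sclmi_run"
    fs_raw: float = 1000.0
    erd_depth_hand: float = 0.5
    foot_erd_depth: float = 1.0
    prior_hand_boost: float = 1.4
    plv_kappa_initial: float = 2.0
    plv_kappa_noninitial: float = 5.0
    apply_notch: bool = False
    csp_band: tuple[float, float] = CSP_BAND
    erd_band: tuple[float, float] = ALPHA_BAND
    l_grid: tuple[int, ...] = (1, 2, 3, 4)
    folds: int = 10
    rfe_eval_counts: tuple[int, ...] = (1, 2, 4, 6, 8, 10, 14, 20, 30, 46, 62)

    def __post_init__(self) -> None:
        if self.condition not in (1, 2):
            raise ValueError(f"condition must be 1 or 2, got {self.condition}")
        if self.n_per_class < self.folds:
            raise ValueError("n_per_class must be >= folds for stratified CV")

    def generator_params(self) -> generator.GeneratorParams:
        return generator.GeneratorParams(
            fs_raw=self.fs_raw,
            erd_depth={
                Limb.RIGHT_HAND: self.erd_depth_hand,
                Limb.LEFT_HAND: self.erd_depth_hand,
            },
            foot_erd_depth=self.foot_erd_depth,
            prior_hand_boost=self.prior_hand_boost,
            plv_kappa_initial=self.plv_kappa_initial,
            plv_kappa_noninitial=self.plv_kappa_noninitial,
            seed=self.seed,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("csp_band", "erd_band", "l_grid", "rfe_eval_counts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("csp_band", "erd_band", "l_grid", "rfe_eval_counts"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_epochs(epochs: pp.EpochArray, path) -> None:
    """Save an epoch array as a compressed bundle plus its label table."""
    np.savez_compressed(
        path,
        data=epochs.data,
        times=epochs.times,
        labels=np.array(epochs.labels),
        fs=epochs.fs,
        montage=np.array(epochs.montage),
        condition=epochs.timing.condition if epochs.timing else 0,
    )


def load_epochs(path) -> pp.EpochArray:
    with np.load(path, allow_pickle=False) as z:
        condition = int(z["condition"])
        timing = condition_timing(condition) if condition else None
        return pp.EpochArray(
            z["data"],
            z["times"],
            [str(s) for s in z["labels"]],
            float(z["fs"]),
            [str(s) for s in z["montage"]],
            timing,
        )


def _float_frame(d: dict) -> pd.DataFrame:
    return pd.DataFrame(d)


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all artifacts under the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    root = logging.getLogger("sclmi")
    root.addHandler(handler)
    try:
        return _run_all(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all(config: RunConfig, out: Path) -> Path:
    config.to_file(out / "config.yaml")
    timing = condition_timing(config.condition)

    logger.info("stage simulate: condition %d, %d trials/class, seed %d",
                config.condition, config.n_per_class, config.seed)
    schedule = make_schedule(config.condition, config.n_per_class, config.seed)
    params = config.generator_params()
    rec, truth = generator.simulate_recording(schedule, params)
    generator.write_fixture(rec, schedule, out, ground_truth=truth)

    logger.info("stage preprocess")
    rec = pp.read_recording(out / "recording.edf")
    if config.apply_notch:
        rec = pp.notch(rec)
    rec = pp.downsample(rec, params.fs_out)
    rec = pp.apply_car(rec)
    epochs = pp.epoch(rec, schedule)
    save_epochs(epochs, out / "epochs.npz")

    logger.info("stage ersp")
    rows = []
    for task in SEQUENCE_NAMES:
        for electrode in ("C3", "Cz", "C4"):
            tf = compute_ersp(epochs.task(task), electrode, timing, task=task)
            frame = pd.DataFrame(tf.values, index=tf.freqs, columns=tf.times)
            frame.to_csv(out / f"ersp_{task}_{electrode}.csv",
                         index_label="freq_hz")
    erd_table = erd_by_role(epochs, timing, band=config.erd_band)
    erd_table.to_csv(out / "erd_roles.csv", index=False)

    logger.info("stage plv")
    plv_groups = {}
    plv_rows = []
    for limb in Limb:
        ini, non = initiality_contrast(epochs, limb, timing)
        plv_groups[limb] = (ini, non)
        for res in (ini, non):
            plv_rows.append(
                {
                    "limb": limb.value,
                    "pair": "-".join(res.pair),
                    "group": res.group,
                    "n": len(res.per_trial),
                    "mean": res.mean,
                    "sd": float(res.per_trial.std(ddof=1)),
                }
            )
    _float_frame(plv_rows).to_csv(out / "plv_groups.csv", index=False)

    logger.info("stage classify-csp")
    csp_epochs = pp.bandpass(epochs, *config.csp_band)
    mask = epochs.time_mask((0.0, timing.imagery_length_s))
    X = csp_epochs.data[:, :, mask]
    csp_res = crossval_multicsp(
        (X, epochs.labels), config.l_grid, config.folds, config.seed
    )
    _write_cv(out / "csp_report.csv", csp_res, "l")

    logger.info("stage classify-psd")
    feats = build_features(epochs, timing)
    counts = [n for n in config.rfe_eval_counts if n <= len(feats.channels)]
    ranking = grouped_svm_rfe(
        feats, epochs.labels, folds=config.folds, seed=config.seed,
        eval_counts=counts,
    )
    pd.DataFrame(
        {"rank": np.arange(1, len(ranking.ranking) + 1),
         "channel": ranking.ranking}
    ).to_csv(out / "psd_ranking.csv", index=False)
    pd.DataFrame(
        {"n_channels": ranking.eval_counts, "cv_accuracy": ranking.accuracy_curve}
    ).to_csv(out / "psd_curve.csv", index=False)
    _write_cv(out / "psd_report.csv", ranking.best_result, "n_channels")

    logger.info("stage report")
    tables = report_tables(plv_groups=plv_groups)
    for name, table in tables.items():
        table.to_csv(out / f"report_{name}.csv", index=False)
    summary = {
        "condition": config.condition,
        "n_trials": len(schedule),
        "csp_accuracy": csp_res.acc,
        "csp_best_l": int(csp_res.selected),
        "psd_accuracy": ranking.best_result.acc,
        "psd_best_n_channels": int(ranking.best_n),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("run complete: %s", json.dumps(summary))
    return out


def _write_cv(path, result, hyper_name: str) -> None:
    frame = pd.DataFrame(
        {
            "fold": np.arange(1, len(result.fold_accuracies) + 1),
            "accuracy": result.fold_accuracies,
        }
    )
    frame[hyper_name] = result.selected
    frame["mean_accuracy"] = result.acc
    frame.to_csv(path, index=False)
    np.savetxt(
        str(path).replace(".csv", "_confusion.csv"),
        result.confusion,
        fmt="%d",
        delimiter=",",
    )
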