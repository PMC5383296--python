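"""End-to-end experiment orchestration.

``run_experiment`` wires the full pipeline: obtain fingerprint pools
(synthetic or from tables), fix the positive training split, realize
every (ratio, library size, trial) grid cell, train and screen each
configured classifier, tabulate recall/precision/MCC per trial, average
over trials, and derive training-ratio recommendations at the configured
cost-effectiveness thresholds. A manifest with the config hash, seeds
and package version accompanies the outputs, and identical config + seed
reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import ClassifierSpec, fit, predict
from .design import (
    ExperimentDesign,
    assemble_trial,
    cell_seed,
    enumerate_cells,
    split_actives,
)
from .fingerprints import FingerprintMatrix, load_fingerprints
from .metrics import aggregate_trials, evaluate, records_to_frame
from .optimizer import DEFAULT_THRESHOLD, recommend_all
from .synthetic import default_model, sample_actives, sample_decoys

logger = logging.getLogger("screenratio")

_SYNTH_KEYS = {
    "n_actives",
    "n_decoys",
    "k_chemotypes",
    "n_bits",
    "template_density",
    "active_flip_prob",
    "near_active_fraction",
    "near_active_flip_prob",
}
_DATA_KEYS = _SYNTH_KEYS | {"actives_path", "decoys_path", "fingerprint_kind"}
_DESIGN_KEYS = {
    "ratio_grid",
    "library_sizes",
    "n_trials",
    "train_fraction",
}
_TOP_KEYS = {
    "data",
    "design",
    "classifiers",
    "thresholds",
    "output_dir",
    "base_seed",
    "n_workers",
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``data`` either names fingerprint tables (``actives_path``,
    ``decoys_path``) or synthetic-generator parameters (``n_actives``,
    ``n_decoys`` and optional model overrides). Unknown keys anywhere are
    rejected before any computation starts.
    """

    data: dict
    design: ExperimentDesign
    classifiers: list[ClassifierSpec]
    thresholds: list[float] = field(default_factory=lambda: [DEFAULT_THRESHOLD])
    output_dir: str | None = None
    base_seed: int = 0
    n_workers: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.data) - _DATA_KEYS
        if unknown:
            raise ValueError(f"unknown data keys: {sorted(unknown)}")
        has_paths = "actives_path" in self.data
        has_synth = "n_actives" in self.data
        if has_paths == has_synth:
            raise ValueError(
                "data must supply either actives_path/decoys_path or "
                "synthetic n_actives/n_decoys (exactly one)"
            )
        if not self.classifiers:
            raise ValueError("at least one classifier is required")
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be >= 0")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        design_raw = dict(raw.get("design", {}))
        unknown = set(design_raw) - _DESIGN_KEYS
        if unknown:
            raise ValueError(f"unknown design keys: {sorted(unknown)}")
        design = ExperimentDesign(
            base_seed=int(raw.get("base_seed", 0)), **design_raw
        )
        classifiers = [
            ClassifierSpec(c["algorithm"], dict(c.get("params", {})))
            for c in raw.get("classifiers", [])
        ]
        return cls(
            data=dict(raw.get("data", {})),
            design=design,
            classifiers=classifiers,
            thresholds=[float(t) for t in raw.get("thresholds", [DEFAULT_THRESHOLD])],
            output_dir=raw.get("output_dir"),
            base_seed=int(raw.get("base_seed", 0)),
            n_workers=int(raw.get("n_workers", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)


def _load_pools(config: RunConfig) -> tuple[FingerprintMatrix, FingerprintMatrix]:
    d = config.data
    if "actives_path" in d:
        for key in ("actives_path", "decoys_path"):
            if key not in d or not Path(d[key]).exists():
                raise FileNotFoundError(f"data path missing or absent: {key}")
        kind = d.get("fingerprint_kind", "keyed-166")
        actives = load_fingerprints(d["actives_path"], kind)
        decoys = load_fingerprints(d["decoys_path"], kind)
        return actives, decoys
    model_kwargs = {}
    for cfg_key, model_key in (
        ("k_chemotypes", "k"),
        ("n_bits", "d"),
        ("template_density", "template_density"),
        ("active_flip_prob", "active_flip_prob"),
        ("near_active_fraction", "near_active_fraction"),
        ("near_active_flip_prob", "near_active_flip_prob"),
    ):
        if cfg_key in d:
            model_kwargs[model_key] = d[cfg_key]
    model = default_model(seed=config.base_seed, **model_kwargs)
    actives = sample_actives(model, int(d["n_actives"]))
    decoys = sample_decoys(model, int(d["n_decoys"]))
    return actives, decoys


def _config_hash(config: RunConfig) -> str:
    payload = {
        "data": config.data,
        "design": asdict(config.design),
        "classifiers": [
            {"algorithm": c.algorithm, "params": c.params} for c in config.classifiers
        ],
        "thresholds": config.thresholds,
        "base_seed": config.base_seed,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _run_cell(actives, decoys, train_pos_ids, test_pos_ids, classifiers, cell, seed):
    ratio, size, trial = cell
    assembly = assemble_trial(
        train_pos_ids, test_pos_ids, decoys.ids, ratio, size, seed, trial=trial
    )
    train_ids = list(assembly.train_pos_ids) + list(assembly.train_neg_ids)
    train_bits = np.vstack(
        [
            actives.subset(assembly.train_pos_ids).bits,
            decoys.subset(assembly.train_neg_ids).bits,
        ]
    )
    train_labels = np.zeros(len(train_ids), dtype=np.uint8)
    train_labels[: len(assembly.train_pos_ids)] = 1

    active_rows = {cid: i for i, cid in enumerate(actives.ids)}
    decoy_rows = {cid: i for i, cid in enumerate(decoys.ids)}
    test_bits = np.empty((len(assembly.test_ids), actives.width), dtype=np.uint8)
    for i, cid in enumerate(assembly.test_ids):
        if assembly.test_labels[i]:
            test_bits[i] = actives.bits[active_rows[cid]]
        else:
            test_bits[i] = decoys.bits[decoy_rows[cid]]

    records = []
    for spec in classifiers:
        state = fit(spec, train_bits, train_labels, seed=seed,
                    fingerprint_kind=actives.kind)
        pred = predict(state, test_bits)
        records.append(
            evaluate(
                pred,
                assembly.test_labels,
                ratio=ratio,
                library_size=size,
                trial=trial,
                classifier=spec.algorithm,
                fingerprint=actives.kind,
            )
        )
    return records


def run_experiment(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Execute the full grid; returns (results, cell_means, recommendations).

    When ``config.output_dir`` is set, results.csv, cell_means.csv,
    recommendations.csv and manifest.json are written there.
    """
    actives, decoys = _load_pools(config)
    train_pos_ids, test_pos_ids = split_actives(
        actives.ids, config.design.train_fraction, config.base_seed
    )
    cells = enumerate_cells(config.design)
    logger.info(
        "grid: %d cells (%d ratios x %d sizes x %d trials), %d classifiers",
        len(cells),
        len(config.design.ratio_grid),
        len(config.design.library_sizes),
        config.design.n_trials,
        len(config.classifiers),
    )

    seeds = [cell_seed(config.base_seed, *cell) for cell in cells]
    if config.n_workers > 1:
        from joblib import Parallel, delayed

        per_cell = Parallel(n_jobs=config.n_workers)(
            delayed(_run_cell)(
                actives, decoys, train_pos_ids, test_pos_ids,
                config.classifiers, cell, seed,
            )
            for cell, seed in zip(cells, seeds)
        )
    else:
        per_cell = []
        for cell, seed in zip(cells, seeds):
            try:
                per_cell.append(
                    _run_cell(
                        actives, decoys, train_pos_ids, test_pos_ids,
                        config.classifiers, cell, seed,
                    )
                )
            except Exception:
                logger.error("cell %s failed", cell)
                raise
    records = [r for cell_records in per_cell for r in cell_records]

    results = records_to_frame(records)
    cell_means = aggregate_trials(results)
    recs = pd.concat(
        [recommend_all(cell_means, t) for t in config.thresholds],
        ignore_index=True,
    )

    n_deg = int(results["degenerate"].sum())
    if n_deg:
        logger.warning("%d trial(s) had degenerate metrics (flagged)", n_deg)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        cell_means.to_csv(out / "cell_means.csv", index=False)
        recs.to_csv(out / "recommendations.csv", index=False)
        manifest = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "base_seed": config.base_seed,
            "n_cells": len(cells),
            "n_actives": actives.n,
            "n_decoys": decoys.n,
            "train_pos": len(train_pos_ids),
            "test_pos": len(test_pos_ids),
            "fingerprint_kind": actives.kind,
            "classifiers": [c.algorithm for c in config.classifiers],
            "degenerate_trials": n_deg,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return results, cell_means, recs


def report(results_dir, out_dir=None) -> dict:
    """Render summary plots and a machine-readable summary from saved tables.

    Produces, per (classifier, fingerprint), panels of recall, precision
    and MCC versus training ratio (one curve per library size) plus the
    PR trajectory, and cost-effectiveness curves. Returns the summary
    dict; incomplete inputs yield a partial report with warnings.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    results = pd.read_csv(results_dir / "results.csv")
    cell_means = aggregate_trials(results)

    summary = {
        "n_rows": int(len(results)),
        "classifiers": sorted(results["classifier"].unique()),
        "fingerprints": sorted(results["fingerprint"].unique()),
        "library_sizes": sorted(int(s) for s in results["library_size"].unique()),
        "panels": [],
        "warnings": [],
    }
    for (clf, fpk), grp in cell_means.groupby(["classifier", "fingerprint"]):
        fig, axes = plt.subplots(1, 4, figsize=(18, 4))
        for measure, ax in zip(("recall", "precision", "mcc"), axes[:3]):
            for size, sub in grp.groupby("library_size"):
                sub = sub.sort_values("ratio")
                ax.plot(sub["ratio"], sub[measure], marker="o", label=f"{size:,}")
            ax.set_xscale("log")
            ax.set_xlabel("IN/A training ratio")
            ax.set_ylabel(measure.upper() if measure == "mcc" else measure)
            ax.set_ylim(-0.05, 1.05)
        ax = axes[3]
        for size, sub in grp.groupby("library_size"):
            sub = sub.sort_values("ratio")
            ax.plot(sub["recall"], sub["precision"], marker="o", label=f"{size:,}")
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.axvline(0.5, color="grey", lw=0.5)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        axes[0].legend(title="library size", fontsize=7)
        fig.suptitle(f"{clf} / {fpk}")
        fname = f"panel_{clf}_{fpk}.png"
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=100)
        plt.close(fig)
        summary["panels"].append(fname)

    if (results_dir / "recommendations.csv").exists():
        recs = pd.read_csv(results_dir / "recommendations.csv")
        summary["recommendations"] = recs.to_dict(orient="records")
    else:
        summary["warnings"].append("recommendations.csv missing; skipped")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
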