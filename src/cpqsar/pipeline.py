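"""End-to-end pipeline: descriptors -> alerts -> selection -> train -> evaluate -> maps.

A run is configured by a :class:`RunConfig` (usually loaded from YAML),
executed into a staging directory and atomically moved to the output
directory on success, so failures never leave partial artifact sets behind.
A manifest records the package version, rulebase version, seed and a hash
of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alerts import annotate_dataset, group_label, load_rulebase, match_alerts
from .cpann import CPANNClassifier, save_model
from .descriptors import compute_descriptor_block
from .maps import class_surface, layer_to_csv, top_map, weight_level_map
from .records import read_structures, write_descriptor_csv
from .scaling import apply_normalization, fit_normalization
from .selection import select_descriptors
from .validation import cross_validate, evaluate, stratified_split

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    structures: str
    labels: str | None = None  # CSV: id,class_label
    output_dir: str = "cpqsar_run"
    rulebase: str | None = None
    seed: int = 0
    test_fraction: float = 0.2
    cv_folds: int = 5
    corr_threshold: float = 0.9
    n_descriptors: int | None = None
    nx: int = 35
    ny: int = 35
    epochs: int = 200
    eta_max: float = 0.5
    eta_min: float = 0.01
    topology: str = "planar"
    neighborhood: str = "triangular"
    output_encoding: str = "numeric_class"
    strict_parse: bool = False

    KNOWN_KEYS = None  # filled below

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.structures).is_file():
            raise ConfigError(f"structures file not found: {self.structures}")
        if self.labels and not Path(self.labels).is_file():
            raise ConfigError(f"labels file not found: {self.labels}")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_labels(path: str) -> dict[str, int]:
    import csv as _csv

    out: dict[str, int] = {}
    with open(path) as fh:
        for row in _csv.DictReader(fh):
            out[row["id"]] = int(row["class_label"])
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out_dir = Path(config.output_dir)
    if out_dir.exists():
        raise ConfigError(f"output directory already exists: {out_dir}")

    staging = Path(tempfile.mkdtemp(prefix="cpqsar_staging_"))
    try:
        _run_stages(config, staging)
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(str(staging), str(out_dir))
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return out_dir


def _run_stages(config: RunConfig, staging: Path) -> None:
    def stage(name):
        logger.info("stage: %s", name)

    stage("read structures")
    records = read_structures(config.structures, strict=config.strict_parse)
    if config.labels:
        labels_by_id = _read_labels(config.labels)
        for rec in records:
            rec.class_label = labels_by_id.get(rec.id)
    records = [r for r in records if r.class_label in (1, 2)] or records

    stage("descriptors")
    matrix = compute_descriptor_block(records)
    write_descriptor_csv(matrix, staging / "descriptors.csv")

    stage("alerts")
    rb = load_rulebase(config.rulebase)
    table, proportions = annotate_dataset(records, rb)
    table.to_csv(staging / "alert_tally.csv")
    groups = {r.id: group_label(match_alerts(r, rb)) for r in records}
    (staging / "alert_summary.json").write_text(
        json.dumps({"proportions": proportions, "groups": groups}, indent=2)
    )

    y = np.array([r.class_label for r in records])
    have_labels = set(np.unique(y)) == {1, 2}

    stage("selection")
    if have_labels:
        report = select_descriptors(matrix, y, config.corr_threshold, config.n_descriptors)
        (staging / "selection.json").write_text(
            json.dumps(
                {"kept": report.kept, "dropped": report.dropped, "fisher": report.fisher},
                indent=2,
            )
        )
        keep_idx = [matrix.column_names.index(c) for c in report.kept]
        matrix = dataclasses.replace(
            matrix,
            values=matrix.values[:, keep_idx],
            column_names=report.kept,
            norm=None,
        )

    stage("normalize + split + train")
    params = fit_normalization(matrix)
    norm = apply_normalization(matrix, params)
    clf = CPANNClassifier(
        nx=config.nx,
        ny=config.ny,
        epochs=config.epochs,
        eta_max=config.eta_max,
        eta_min=config.eta_min,
        topology=config.topology,
        neighborhood=config.neighborhood,
        output_encoding=config.output_encoding,
        random_state=config.seed,
    )
    results: dict[str, object] = {}
    if have_labels:
        train_idx, test_idx = stratified_split(norm.values, y, config.test_fraction, config.seed)
        clf.fit(norm.values[train_idx], y[train_idx])
        results["train_accuracy"] = evaluate(clf, norm.values[train_idx], y[train_idx]).accuracy
        results["test_accuracy"] = evaluate(clf, norm.values[test_idx], y[test_idx]).accuracy
        cv = cross_validate(
            clf, norm.values[train_idx], y[train_idx], folds=config.cv_folds, seed=config.seed
        )
        results["cv_accuracy_pooled"] = cv.accuracy
        results["cv_accuracy_mean_fold"] = cv.mean_fold_accuracy
    else:
        clf.fit(norm.values, np.ones(len(norm.values), dtype=int))
    clf.model_.norm = params
    clf.model_.column_names = list(norm.column_names)
    save_model(clf.model_, staging / "model.npz")
    (staging / "evaluation.json").write_text(json.dumps(results, indent=2))

    stage("maps")
    maps_dir = staging / "maps"
    maps_dir.mkdir()
    tm = top_map(clf, norm.values, norm.row_ids)
    np.savetxt(maps_dir / "top_map_counts.csv", tm.counts, delimiter=",", fmt="%d")
    for name in norm.column_names:
        safe = name.replace("/", "_")
        layer_to_csv(weight_level_map(clf, name), maps_dir / f"weights_{safe}.csv")
    if have_labels:
        layer_to_csv(class_surface(clf), maps_dir / "class_surface.csv")

    manifest = {
        "package_version": __version__,
        "rulebase_version": rb.version,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "n_molecules": len(records),
    }
    (staging / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
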