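"""End-to-end pipeline: (optional) quantification -> connectivity -> reports.

Every run writes, under the output directory:

* ``uptake_table.tsv``      (only when section-level input is quantified)
* ``edges_<seed>.tsv``      one per seed — target, group, vip, sd, ci, call,
  and the between-group comparison columns
* ``label_matrix.tsv``      seeds x regions classification matrix
* ``labels_triplets.tsv``   (seed, target, label) listing for plotting tools
* ``manifest.json``         config echo, package version, input/output
  checksums and per-stage record counts — written last, so its presence
  marks a completed run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .connectivity import DEFAULT_SEEDS, SeedConnectivity
from .exceptions import ConfigurationError
from .io import load_sections, load_standards, load_uptake_table, write_table
from .lcgu import fit_calibration, uptake_table_from_sections

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one reproducible pipeline run."""

    output_dir: str
    uptake_path: str | None = None
    sections_path: str | None = None
    standards_path: str | None = None
    seeds: Sequence[str] = DEFAULT_SEEDS
    n_components: int = 2
    vip_threshold: float = 0.8
    ci_level: float = 0.95
    alpha: float = 0.05
    family: str = "per_seed"
    criterion: str = "ci_lower"
    control_label: str | None = None
    denominator: str = "per_roi"
    rng_seed: int = 0

    def __post_init__(self):
        if self.uptake_path is None and self.sections_path is None:
            raise ConfigurationError("either uptake_path or sections_path is required")
        if self.vip_threshold <= 0:
            raise ConfigurationError("vip_threshold must be > 0")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs, outputs, counts = {}, {}, {}

    try:
        if config.sections_path is not None:
            sections = load_sections(config.sections_path)
            inputs["sections"] = _sha256(Path(config.sections_path))
            calibration = None
            if config.standards_path is not None:
                calibration = fit_calibration(load_standards(config.standards_path))
                inputs["standards"] = _sha256(Path(config.standards_path))
            table = uptake_table_from_sections(
                sections, calibration=calibration, denominator=config.denominator
            )
            write_table(table, out / "uptake_table.tsv")
            outputs["uptake_table.tsv"] = _sha256(out / "uptake_table.tsv")
        else:
            table = load_uptake_table(config.uptake_path)
            inputs["uptake"] = _sha256(Path(config.uptake_path))
        counts["animals"] = int(table.shape[0])
        counts["regions"] = int(table.shape[1] - 2)
    except Exception:
        logger.exception("pipeline stage 'quantify/load' failed")
        raise

    try:
        model = SeedConnectivity(
            seeds=tuple(config.seeds),
            n_components=config.n_components,
            vip_threshold=config.vip_threshold,
            ci_level=config.ci_level,
            alpha=config.alpha,
            family=config.family,
            criterion=config.criterion,
            control_label=config.control_label,
        ).fit(table)
    except Exception:
        logger.exception("pipeline stage 'connectivity' failed")
        raise

    for seed in config.seeds:
        edges = model.edges_[model.edges_["seed"] == seed]
        comp = model.comparisons_[model.comparisons_["seed"] == seed]
        merged = edges.merge(comp.drop(columns="seed"), on="target", how="left")
        name = f"edges_{seed}.tsv"
        write_table(merged, out / name)
        outputs[name] = _sha256(out / name)
    counts["comparisons"] = int(model.comparisons_.shape[0])

    labels = model.labels_.reset_index(names="seed")
    write_table(labels, out / "label_matrix.tsv")
    outputs["label_matrix.tsv"] = _sha256(out / "label_matrix.tsv")

    triplets = model.comparisons_[["seed", "target", "label"]]
    write_table(triplets, out / "labels_triplets.tsv")
    outputs["labels_triplets.tsv"] = _sha256(out / "labels_triplets.tsv")

    manifest = {
        "config": dataclasses.asdict(config) | {"seeds": list(config.seeds)},
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "groups": {"control": model.groups_[0], "treated": model.groups_[1]},
        "family_size": model.family_size_,
        "inputs_sha256": inputs,
        "outputs_sha256": outputs,
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
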