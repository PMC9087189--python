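"""End-to-end report runs: load → curate → evaluate → summarize → export.

A run is described by a :class:`RunConfig`; outputs are a Table-style
summary CSV, a per-drug evaluation CSV, scatter data (CSV and PNG), and
a run log echoing the configuration and exclusion counts. Every CSV
carries a comment header with the schema version and a fingerprint of
the configuration, so any output file identifies the run that made it.
Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .evaluation import (
    ClassSummary,
    EvaluationRow,
    bootstrap_ci,
    evaluate,
    export_scatter,
    format_pct,
    summarize,
)
from .records import apply_exclusions, read_records
from .scaling import Method, SpeciesRegistry, load_species_config

__all__ = ["RunConfig", "ReportBundle", "run_report", "SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    input_csv: str
    output_dir: str
    method: str = "bsa"  # bsa | bw | auto | both
    fold_thresholds: tuple[float, ...] = (2.0, 3.0)
    grouping: str = "standard"  # standard | none
    n_bootstrap: int = 0
    seed: int = 0
    species_config: str | None = None

    def __post_init__(self) -> None:
        if self.method not in {"bsa", "bw", "auto", "both"}:
            raise ValueError(
                f"unknown method {self.method!r}; use bsa, bw, auto or both"
            )
        if any(k < 1 for k in self.fold_thresholds):
            raise ValueError("fold thresholds must be ≥ 1")
        if self.grouping not in {"standard", "none"}:
            raise ValueError(f"unknown grouping {self.grouping!r}")

    def fingerprint(self) -> str:
        # analysis parameters only: where outputs land must not change them
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class ReportBundle:
    summary_csv: Path
    per_drug_csv: Path
    scatter_csv: Path
    scatter_png: Path
    run_log: Path


def _header_lines(config: RunConfig) -> list[str]:
    return [
        f"xenodose v{__version__} schema={SCHEMA_VERSION} "
        f"config={config.fingerprint()} seed={config.seed}",
    ]


def _write_csv(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def _summary_frame(
    summaries: Sequence[ClassSummary],
    rows: Sequence[EvaluationRow],
    config: RunConfig,
) -> pd.DataFrame:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else format_pct(x)

    data = {
        "class": [s.class_label for s in summaries],
        "subclass": [s.subclass_label for s in summaries],
        "n": [s.n for s in summaries],
        "pct_within_2x_bsa": [fmt(s.pct_within_2x_bsa) for s in summaries],
        "pct_within_3x_bsa": [fmt(s.pct_within_3x_bsa) for s in summaries],
        "pct_within_2x_bw": [fmt(s.pct_within_2x_bw) for s in summaries],
        "pct_within_3x_bw": [fmt(s.pct_within_3x_bw) for s in summaries],
    }
    return pd.DataFrame(data)


def run_report(config: RunConfig) -> ReportBundle:
    """Execute a full evaluation run and write the report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    registry = (
        load_species_config(config.species_config)
        if config.species_config
        else None
    )
    records = read_records(config.input_csv, registry=registry)
    kept, excluded = apply_exclusions(records)
    if not kept:
        raise ValueError("no records remain after curation exclusions")

    if config.method == "both":
        rows = evaluate(kept, Method.BSA) + evaluate(kept, Method.BW)
    else:
        rows = evaluate(kept, config.method)

    summaries = summarize(rows) if config.grouping == "standard" else summarize(
        rows,
        [("All", "all", lambda c: True, True)],
    )

    per_drug = pd.DataFrame(
        {
            "drug_name": [r.drug_name for r in rows],
            "modality_class": [r.modality_class.value for r in rows],
            "method": [r.method.value for r in rows],
            "predicted_dose_mgkg": [r.predicted_dose for r in rows],
            "clinical_dose_mgkg": [r.clinical_dose for r in rows],
            "fold_error": [r.fold_error for r in rows],
            "within_2x": [r.within_2x for r in rows],
            "within_3x": [r.within_3x for r in rows],
        }
    )

    bundle = ReportBundle(
        summary_csv=outdir / "summary.csv",
        per_drug_csv=outdir / "per_drug.csv",
        scatter_csv=outdir / "scatter.csv",
        scatter_png=outdir / "scatter.png",
        run_log=outdir / "run.log",
    )

    _write_csv(_summary_frame(summaries, rows, config), bundle.summary_csv, config)
    _write_csv(per_drug, bundle.per_drug_csv, config)
    export_scatter(
        rows,
        bundle.scatter_csv,
        bundle.scatter_png,
        header_lines=_header_lines(config),
    )

    log_lines = [
        *_header_lines(config),
        f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}",
        f"records loaded: {len(records)}",
        f"records kept: {len(kept)}",
        f"records excluded: {len(excluded)}",
    ]
    for rec, reason in excluded:
        log_lines.append(f"excluded: {rec.drug_name} ({reason})")
    if config.n_bootstrap:
        for k in config.fold_thresholds:
            low, high = bootstrap_ci(
                rows, k, n_boot=config.n_bootstrap, seed=config.seed
            )
            log_lines.append(
                f"bootstrap 95% CI, within {k:g}x (all rows, "
                f"{config.n_bootstrap} resamples): "
                f"[{format_pct(low)}, {format_pct(high)}]"
            )
    bundle.run_log.write_text("\n".join(log_lines) + "\n")
    log.info("report written to %s", outdir)
    return bundle
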