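"""End-to-end analysis pipeline and input validation.

Ties the stages together for one trial: read/validate events (and
optionally markers), segment cycles, classify fore-hind coordination and
compute circular statistics, decompose support periods, compute spatial
measures, and assemble a JSON-serializable report bundle. Deterministic
given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import coordination, spatial, support
from .events import (GaitEventTable, GaitValidationError, TrialMeta,
                     read_event_table, segment_all, temporal_summary,
                     temporal_variables, validate_events)
from .stats import asymmetry_table

logger = logging.getLogger(__name__)


def _records(df: pd.DataFrame) -> list[dict]:
    """DataFrame rows as JSON-safe plain-Python records (NaN -> None)."""
    if df.empty:
        return []
    return json.loads(df.to_json(orient="records"))


class RunConfig(BaseModel):
    """Configuration of one analysis run (deserializable from YAML/JSON)."""

    events_path: str
    markers_path: str | None = None
    marker_dialect: str = "wide"
    px_to_m: float | None = None
    belt_speed: float = Field(default=0.4, gt=0)
    frame_rate: float = Field(default=60.0, ge=0)
    subject: str = "subject"
    state: str = "intact"
    fore: str = "RF"
    hind: str = "RH"
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute events -> coordination -> support -> spatial -> summary.

    Returns the report bundle (plain dicts/lists, JSON-serializable) and,
    when ``config.outdir`` is set, writes ``report.json`` plus the tidy
    CSV tables there. Any stage's validation error aborts with the stage
    name and offending records.
    """
    meta = TrialMeta(belt_speed=config.belt_speed, frame_rate=config.frame_rate,
                     subject=config.subject, state=config.state)
    try:
        table = read_event_table(config.events_path, meta)
    except GaitValidationError as err:
        raise RuntimeError(
            f"stage events: validation failed: {err.violations}") from err
    logger.info("events: %d rows across %d limbs", len(table.events),
                table.events["limb"].nunique())

    markers = None
    if config.markers_path:
        markers = spatial.read_marker_table(
            config.markers_path, dialect=config.marker_dialect,
            px_to_m=config.px_to_m)
        logger.info("markers: %d frames, %d columns", len(markers),
                    markers.shape[1])

    cycles = segment_all(table)
    tidy = temporal_variables(cycles, meta)
    summary = temporal_summary(tidy)
    logger.info("temporal: %d cycles", len(tidy))

    classification = coordination.classify_fore_hind(
        table, config.fore, config.hind)
    prop = coordination.proportion_2to1(classification)
    prop12 = coordination.proportion_of(classification, coordination.LABEL_12)
    samples = coordination.phase_intervals(
        table, config.fore, config.hind, classification)
    summaries = coordination.circular_summaries_by_label(samples)
    phase_df = coordination.phase_table(samples, meta,
                                        f"{config.fore}/{config.hind}")
    logger.info("coordination: %d classified cycles, %d phase samples",
                int((classification["label"] != "unclassified").sum()),
                len(samples))

    decomps = support.decompose_trial(table, cycles.get(config.hind, []))
    support_df = support.decompositions_to_frame(decomps, meta)
    support_agg = support.aggregate_support(support_df)
    logger.info("support: %d complete of %d cycles",
                support_df["cycle_idx"].nunique() if not support_df.empty else 0,
                len(decomps))

    spatial_df = pd.DataFrame()
    if markers is not None and "time_s" in markers.columns:
        spatial_df = spatial.spatial_summary(cycles, markers, config.belt_speed)
        logger.info("spatial: %d cycle rows", len(spatial_df))

    asym = asymmetry_table(summary)

    report = {
        "meta": dataclasses.asdict(meta),
        "temporal": _records(tidy),
        "temporal_summary": _records(summary),
        "classification": _records(classification),
        "proportion_2to1": dataclasses.asdict(prop),
        "proportion_1to2": dataclasses.asdict(prop12),
        "phase_samples": _records(phase_df),
        "circular_summaries": {label: dataclasses.asdict(s)
                               for label, s in summaries.items()},
        "support": _records(support_df),
        "support_aggregate": _records(support_agg),
        "spatial": _records(spatial_df),
        "asymmetry": _records(asym),
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, allow_nan=True))
        tidy.to_csv(outdir / "temporal.csv", index=False)
        phase_df.to_csv(outdir / "phases.csv", index=False)
        support_df.to_csv(outdir / "support.csv", index=False)
        if not spatial_df.empty:
            spatial_df.to_csv(outdir / "spatial.csv", index=False)
        asym.to_csv(outdir / "asymmetry.csv", index=False)
    return report


def validate_inputs(paths: list) -> list[dict]:
    """Per-file validation report: ``{path, ok, errors}`` entries.

    Event CSVs are checked against the structural invariants with
    row-level diagnostics; unreadable files fail their entry rather than
    raising.
    """
    out = []
    for path in paths:
        entry = {"path": str(path), "ok": False, "errors": []}
        try:
            df = pd.read_csv(path)
        except Exception as err:  # unreadable/malformed file
            entry["errors"].append({"row": None, "message": str(err)})
            out.append(entry)
            continue
        violations = validate_events(df)
        entry["errors"] = violations
        entry["ok"] = not violations
        out.append(entry)
    return out
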