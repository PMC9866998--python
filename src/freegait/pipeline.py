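"""End-to-end orchestration from raw CSV (or simulation) to result tables."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .bouts import extract_walking_bouts, window_bouts
from .characteristics import compute_step_table
from .config import PipelineConfig
from .context import (
    ContextualWindow,
    align_context,
    attach_anomalies,
    contextual_summary,
    review_manifest,
)
from .events import detect_events
from .io import (
    read_accel_csv,
    read_context_csv,
    write_accel_csv,
    write_context_csv,
    write_ground_truth_json,
    write_step_table,
)
from .simulate import SimParams, simulate_recording, simulate_walk
from .summary import DOMAIN_ROWS, WindowSummary, flag_anomalies, stratify_domains, summarize_window
from .types import AccelRecording, ContextLabel, FreegaitError

log = logging.getLogger("freegait")


@dataclass
class RunRecord:
    """Provenance of a pipeline run: config, inputs, per-stage counts."""

    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    status: str = "ok"
    failure_reason: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run."""

    bouts: list
    windows: list
    step_table: pd.DataFrame
    summaries: list
    contextual_windows: list
    flags: list
    record: RunRecord

    @property
    def n_steps(self) -> int:
        return len(self.step_table)


def run_on_recording(
    rec: AccelRecording,
    track: Optional[Sequence[ContextLabel]] = None,
    cfg: Optional[PipelineConfig] = None,
    recording_id: str = "rec",
) -> PipelineResult:
    """Run bout -> event -> characteristic -> summary stages on a recording."""
    cfg = cfg or PipelineConfig()
    record = RunRecord(config=cfg.to_dict())

    bouts = extract_walking_bouts(rec, cfg, recording_id=recording_id)
    windows = window_bouts(bouts, cfg.window_s)

    tables = []
    n_low_quality = 0
    for i, bout in enumerate(bouts):
        ev, v, _ = detect_events(rec, bout, cfg, source_bout=f"{recording_id}-b{i}")
        if ev.n_ic < 2:
            continue
        n_low_quality += int(ev.low_quality)
        tbl = compute_step_table(v, ev, cfg)
        tbl["bout_id"] = f"{recording_id}-b{i}"
        tables.append(tbl)
    step_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["ic_time", "side", "step_time", "stance_time", "swing_time",
                     "step_length", "step_velocity", "bout_id"]
        )
    )

    summaries: list[WindowSummary] = []
    n_dropped = 0
    for w in windows:
        ws = summarize_window(step_table, w, cfg)
        if ws is None:
            n_dropped += 1
        else:
            summaries.append(ws)

    flags = flag_anomalies(step_table, cfg.anomaly_k) if len(step_table) else []
    cws = align_context(summaries, list(track) if track else [])
    attach_anomalies(cws, flags, step_table["ic_time"].to_numpy(dtype=float))

    record.counts = {
        "n_samples": rec.n_samples,
        "n_bouts": len(bouts),
        "n_windows": len(windows),
        "n_windows_summarized": len(summaries),
        "n_windows_dropped": n_dropped,
        "n_steps": len(step_table),
        "n_low_quality_bouts": n_low_quality,
        "n_anomaly_flags": len(flags),
    }
    return PipelineResult(
        bouts=bouts, windows=windows, step_table=step_table,
        summaries=summaries, contextual_windows=cws, flags=flags, record=record,
    )


def _checksum(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    accel_path: Union[str, Path],
    context_path: Optional[Union[str, Path]] = None,
    config_path: Optional[Union[str, Path]] = None,
    out_dir: Union[str, Path] = "freegait_out",
    units: str = "m_per_s2",
) -> Path:
    """File-level pipeline: read inputs, run all stages, write result files.

    Writes ``steps.csv``, ``bouts.csv``, ``window_summaries.csv``,
    ``domain_table.csv``, ``anomalies.csv``, ``run_record.json`` and, when
    context labels are given, ``contextual_summary.csv`` plus the review
    manifest (CSV and JSON).  On failure, partial outputs are removed and
    the RunRecord is retained with the failure reason.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_json(config_path) if config_path else PipelineConfig()
    record = RunRecord(config=cfg.to_dict())
    written: list[Path] = []
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        rec = read_accel_csv(accel_path, units=units, fs="infer")
        record.input_checksums[str(accel_path)] = _checksum(accel_path)
        track = None
        if context_path is not None:
            track = read_context_csv(context_path)
            record.input_checksums[str(context_path)] = _checksum(context_path)

        result = run_on_recording(rec, track, cfg)
        record.counts = result.record.counts

        write_step_table(out / "steps.csv", result.step_table)
        written.append(out / "steps.csv")
        pd.DataFrame(
            [{"start": b.start, "end": b.end} for b in result.bouts]
        ).to_csv(out / "bouts.csv", index=False)
        written.append(out / "bouts.csv")

        rows = []
        for ws in result.summaries:
            row = {"start": ws.window.start, "end": ws.window.end, "n_steps": ws.n_steps}
            for (char, stat), val in ws.values.items():
                row[f"{char}_{stat}"] = val
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "window_summaries.csv", index=False, float_format="%.9g")
        written.append(out / "window_summaries.csv")

        if result.summaries:
            dt = pd.concat(
                [
                    stratify_domains(ws).assign(window_start=ws.window.start)
                    for ws in result.summaries
                ],
                ignore_index=True,
            )
        else:
            dt = pd.DataFrame(columns=["domain", "characteristic", "value", "window_start"])
        dt.to_csv(out / "domain_table.csv", index=False, float_format="%.9g")
        written.append(out / "domain_table.csv")

        pd.DataFrame(
            result.flags, columns=["step_index", "characteristic", "score"]
        ).to_csv(out / "anomalies.csv", index=False, float_format="%.9g")
        written.append(out / "anomalies.csv")

        if track is not None and result.contextual_windows:
            cs = contextual_summary(result.contextual_windows)
            cs.to_csv(out / "contextual_summary.csv", float_format="%.9g")
            written.append(out / "contextual_summary.csv")
            manifest = review_manifest(
                result.contextual_windows, top_n=10, video_offset_s=cfg.video_offset_s
            )
            manifest.to_csv(out / "review_manifest.csv", index=False, float_format="%.9g")
            (out / "review_manifest.json").write_text(
                manifest.to_json(orient="records", indent=2) + "\n"
            )
            written.extend([out / "review_manifest.csv", out / "review_manifest.json"])
    except FreegaitError as exc:
        record.status = "failed"
        record.failure_reason = str(exc)
        for p in written:
            p.unlink(missing_ok=True)
        (out / "run_record.json").write_text(record.to_json() + "\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    (out / "run_record.json").write_text(record.to_json() + "\n")
    return out


def simulate_to_dir(
    params: SimParams,
    out_dir: Union[str, Path],
    schedule: Optional[Sequence] = None,
) -> Path:
    """Write a simulated dataset (accel CSV, truth JSON, context CSV).

    Without a schedule, a single continuous walk of ``params.duration_s``
    is generated (context: one lab walk segment).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if schedule is None:
        rec, truth = simulate_walk(params)
        labels = [
            ContextLabel(0.0, params.duration_s, terrain="lab",
                         environment="indoor", task="single", notes="walk")
        ]
    else:
        rec, truth, labels = simulate_recording(schedule, params)
    write_accel_csv(out / "accel.csv", rec)
    write_ground_truth_json(out / "truth.json", truth)
    write_context_csv(out / "context.csv", labels)
    return out
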