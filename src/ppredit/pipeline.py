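"""End-to-end off-target pipeline: reference filter -> replicate-consensus
calling -> pooled filters -> context extraction -> labelling -> consensus
profile -> matching-score annotation -> reports.

Configuration is a plain mapping (or YAML file).  Every artifact written
carries the configuration hash in a leading comment line so a results
directory can be audited against the parameters that produced it; the log
records the thresholds actually applied and per-stage record counts.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as pio
from .calling import (
    ConfigurationError,
    FilterThresholds,
    call_offtargets,
    calls_table,
    reference_filter,
)
from .profile import build_profile, matching_score, max_score

__all__ = ["pipeline_run", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "min_reads": 10,
    "min_replicates": 2,
    "min_coverage": 20,
    "min_rate": 0.015,
    "ref_c_min": 0.99,
    "ref_t_max": 0.005,
    "min_edited": 2,
    "per_rep_min_rate": 0.01,
    "upstream": 30,
    "downstream": 5,
    "profile_bounds": [-17, 5],
    "dedupe": True,
}


def pipeline_run(config: Mapping | str | Path,
                 out_dir: str | Path | None = None) -> dict[str, Path]:
    """Run the pipeline described by ``config``; returns artifact paths.

    Required config keys: ``transcriptome_fasta``, ``annotation``,
    ``pileups`` and (unless ``out_dir`` is passed) ``out_dir``.  Optional
    keys override :data:`DEFAULT_CONFIG`.  Aborts with
    :class:`~ppredit.calling.ConfigurationError` before any calling when the
    pileups contain no control replicates.
    """
    if not isinstance(config, Mapping):
        config = pio.read_config(config)
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    for key in ("transcriptome_fasta", "annotation", "pileups"):
        if key not in cfg:
            raise ConfigurationError(f"config is missing required key {key!r}")
    out = Path(out_dir or cfg.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)
    # the output location is not an analysis parameter
    chash = pio.config_hash({k: v for k, v in cfg.items() if k != "out_dir"})
    stamp = f"config_hash={chash}"
    logger.info("pipeline start (config hash %s)", chash)

    annotations = list(
        pio.read_transcriptome(cfg["transcriptome_fasta"], cfg["annotation"]).values()
    )
    logger.info("stage reference_filter: %d transcripts in, min_reads=%s",
                len(annotations), cfg["min_reads"])
    kept = reference_filter(annotations, min_reads=cfg["min_reads"])
    logger.info("stage reference_filter: %d transcripts retained", len(kept))
    kept_ids = {a.transcript_id for a in kept}

    pileups = pio.read_pileups(cfg["pileups"])
    if not (pileups["group"] == "control").any():
        raise ConfigurationError(
            "pileups contain no control replicates; aborting before calling"
        )
    pileups = pileups[pileups["transcript_id"].isin(kept_ids)].reset_index(drop=True)

    thresholds = FilterThresholds(
        min_replicates=int(cfg["min_replicates"]),
        min_coverage=int(cfg["min_coverage"]),
        min_rate=float(cfg["min_rate"]),
        ref_c_min=float(cfg["ref_c_min"]),
        ref_t_max=float(cfg["ref_t_max"]),
        min_edited=int(cfg["min_edited"]),
        per_rep_min_rate=float(cfg["per_rep_min_rate"]),
    )
    logger.info("stage call: thresholds %s", thresholds)
    calls, audit = call_offtargets(
        pileups,
        {a.transcript_id: a for a in kept},
        thresholds=thresholds,
        upstream=int(cfg["upstream"]),
        downstream=int(cfg["downstream"]),
    )
    logger.info("stage call: %d candidates, %d passed all filters",
                len(audit), len(calls))

    artifacts: dict[str, Path] = {}
    audit_path = out / "candidates_audit.tsv"
    pio._write_tsv(audit_path, audit, header_comment=stamp)
    artifacts["audit"] = audit_path

    if calls:
        windows = [c.context for c in calls]
        lo, hi = (int(b) for b in cfg["profile_bounds"])
        profile = build_profile(windows, bounds=(lo, hi), dedupe=bool(cfg["dedupe"]))
        mx = max_score(profile)
        logger.info("stage profile: bounds [%d..%d], max score %d", lo, hi, mx)
        calls = [
            replace(c, matching_score=matching_score(c.context, profile))
            for c in calls
        ]
        profile_path = out / "profile.tsv"
        pio.write_profile(profile_path, profile, header_comment=stamp)
        artifacts["profile"] = profile_path
        windows_path = out / "windows.tsv"
        pio.write_windows(windows_path, windows)
        artifacts["windows"] = windows_path

    report = calls_table(calls)
    report = report.sort_values("editing_percent", ascending=False).reset_index(drop=True)
    report_path = out / "calls.tsv"
    pio._write_tsv(report_path, report, header_comment=stamp)
    artifacts["calls"] = report_path

    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "config_hash": chash,
        "counts": {
            "transcripts_in": len(annotations),
            "transcripts_kept": len(kept),
            "candidates": int(len(audit)),
            "calls": int(len(calls)),
        },
    }
    manifest_path = out / "manifest.yaml"
    pio.write_config(manifest_path, manifest)
    artifacts["manifest"] = manifest_path
    logger.info("pipeline done: %d calls -> %s", len(calls), out)
    return artifacts
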