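"""Candidate-target scanning of a transcriptome with a consensus profile.

Slides the decile matching score over every cytidine of every transcript:
a position-frequency-matrix search in the spirit of weight-matrix target
scanners, restricted to the thresholded consensus positions.  Windows that
run over a transcript end are scored with pads contributing zero and
flagged ``truncated`` rather than discarded.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import TranscriptAnnotation, extract_context
from .profile import ConsensusProfile, matching_score, max_score

__all__ = ["scan_transcriptome", "predicted_vs_observed"]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = [
    "transcript_id", "position", "score", "max_score", "truncated", "window",
]


def _scan_sequence(seq: str, profile: ConsensusProfile) -> np.ndarray:
    """Vector of matching scores for every position of ``seq`` (C or not)."""
    lo, hi = profile.bounds
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    scores = np.zeros(n, dtype=int)
    for offset, (nt, decile) in profile.decile_map.items():
        shifted = np.full(n, b"-", dtype="S1")
        src_lo = max(0, -offset)
        src_hi = min(n, n - offset)
        if src_lo < src_hi:
            shifted[src_lo:src_hi] = arr[src_lo + offset:src_hi + offset]
        scores += decile * (shifted == nt.encode("ascii"))
    return scores


def scan_transcriptome(
    annotations: Mapping[str, TranscriptAnnotation] | Sequence[TranscriptAnnotation],
    profile: ConsensusProfile,
    min_score: int = 0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Ranked candidate editing sites across a transcriptome.

    Every reference-C position is scored against the profile; candidates
    with ``score >= min_score`` are returned sorted by score (descending)
    with lexicographic (transcript_id, position) tie-breaks, truncated to
    ``top_n`` if given.  A ``min_score`` above the profile's maximum yields
    an empty table (with a logged warning).
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.transcript_id: a for a in annotations}
    mx = max_score(profile)
    if min_score > mx:
        logger.warning(
            "min_score %d exceeds the profile maximum %d; no candidate can match",
            min_score, mx,
        )
        return pd.DataFrame(columns=SCAN_COLUMNS)

    lo, hi = profile.bounds
    frames = []
    for tid in sorted(annotations):
        ann = annotations[tid]
        seq = ann.sequence
        if not seq:
            continue
        scores = _scan_sequence(seq, profile)
        is_c = np.frombuffer(seq.encode("ascii"), dtype="S1") == b"C"
        keep = is_c & (scores >= min_score)
        positions = np.nonzero(keep)[0]
        if len(positions) == 0:
            continue
        truncated = (positions + lo < 0) | (positions + hi >= len(seq))
        windows = [
            extract_context(ann, int(p), upstream=-lo if lo < 0 else 0,
                            downstream=hi if hi > 0 else 0).sequence
            for p in positions
        ]
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "position": positions,
                    "score": scores[positions],
                    "max_score": mx,
                    "truncated": truncated,
                    "window": windows,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["score", "transcript_id", "position"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n).reset_index(drop=True)
    return out


def predicted_vs_observed(
    candidates: pd.DataFrame, calls: pd.DataFrame | Sequence
) -> dict:
    """Join scanner candidates with observed calls on (transcript, position).

    ``calls`` may be a list of :class:`~ppredit.calling.OffTargetCall` or a
    DataFrame with ``transcript_id``/``position`` columns.  Returns a dict
    with the joined ``table`` (flags ``predicted`` / ``edited``), the
    ``non_edited_candidates`` sub-table (high-score candidates never called,
    the interesting discrepancy class) and summary ``counts``.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [{"transcript_id": c.transcript_id, "position": c.position} for c in calls],
            columns=["transcript_id", "position"],
        )
    cand = candidates[["transcript_id", "position", "score"]].copy()
    cand["predicted"] = True
    obs = calls[["transcript_id", "position"]].drop_duplicates().copy()
    obs["edited"] = True
    table = cand.merge(obs, on=["transcript_id", "position"], how="outer")
    table["predicted"] = table["predicted"].eq(True)
    table["edited"] = table["edited"].eq(True)
    table = table.sort_values(["transcript_id", "position"]).reset_index(drop=True)
    non_edited = table[table["predicted"] & ~table["edited"]].reset_index(drop=True)
    counts = {
        "n_candidates": int(table["predicted"].sum()),
        "n_called": int(table["edited"].sum()),
        "n_predicted_and_edited": int((table["predicted"] & table["edited"]).sum()),
        "n_candidates_not_edited": int(len(non_edited)),
        "n_called_missed_by_prediction": int(
            (~table["predicted"] & table["edited"]).sum()
        ),
    }
    return {"table": table, "non_edited_candidates": non_edited, "counts": counts}
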