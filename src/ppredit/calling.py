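"""Replicate-filtered calling of C-to-U editing sites from base counts.

Input is a per-site, per-replicate pileup summary (A/C/G/T counts) for
factor-expressing samples and editing-dead / tag-only controls, plus the
transcriptome the reads were mapped to.  A transcript position becomes a
candidate when editing is detected (>= 2 edited reads and >= 1% of reads,
by default) in at least two factor replicates and in no control replicate,
and the reference base is C.  Candidates then pass four pooled-count
filters: (i) clean cytidine background > 99% in the control, (ii) thymidine
background < 0.5% in the control, (iii) coverage >= 20 reads in both pooled
sample and pooled control, and (iv) pooled editing efficiency >= 1.5%.

Editing rates pool reads across replicates (sum of edited / sum of total),
they are not per-replicate averages.  Coordinates are 0-based half-open
internally; site labels are 1-based (``gene`` + ``eU`` + CDS position +
amino-acid change, or ``eU±n`` for UTR sites).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .profile import ConsensusProfile, TargetWindow, matching_score

__all__ = [
    "PILEUP_COLUMNS",
    "FilterThresholds",
    "TranscriptAnnotation",
    "OffTargetCall",
    "ConfigurationError",
    "reference_filter",
    "per_replicate_call",
    "call_sites",
    "apply_filters",
    "edit_rate",
    "sanger_rate",
    "extract_context",
    "label_site",
    "parse_site_label",
    "call_offtargets",
    "calls_table",
    "shared_offtargets",
]

PILEUP_COLUMNS = [
    "transcript_id", "position", "replicate_id", "group", "nA", "nC", "nG", "nT",
]

GROUPS = ("factor", "control")


class ConfigurationError(ValueError):
    """Raised when mandatory pipeline inputs (e.g. controls) are missing."""


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the off-target filters.

    min_replicates
        Factor replicates in which editing must be detected (>= 2).
    min_coverage
        Pooled read coverage required in sample and control (filter iii).
    min_rate
        Pooled editing efficiency cut-off (filter iv), fraction.
    ref_c_min
        Minimum cytidine fraction in the pooled control (filter i).
    ref_t_max
        Maximum thymidine fraction in the pooled control (filter ii).
    min_edited / per_rep_min_rate
        Per-replicate detection: edited reads and per-replicate rate.
    """

    min_replicates: int = 2
    min_coverage: int = 20
    min_rate: float = 0.015
    ref_c_min: float = 0.99
    ref_t_max: float = 0.005
    min_edited: int = 2
    per_rep_min_rate: float = 0.01


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript with CDS bounds and an abundance estimate.

    ``cds_start``/``cds_end`` are a 0-based half-open interval into
    ``sequence``; ``num_reads`` is the mapped-read abundance estimate used
    by :func:`reference_filter`.
    """

    transcript_id: str
    gene: str
    protein_name: str
    sequence: str
    cds_start: int
    cds_end: int
    num_reads: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not 0 <= self.cds_start <= self.cds_end <= len(seq):
            raise ValueError(
                f"CDS [{self.cds_start}, {self.cds_end}) outside transcript "
                f"{self.transcript_id!r} of length {len(seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if self.num_reads < 0:
            raise ValueError("num_reads must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OffTargetCall:
    """A filtered, labelled, quantified editing site."""

    transcript_id: str
    gene: str
    position: int
    label: str
    region: str
    context: TargetWindow
    edit_rate: float
    n_replicates_detected: int
    protein_name: str = ""
    matching_score: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.edit_rate <= 1.0:
            raise ValueError("edit_rate must be in [0, 1]")
        if self.n_replicates_detected < 2:
            raise ValueError("calls require detection in >= 2 replicates")


def reference_filter(
    annotations: Sequence[TranscriptAnnotation], min_reads: float = 10
) -> list[TranscriptAnnotation]:
    """Keep transcripts with abundance ``num_reads >= min_reads`` (order kept)."""
    return [a for a in annotations if a.num_reads >= min_reads]


def _counts_total(counts: Mapping[str, int]) -> int:
    return sum(int(counts.get(b, 0)) for b in "ACGT")


def per_replicate_call(
    counts: Mapping[str, int], min_edited: int = 2, min_rate: float = 0.01
) -> bool:
    """Detection in one replicate at a reference-C site.

    True iff at least ``min_edited`` T reads are present and they make up at
    least ``min_rate`` of the reads.  Zero coverage is "not detected", not
    an error.
    """
    total = _counts_total(counts)
    if total == 0:
        return False
    n_t = int(counts.get("T", 0))
    return n_t >= min_edited and n_t / total >= min_rate


def _validate_pileups(pileups: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PILEUP_COLUMNS if c not in pileups.columns]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    bad = set(pileups["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown sample groups {sorted(bad)}; expected {GROUPS}")
    return pileups


def call_sites(
    pileups: pd.DataFrame,
    annotations: Mapping[str, TranscriptAnnotation] | Sequence[TranscriptAnnotation],
    min_replicates: int = 2,
    min_edited: int = 2,
    min_rate: float = 0.01,
) -> pd.DataFrame:
    """Replicate-consensus candidate sites from a pileup table.

    A (transcript, position) is a candidate iff the reference base is C,
    :func:`per_replicate_call` is true in >= ``min_replicates`` factor
    replicates and false in every control replicate.  Controls are
    mandatory; their absence raises :class:`ConfigurationError`.

    Returns a DataFrame ``transcript_id, position, n_factor_called,
    n_control_called`` sorted by transcript and position.
    """
    pileups = _validate_pileups(pileups)
    if isinstance(annotations, Mapping):
        ann = dict(annotations)
    else:
        ann = {a.transcript_id: a for a in annotations}
    if not (pileups["group"] == "control").any():
        raise ConfigurationError(
            "no control replicates in pileup table; controls are mandatory"
        )
    n_factor_reps = pileups.loc[pileups["group"] == "factor", "replicate_id"].nunique()
    if n_factor_reps < min_replicates:
        raise ConfigurationError(
            f"need >= {min_replicates} factor replicates, got {n_factor_reps}"
        )

    df = pileups.copy()
    total = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(total > 0, df["nT"] / total.where(total > 0, 1), 0.0)
    df["called"] = (df["nT"] >= min_edited) & (total > 0) & (rate >= min_rate)

    grouped = (
        df.groupby(["transcript_id", "position", "group"], sort=False)["called"]
        .sum()
        .unstack("group", fill_value=0)
        .reindex(columns=list(GROUPS), fill_value=0)
        .reset_index()
        .rename(columns={"factor": "n_factor_called", "control": "n_control_called"})
    )
    cand = grouped[
        (grouped["n_factor_called"] >= min_replicates)
        & (grouped["n_control_called"] == 0)
    ].copy()

    def _is_ref_c(row) -> bool:
        a = ann.get(row["transcript_id"])
        if a is None or not 0 <= row["position"] < len(a):
            return False
        return a.sequence[int(row["position"])] == "C"

    if len(cand):
        cand = cand[cand.apply(_is_ref_c, axis=1)]
    cand = cand.sort_values(["transcript_id", "position"]).reset_index(drop=True)
    cand[["n_factor_called", "n_control_called"]] = cand[
        ["n_factor_called", "n_control_called"]
    ].astype(int)
    return cand


def apply_filters(
    factor_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[bool, tuple[str, ...]]:
    """Pooled-count filters (i)-(iv) for one candidate site.

    Returns ``(passed, violated)`` where ``violated`` lists the roman
    numerals of failed criteria.  All predicates are evaluated, so the pass
    set is independent of filter order.  A site without control coverage
    cannot demonstrate a clean background and fails (i)-(iii).
    """
    violated: list[str] = []
    f_total = _counts_total(factor_counts)
    c_total = _counts_total(control_counts)

    if c_total > 0:
        if control_counts.get("C", 0) / c_total <= thresholds.ref_c_min:
            violated.append("i")
        if control_counts.get("T", 0) / c_total >= thresholds.ref_t_max:
            violated.append("ii")
    else:
        violated.extend(["i", "ii"])
    if f_total < thresholds.min_coverage or c_total < thresholds.min_coverage:
        violated.append("iii")
    if f_total == 0 or factor_counts.get("T", 0) / max(f_total, 1) < thresholds.min_rate:
        violated.append("iv")
    return (not violated, tuple(violated))


def edit_rate(replicate_counts: Iterable[Mapping[str, int]]) -> float:
    """Pooled editing rate: sum of T reads over sum of total reads.

    Replicates are pooled before dividing, never averaged; all-zero
    coverage raises ``ValueError`` (the rate is undefined).
    """
    t_sum = 0
    total_sum = 0
    for counts in replicate_counts:
        t_sum += int(counts.get("T", 0))
        total_sum += _counts_total(counts)
    if total_sum == 0:
        raise ValueError("editing rate undefined: zero total coverage")
    return t_sum / total_sum


def sanger_rate(peak_t: float, peak_c: float) -> float:
    """Editing rate from Sanger chromatogram peaks: T / (T + C)."""
    if peak_t < 0 or peak_c < 0:
        raise ValueError("peak heights must be non-negative")
    if peak_t + peak_c == 0:
        raise ValueError("editing rate undefined: both peaks are zero")
    return peak_t / (peak_t + peak_c)


def extract_context(
    annotation: TranscriptAnnotation,
    position: int,
    upstream: int = 30,
    downstream: int = 5,
    edit_rate: float | None = None,
) -> TargetWindow:
    """Sequence window around an edited C, ``'-'``-padded at transcript ends.

    The default window spans offsets -30..+5; construct-style extraction
    (40 nt upstream, 5 nt downstream) yields the 46-nt windows used for
    delivered targets.
    """
    seq = annotation.sequence
    if not 0 <= position < len(seq):
        raise IndexError(
            f"position {position} outside transcript {annotation.transcript_id!r}"
        )
    chars = []
    for off in range(-upstream, downstream + 1):
        i = position + off
        chars.append(seq[i] if 0 <= i < len(seq) else "-")
    return TargetWindow(
        gene=annotation.gene,
        transcript_id=annotation.transcript_id,
        site_position=position,
        sequence="".join(chars),
        lo=-upstream,
        edit_rate=edit_rate,
    )


def label_site(annotation: TranscriptAnnotation, position: int) -> tuple[str, str]:
    """Nomenclature label and region for an edited C.

    CDS sites: ``gene`` + ``eU`` + 1-based CDS position + amino acids
    before/after the C-to-U change (stop gains use ``*``), e.g.
    ``nad4eU272SL``.  UTR sites: ``eU-<n>`` upstream of the CDS (nearest
    upstream base = 1) and ``eU+<n>`` downstream (first base after the stop
    = 1).
    """
    seq = annotation.sequence
    if not 0 <= position < len(seq):
        raise IndexError(
            f"position {position} outside transcript {annotation.transcript_id!r}"
        )
    if seq[position] != "C":
        raise ValueError(
            f"reference base at {annotation.transcript_id}:{position} is "
            f"{seq[position]!r}, not C"
        )
    gene = annotation.gene
    if position < annotation.cds_start:
        return f"{gene}eU-{annotation.cds_start - position}", "5'UTR"
    if position >= annotation.cds_end:
        return f"{gene}eU+{position - annotation.cds_end + 1}", "3'UTR"
    cds_pos1 = position - annotation.cds_start + 1
    codon_idx = (cds_pos1 - 1) // 3
    codon_start = annotation.cds_start + 3 * codon_idx
    codon = seq[codon_start:codon_start + 3]
    within = (cds_pos1 - 1) % 3
    edited = codon[:within] + "T" + codon[within + 1:]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(edited).translate())
    return f"{gene}eU{cds_pos1}{aa_before}{aa_after}", "CDS"


_LABEL_RE = re.compile(
    r"^(?P<gene>.*)eU(?:(?P<sign>[+-])(?P<utr_pos>\d+)"
    r"|(?P<cds_pos>\d+)(?P<aa_before>[A-Z*])(?P<aa_after>[A-Z*]))$"
)


def parse_site_label(label: str) -> dict:
    """Invert :func:`label_site`: recover gene, region, position and change."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable site label {label!r}")
    if m.group("sign"):
        region = "3'UTR" if m.group("sign") == "+" else "5'UTR"
        return {
            "gene": m.group("gene"),
            "region": region,
            "position": int(m.group("utr_pos")),
            "aa_change": None,
        }
    return {
        "gene": m.group("gene"),
        "region": "CDS",
        "position": int(m.group("cds_pos")),
        "aa_change": (m.group("aa_before"), m.group("aa_after")),
    }


def _pool(group_df: pd.DataFrame) -> dict[str, int]:
    return {b: int(group_df[f"n{b}"].sum()) for b in "ACGT"}


def call_offtargets(
    pileups: pd.DataFrame,
    annotations: Mapping[str, TranscriptAnnotation] | Sequence[TranscriptAnnotation],
    thresholds: FilterThresholds = FilterThresholds(),
    profile: ConsensusProfile | None = None,
    upstream: int = 30,
    downstream: int = 5,
) -> tuple[list[OffTargetCall], pd.DataFrame]:
    """Full caller: replicate consensus, pooled filters, context and labels.

    Returns the passing calls plus an audit table with one row per candidate
    carrying the violated filter criteria (empty string = passed).  When a
    ``profile`` is given each call is annotated with its matching score.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.transcript_id: a for a in annotations}
    candidates = call_sites(
        pileups,
        annotations,
        min_replicates=thresholds.min_replicates,
        min_edited=thresholds.min_edited,
        min_rate=thresholds.per_rep_min_rate,
    )
    calls: list[OffTargetCall] = []
    audit_rows = []
    for _, row in candidates.iterrows():
        tid, pos = row["transcript_id"], int(row["position"])
        site = pileups[(pileups["transcript_id"] == tid) & (pileups["position"] == pos)]
        factor_counts = _pool(site[site["group"] == "factor"])
        control_counts = _pool(site[site["group"] == "control"])
        passed, violated = apply_filters(factor_counts, control_counts, thresholds)
        audit_rows.append(
            {
                "transcript_id": tid,
                "position": pos,
                "n_factor_called": int(row["n_factor_called"]),
                "passed": passed,
                "violated": ",".join(violated),
            }
        )
        if not passed:
            continue
        ann = annotations[tid]
        rate = edit_rate(
            [_pool(g) for _, g in site[site["group"] == "factor"].groupby("replicate_id")]
        )
        context = extract_context(ann, pos, upstream, downstream, edit_rate=rate)
        label, region = label_site(ann, pos)
        score = matching_score(context, profile) if profile is not None else None
        calls.append(
            OffTargetCall(
                transcript_id=tid,
                gene=ann.gene,
                position=pos,
                label=label,
                region=region,
                context=context,
                edit_rate=rate,
                n_replicates_detected=int(row["n_factor_called"]),
                protein_name=ann.protein_name,
                matching_score=score,
            )
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=["transcript_id", "position", "n_factor_called", "passed", "violated"],
    )
    return calls, audit


def calls_table(calls: Sequence[OffTargetCall]) -> pd.DataFrame:
    """Flatten calls into the report layout (label, protein, accession,
    replicates, mean editing %, context sequence)."""
    rows = [
        {
            "label": c.label,
            "protein_name": c.protein_name,
            "accession": c.transcript_id,
            "position": c.position,
            "region": c.region,
            "replicates": c.n_replicates_detected,
            "editing_percent": round(100.0 * c.edit_rate, 2),
            "matching_score": c.matching_score if c.matching_score is not None else "",
            "context": c.context.sequence,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "protein_name", "accession", "position", "region",
            "replicates", "editing_percent", "matching_score", "context",
        ],
    )


def shared_offtargets(
    call_sets: Mapping[str, Sequence[OffTargetCall]],
) -> pd.DataFrame:
    """Membership of sites across named call sets.

    Returns a DataFrame keyed by (transcript_id, position) with one boolean
    column per set plus ``n_sets``; the all-true rows are the intersection.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets to compare")
    keys: dict[tuple[str, int], dict[str, bool]] = {}
    for name, calls in call_sets.items():
        for c in calls:
            keys.setdefault((c.transcript_id, c.position), {})[name] = True
    names = list(call_sets)
    rows = []
    for (tid, pos), membership in sorted(keys.items()):
        row = {"transcript_id": tid, "position": pos}
        row.update({n: membership.get(n, False) for n in names})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["transcript_id", "position", *names])
    if len(df):
        df["n_sets"] = df[names].sum(axis=1).astype(int)
    else:
        df["n_sets"] = pd.Series(dtype=int)
    return df
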