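"""Synthetic data with the statistical structure the caller assumes.

The generator emulates the shape of a factor-expression RNA-seq experiment
at the pileup-summary level: a small multi-transcript transcriptome with
planted C-to-U sites, three (or more) factor-expressing replicates plus
editing-dead controls, Poisson read coverage, binomial editing at a fixed
per-site efficiency, and a low uniform sequencing-error background.  Reads
themselves are never simulated -- per-site base counts are the simulation
boundary, matching the caller's input contract.

All generators are pure functions of their parameters and a seed.  A single
master seed fans out to per-replicate substreams through the seed-sequence
key ``[seed, group_code, replicate_index]`` (factor = 1, control = 2), so
adding a replicate never perturbs the counts of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import PILEUP_COLUMNS, TranscriptAnnotation
from .code import EditingFactor, PPRMotif
from .profile import ConsensusProfile, TargetWindow, matching_score

__all__ = [
    "PlantedSite",
    "make_factor",
    "make_transcriptome",
    "simulate_pileups",
    "simulate_sanger",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "transcript_id", "gene", "position", "region", "efficiency", "score",
]

#: The PPR56-like preset: 13 repeats, N- to C-terminal, with the 5/L
#: identities reported for the natural array where known (S-10TD, P-9TN,
#: S-7TD, P-6ND, S-4TN, P2-3ND, S2-1ND and the L-type repeats L-11MD,
#: L-5LD, L2-2VD).  L-8, P-12 and S-13 carry synthetic placeholder
#: identities -- this preset is a stand-in for the natural factor, not a
#: reproduction of it.
_PPR56_LIKE = [
    ("S", 13, "N", "D"),
    ("P", 12, "T", "N"),
    ("L", 11, "M", "D"),
    ("S", 10, "T", "D"),
    ("P", 9, "T", "N"),
    ("L", 8, "A", "D"),
    ("S", 7, "T", "D"),
    ("P", 6, "N", "D"),
    ("L", 5, "L", "D"),
    ("S", 4, "T", "N"),
    ("P2", 3, "N", "D"),
    ("L2", 2, "V", "D"),
    ("S2", 1, "N", "D"),
]

_CLASS_CYCLE = {0: ("S", "S2"), 1: ("L", "L2"), 2: ("P", "P2")}


def _validate_layout(motifs: Sequence[PPRMotif]) -> None:
    """Layouts must alternate P/L/S (cyclically) and end in P2-L2-S2."""
    if len(motifs) < 3:
        raise ValueError("layout needs at least the terminal P2-L2-S2 triplet")
    tail = [m.motif_class for m in motifs[-3:]]
    if tail != ["P2", "L2", "S2"]:
        raise ValueError(f"layout must end in P2-L2-S2, got {'-'.join(tail)}")
    n = len(motifs)
    for i, m in enumerate(motifs):
        if m.repeat_number != n - i:
            raise ValueError("repeat numbers must run n..1 without gaps")
        plain, two = _CLASS_CYCLE[(m.repeat_number - 1) % 3]
        if m.motif_class not in (plain, two):
            raise ValueError(
                f"motif {m.label} breaks the P/L/S alternation (expected "
                f"{plain} or {two})"
            )


def make_factor(spec: str = "PPR56-like", name: str | None = None) -> EditingFactor:
    """Build an editing factor from a preset or a motif-layout text.

    ``spec`` is either the preset name ``"PPR56-like"`` or a layout text
    with one tab-separated motif per line (label, class, aa5, aaL; ``#``
    comments allowed), N- to C-terminal.  Layouts must alternate P/L/S
    classes and end in the P2-L2-S2 triplet.
    """
    if spec.strip() == "PPR56-like":
        motifs = tuple(PPRMotif(c, n, a5, aL) for c, n, a5, aL in _PPR56_LIKE)
        return EditingFactor(name or "PPR56-like", motifs, has_dyw=True)
    from .io import parse_factor_text  # local import to avoid a cycle

    factor = parse_factor_text(spec, name=name or "custom")
    _validate_layout(factor.motifs)
    return factor


@dataclass(frozen=True)
class PlantedSite:
    """Specification of one planted editing site.

    ``window`` is either ``None`` (random context, consensus-matching when a
    profile is supplied to :func:`make_transcriptome`) or an explicit
    sequence placed with its first base at offset ``window_lo`` relative to
    the edited C.
    """

    efficiency: float
    window: str | None = None
    window_lo: int = -30

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")


def _region_of(pos: int, cds_start: int, cds_end: int) -> str:
    if pos < cds_start:
        return "5'UTR"
    if pos >= cds_end:
        return "3'UTR"
    return "CDS"


def make_transcriptome(
    n_transcripts: int = 10,
    length: int = 1000,
    planted: Sequence[PlantedSite] | None = None,
    seed: int = 0,
    profile: ConsensusProfile | None = None,
    num_reads: float = 100.0,
    composition: Sequence[float] | None = None,
) -> tuple[list[TranscriptAnnotation], pd.DataFrame]:
    """A random transcriptome with planted editing sites and a truth table.

    Transcript backgrounds are uniform A/C/G/T (or the given ``composition``
    over A, C, G, T).  Each transcript gets a central CDS (length a multiple
    of three) flanked by UTRs, and abundance ``num_reads`` so it survives
    the default reference filter.  Planted sites are assigned round-robin to
    transcripts at positions where the context window fits; when a
    ``profile`` is given, sites without an explicit window sequence receive
    a consensus-matching environment and every truth row records the
    construction-time matching score.

    Returns ``(annotations, truth)`` where ``truth`` has columns
    ``transcript_id, gene, position, region, efficiency, score``.
    Deterministic: identical arguments give identical output.
    """
    if n_transcripts < 1 or length < 50:
        raise ValueError("need n_transcripts >= 1 and length >= 50")
    planted = list(planted or [])
    rng = np.random.default_rng([seed, 1])
    p = None if composition is None else np.asarray(composition, dtype=float)
    if p is not None:
        p = p / p.sum()

    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, size=length, p=p)) for _ in range(n_transcripts)]

    cds_start = max(3, length // 5)
    cds_len = (3 * length // 5) // 3 * 3
    cds_end = min(cds_start + cds_len, length - 3)
    cds_end -= (cds_end - cds_start) % 3

    w_lo, w_hi = (-30, 5) if profile is None else (min(profile.lo, -30), max(profile.hi, 5))
    truth_rows = []
    used: dict[int, list[int]] = {i: [] for i in range(n_transcripts)}
    for k, site in enumerate(planted):
        t = k % n_transcripts
        lo_ok = -w_lo
        hi_ok = length - w_hi - 1
        if lo_ok >= hi_ok:
            raise ValueError("transcripts too short for the planted windows")
        for _ in range(1000):
            pos = int(rng.integers(lo_ok, hi_ok))
            if all(abs(pos - q) > (w_hi - w_lo + 1) for q in used[t]):
                break
        else:
            raise ValueError("could not place planted site without overlap")
        used[t].append(pos)

        seq = list(seqs[t])
        if site.window is not None:
            win = site.window.upper().replace("U", "T")
            start = pos + site.window_lo
            if start < 0 or start + len(win) > length:
                raise ValueError("explicit planted window does not fit")
            seq[start:start + len(win)] = list(win)
        elif profile is not None:
            for o, (nt, _) in profile.decile_map.items():
                seq[pos + o] = nt
        seq[pos] = "C"
        seqs[t] = "".join(seq)
        truth_rows.append((t, pos, site.efficiency))

    annotations = [
        TranscriptAnnotation(
            transcript_id=f"T{i + 1:03d}",
            gene=f"gene{i + 1:03d}",
            protein_name=f"protein {i + 1:03d}",
            sequence=seqs[i],
            cds_start=cds_start,
            cds_end=cds_end,
            num_reads=num_reads,
        )
        for i in range(n_transcripts)
    ]

    rows = []
    for t, pos, eff in truth_rows:
        ann = annotations[t]
        score: float | int = float("nan")
        if profile is not None:
            chars = [
                ann.sequence[pos + o] if 0 <= pos + o < length else "-"
                for o in range(min(profile.lo, 0), max(profile.hi, 0) + 1)
            ]
            win = TargetWindow(
                ann.gene, ann.transcript_id, pos, "".join(chars),
                lo=min(profile.lo, 0),
            )
            score = matching_score(win, profile)
        rows.append(
            {
                "transcript_id": ann.transcript_id,
                "gene": ann.gene,
                "position": pos,
                "region": _region_of(pos, cds_start, cds_end),
                "efficiency": eff,
                "score": score,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["transcript_id", "position"]).reset_index(drop=True)
    return annotations, truth


_GROUP_CODE = {"factor": 1, "control": 2}


def simulate_pileups(
    annotations: Sequence[TranscriptAnnotation],
    truth: pd.DataFrame,
    n_factor_reps: int = 3,
    n_control_reps: int = 3,
    coverage: float = 100.0,
    error: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site, per-replicate base counts for factor and control groups.

    Per site and replicate the total read count is Poisson(``coverage``).
    At planted sites in factor replicates the T count is
    ``Binomial(total, efficiency + error * (1 - efficiency))`` with the
    remainder on the reference C; everywhere else (and in all control
    replicates) each non-reference base is ``Binomial(total, error / 3)``.

    Editing-dead controls share the error model but never the editing
    signal, which is exactly the contrast the caller exploits.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error < 0.01:
        raise ValueError("error rate must be in [0, 0.01)")
    tids = np.concatenate(
        [np.repeat(a.transcript_id, len(a)) for a in annotations]
    )
    positions = np.concatenate([np.arange(len(a)) for a in annotations])
    refs = np.frombuffer(
        "".join(a.sequence for a in annotations).encode("ascii"), dtype="S1"
    )
    n = len(refs)

    planted_eff = {
        (r["transcript_id"], int(r["position"])): float(r["efficiency"])
        for _, r in truth.iterrows()
    }
    planted_idx = np.array(
        [i for i in range(n) if (tids[i], int(positions[i])) in planted_eff],
        dtype=int,
    )
    planted_p = np.array(
        [
            planted_eff[(tids[i], int(positions[i]))]
            for i in planted_idx
        ],
        dtype=float,
    )

    frames = []
    for group, n_reps in (("factor", n_factor_reps), ("control", n_control_reps)):
        for r in range(n_reps):
            rng = np.random.default_rng([seed, _GROUP_CODE[group], r])
            totals = rng.poisson(lam=coverage, size=n)
            counts = {b: np.zeros(n, dtype=int) for b in "ACGT"}
            for b in "ACGT":
                mask = refs != b.encode("ascii")
                err = np.zeros(n, dtype=int)
                err[mask] = rng.binomial(totals[mask], error / 3.0)
                counts[b] += err
            non_ref = sum(counts[b] for b in "ACGT")
            for b in "ACGT":
                mask = refs == b.encode("ascii")
                counts[b][mask] = np.maximum(totals[mask] - non_ref[mask], 0)
            if group == "factor" and len(planted_idx):
                p_obs = planted_p + error * (1.0 - planted_p)
                n_t = rng.binomial(totals[planted_idx], p_obs)
                counts["T"][planted_idx] = n_t
                counts["A"][planted_idx] = 0
                counts["G"][planted_idx] = 0
                counts["C"][planted_idx] = totals[planted_idx] - n_t
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": tids,
                        "position": positions,
                        "replicate_id": f"{group[0].upper()}{r + 1}",
                        "group": group,
                        "nA": counts["A"],
                        "nC": counts["C"],
                        "nG": counts["G"],
                        "nT": counts["T"],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def simulate_sanger(
    efficiency: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1000.0,
) -> tuple[float, float]:
    """Sanger-like (T peak, C peak) heights at an editing position.

    The underlying peak ratio is the efficiency plus Gaussian noise of
    standard deviation ``noise_sd``, clipped to [0, 1]; peak heights sum to
    ``scale``.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng([seed, 3])
    ratio = float(np.clip(efficiency + rng.normal(0.0, noise_sd) if noise_sd > 0
                          else efficiency, 0.0, 1.0))
    return ratio * scale, (1.0 - ratio) * scale
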