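"""Consensus profiles of editing-site environments and the matching score.

Off-target editing sites are summarised by their sequence environment, by
default 30 nt upstream and 5 nt downstream of the edited cytidine (offset 0).
Per-offset nucleotide frequencies define a consensus: an offset is
*thresholded* when a unique nucleotide dominates with frequency >= 40%, and
its weight is the frequency floored to the nearest 10% step (deciles 40..90,
capped at 90).  The matching score of a candidate window is the sum of the
decile weights at every thresholded offset whose nucleotide the window
carries; the profile's maximum score is the sum over all thresholded offsets.

Scores are integers by construction -- sums of decile steps -- mirroring how
conservation-profile cut-offs in 10% steps are read off a sequence logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .code import normalize_base

__all__ = [
    "NUCLEOTIDES",
    "TargetWindow",
    "ConsensusProfile",
    "build_profile",
    "matching_score",
    "max_score",
    "consensus_string",
    "profile_shift_report",
]

NUCLEOTIDES = ("A", "C", "G", "T")

_EPS = 1e-9


def _normalize_seq(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == "U":
            ch = "T"
        if ch not in "ACGTN-":
            raise ValueError(f"invalid window symbol {ch!r}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class TargetWindow:
    """Sequence environment of an edited cytidine.

    ``sequence[0]`` sits at offset ``lo`` (default -30); the edited C is at
    offset 0 and must read C in the (pre-editing) reference.  ``'-'`` pads
    mark positions beyond the transcript ends; ``N`` is tolerated.
    """

    gene: str
    transcript_id: str
    site_position: int
    sequence: str
    lo: int = -30
    edit_rate: float | None = None

    def __post_init__(self) -> None:
        seq = _normalize_seq(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not self.lo <= 0 <= self.lo + len(seq) - 1:
            raise ValueError("window must cover offset 0 (the edited site)")
        if self.base_at(0) != "C":
            raise ValueError(
                f"reference base at offset 0 must be C, got {self.base_at(0)!r}"
            )
        if self.edit_rate is not None and not 0.0 <= self.edit_rate <= 1.0:
            raise ValueError("edit_rate must be in [0, 1]")

    @property
    def hi(self) -> int:
        return self.lo + len(self.sequence) - 1

    def base_at(self, offset: int, default: str | None = None) -> str:
        """Nucleotide at a signed offset; ``default`` (if given) outside."""
        i = offset - self.lo
        if 0 <= i < len(self.sequence):
            return self.sequence[i]
        if default is not None:
            return default
        raise IndexError(f"offset {offset} outside window [{self.lo}..{self.hi}]")

    def covers(self, lo: int, hi: int) -> bool:
        return self.lo <= lo and self.hi >= hi


def _decile(freq: float) -> int | None:
    """Frequency -> decile weight: floor to 10% steps, >= 40, capped at 90."""
    d = 10 * math.floor(10.0 * freq + _EPS)
    if d < 40:
        return None
    return min(d, 90)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-offset nucleotide frequencies plus the thresholded consensus.

    ``freq`` is a DataFrame indexed by signed offsets with columns A/C/G/T;
    rows sum to 1 (or to 0 at offsets where every window was a pad).
    ``decile_map`` assigns ``(nucleotide, decile)`` to offsets where a unique
    nucleotide dominates at >= 40%.
    """

    freq: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.freq
        if list(f.columns) != list(NUCLEOTIDES):
            raise ValueError("freq must have columns A, C, G, T")
        sums = f.sum(axis=1).to_numpy()
        if not np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0)):
            raise ValueError("per-offset frequencies must sum to 1 (or 0 for all-pad)")

    @property
    def lo(self) -> int:
        return int(self.freq.index.min())

    @property
    def hi(self) -> int:
        return int(self.freq.index.max())

    @property
    def bounds(self) -> tuple[int, int]:
        return self.lo, self.hi

    @property
    def n_offsets(self) -> int:
        return len(self.freq)

    @property
    def decile_map(self) -> dict[int, tuple[str, int]]:
        out: dict[int, tuple[str, int]] = {}
        for offset, row in self.freq.iterrows():
            vals = row.to_numpy(dtype=float)
            top = vals.max()
            if top <= 0.0:
                continue
            winners = [n for n, v in zip(NUCLEOTIDES, vals) if v > top - _EPS]
            if len(winners) != 1:
                continue  # tie: no unique dominant nucleotide
            d = _decile(top)
            if d is not None:
                out[int(offset)] = (winners[0], d)
        return out

    def consensus_window(self, gene: str = "consensus",
                         transcript_id: str = "consensus") -> TargetWindow:
        """A window carrying the thresholded nucleotide at every thresholded
        offset (dominant or ``A`` elsewhere, ``C`` at offset 0); by
        construction it attains ``max_score``."""
        lo = min(self.lo, 0)
        hi = max(self.hi, 0)
        dec = self.decile_map
        chars = []
        for o in range(lo, hi + 1):
            if o == 0:
                chars.append("C")
            elif o in dec:
                chars.append(dec[o][0])
            elif o in self.freq.index:
                row = self.freq.loc[o]
                chars.append(row.idxmax() if row.sum() > 0 else "A")
            else:
                chars.append("A")
        return TargetWindow(gene, transcript_id, 0, "".join(chars), lo=lo)


def build_profile(
    windows: Sequence[TargetWindow],
    bounds: tuple[int, int] = (-30, 5),
    dedupe: bool = False,
) -> ConsensusProfile:
    """Per-offset nucleotide frequencies over a set of editing-site windows.

    With ``dedupe=True``, windows sharing both gene and sequence are counted
    once -- identical target sequences in different transcript variants of
    one gene should not inflate the consensus.  Pads (``'-'``) and ``N`` are
    excluded from numerator and denominator at the affected offset.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("build_profile needs at least one window")
    lo, hi = bounds
    if lo > hi:
        raise ValueError("bounds must satisfy lo <= hi")
    if dedupe:
        seen: set[tuple[str, str]] = set()
        unique = []
        for w in windows:
            key = (w.gene, w.sequence)
            if key not in seen:
                seen.add(key)
                unique.append(w)
        windows = unique

    offsets = range(lo, hi + 1)
    rows = [
        "".join(w.base_at(o, default="-") for o in offsets) for w in windows
    ]
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype="S1")
    mat = mat.reshape(len(windows), hi - lo + 1)
    counts = pd.DataFrame(
        {n: (mat == n.encode("ascii")).sum(axis=0) for n in NUCLEOTIDES},
        index=pd.Index(offsets, name="offset"),
        dtype=float,
    )
    totals = counts.sum(axis=1)
    freq = counts.div(totals.where(totals > 0, other=np.nan), axis=0).fillna(0.0)
    return ConsensusProfile(freq)


def matching_score(window: TargetWindow, profile: ConsensusProfile) -> int:
    """Sum of decile weights at thresholded offsets the window matches."""
    if not window.covers(profile.lo, profile.hi):
        raise IndexError(
            f"window [{window.lo}..{window.hi}] shorter than profile bounds "
            f"[{profile.lo}..{profile.hi}]"
        )
    score = 0
    for offset, (nt, decile) in profile.decile_map.items():
        if window.base_at(offset) == nt:
            score += decile
    return score


def max_score(profile: ConsensusProfile) -> int:
    """Maximum attainable matching score: sum over all thresholded offsets."""
    return sum(d for _, d in profile.decile_map.values())


def consensus_string(profile: ConsensusProfile) -> str:
    """One character per offset: uppercase thresholded nucleotide, lowercase
    dominant-but-subthreshold nucleotide, ``'.'`` where frequencies are
    uniform (ties resolved alphabetically)."""
    dec = profile.decile_map
    chars = []
    for offset, row in profile.freq.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.max() - vals.min() < _EPS:
            chars.append(".")
            continue
        if int(offset) in dec:
            chars.append(dec[int(offset)][0])
        else:
            top = vals.max()
            winner = next(n for n, v in zip(NUCLEOTIDES, vals) if v > top - _EPS)
            chars.append(winner.lower())
    return "".join(chars)


def profile_shift_report(
    profile_a: ConsensusProfile, profile_b: ConsensusProfile
) -> pd.DataFrame:
    """Offsets where the thresholded nucleotide or its decile differ.

    Symmetric: an offset thresholded in only one profile is reported with
    the other side empty.  Profiles must share bounds.
    """
    if profile_a.bounds != profile_b.bounds:
        raise ValueError(
            f"profile bounds differ: {profile_a.bounds} vs {profile_b.bounds}"
        )
    dec_a = profile_a.decile_map
    dec_b = profile_b.decile_map
    rows = []
    for offset in sorted(set(dec_a) | set(dec_b)):
        a = dec_a.get(offset)
        b = dec_b.get(offset)
        if a != b:
            rows.append(
                {
                    "offset": offset,
                    "nt_a": a[0] if a else "",
                    "decile_a": a[1] if a else 0,
                    "nt_b": b[0] if b else "",
                    "decile_b": b[1] if b else 0,
                }
            )
    return pd.DataFrame(rows, columns=["offset", "nt_a", "decile_a", "nt_b", "decile_b"])
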