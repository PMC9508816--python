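"""PLS-type PPR arrays and the PPR-RNA recognition code.

Plant organelle C-to-U editing factors carry an array of pentatricopeptide
repeats (PPRs) that reads the RNA upstream of the edited cytidine one
nucleotide per repeat.  Two amino-acid positions within each repeat --
position 5 and the terminal ("Last", L) position -- specify the nucleotide
preference through a small combinatorial code:

    ======  ======  ==========
    pos 5   pos L   nucleotide
    ======  ======  ==========
    T or S  N       A
    T or S  D       G
    N       S       C
    N       D       U
    N       N       C or U
    ======  ======  ==========

Any other (5, L) combination carries no prediction.  Repeats are numbered
backwards from the C-terminus (terminal repeat = 1) and the terminal S2-type
repeat is juxtaposed with target position -4, counting the edited cytidine
as position 0; repeat number ``n`` therefore reads target position
``-(n + 3)``.

Internally all nucleotides are handled in the DNA alphabet (U is accepted on
input and normalised to T) because transcriptome FASTA files and pileup
tables are DNA-alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "MOTIF_CLASSES",
    "PPRMotif",
    "EditingFactor",
    "code_prediction",
    "motif_position",
    "classify_pair",
    "juxtapose",
    "mutate_motif",
    "match_tally",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: PPR variants of the PLS array: canonical (P), long (L), short (S) and the
#: C-terminal P2-L2-S2 triplet preceding the E1/E2/DYW domains.
MOTIF_CLASSES = ("P", "L", "S", "P2", "L2", "S2")

#: Motif classes covered by the core code; L/L2 preferences are empirical only.
CANONICAL_CLASSES = frozenset({"P", "S", "P2", "S2"})

_CODE: dict[tuple[str, str], frozenset[str]] = {
    ("T", "N"): frozenset("A"),
    ("S", "N"): frozenset("A"),
    ("T", "D"): frozenset("G"),
    ("S", "D"): frozenset("G"),
    ("N", "S"): frozenset("C"),
    ("N", "D"): frozenset("T"),
    ("N", "N"): frozenset("CT"),
}

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def normalize_base(base: str) -> str:
    """Uppercase a single nucleotide and map RNA U onto DNA T."""
    b = base.upper()
    return "T" if b == "U" else b


def _check_aa(aa: str, name: str) -> str:
    if not isinstance(aa, str) or len(aa) != 1 or aa not in AA_ALPHABET:
        raise ValueError(
            f"{name} must be a single uppercase amino-acid letter, got {aa!r}"
        )
    return aa


def code_prediction(aa5: str, aaL: str) -> frozenset[str]:
    """Predicted nucleotide set for a (position 5, position L) pair.

    Returns a frozenset over the DNA alphabet; the empty set means the
    combination carries no prediction.
    """
    _check_aa(aa5, "aa5")
    _check_aa(aaL, "aaL")
    return _CODE.get((aa5, aaL), frozenset())


@dataclass(frozen=True)
class PPRMotif:
    """One repeat of a PLS-type PPR array.

    Parameters
    ----------
    motif_class
        One of ``P, L, S, P2, L2, S2``.
    repeat_number
        Backward numbering; the C-terminal repeat is 1.
    aa5, aaL
        One-letter amino acids at positions 5 and L.
    """

    motif_class: str
    repeat_number: int
    aa5: str
    aaL: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if self.repeat_number < 1:
            raise ValueError("repeat_number must be >= 1")
        _check_aa(self.aa5, "aa5")
        _check_aa(self.aaL, "aaL")

    @property
    def label(self) -> str:
        """Label of the form class-number, e.g. ``S-7`` or ``P2-3``."""
        return f"{self.motif_class}-{self.repeat_number}"

    @property
    def canonical(self) -> bool:
        """True for P/S-type repeats covered by the core code."""
        return self.motif_class in CANONICAL_CLASSES

    @classmethod
    def from_label(cls, label: str, aa5: str, aaL: str) -> "PPRMotif":
        """Build a motif from a ``class-number`` label such as ``S2-1``."""
        try:
            motif_class, num = label.rsplit("-", 1)
            repeat_number = int(num)
        except ValueError as exc:
            raise ValueError(f"malformed motif label {label!r}") from exc
        return cls(motif_class, repeat_number, aa5, aaL)

    def prediction(self) -> frozenset[str]:
        return code_prediction(self.aa5, self.aaL)


def motif_position(motif: PPRMotif | int) -> int:
    """Target offset read by a repeat under backward numbering.

    The terminal S2-1 repeat aligns with offset -4 relative to the edited
    cytidine at offset 0; repeat number ``n`` reads offset ``-(n + 3)``,
    one nucleotide per repeat.
    """
    n = motif.repeat_number if isinstance(motif, PPRMotif) else int(motif)
    if n < 1:
        raise ValueError("repeat_number must be >= 1")
    return -(n + 3)


@dataclass(frozen=True)
class EditingFactor:
    """A PLS-type editing factor: an ordered PPR array plus bookkeeping.

    ``motifs`` run from N- to C-terminus; the terminal motif must be S2-1 and
    repeat numbers strictly decrease toward the C-terminus.  ``has_dyw``
    records whether the construct carries a functional DYW deaminase domain
    (editing-dead DYW mutants serve as control samples downstream).
    """

    name: str
    motifs: tuple[PPRMotif, ...]
    has_dyw: bool = True

    def __post_init__(self) -> None:
        motifs = tuple(self.motifs)
        object.__setattr__(self, "motifs", motifs)
        if not motifs:
            raise ValueError("factor needs at least one motif")
        last = motifs[-1]
        if last.motif_class != "S2" or last.repeat_number != 1:
            raise ValueError("terminal motif must be S2-1")
        numbers = [m.repeat_number for m in motifs]
        if any(a <= b for a, b in zip(numbers, numbers[1:])):
            raise ValueError("repeat numbers must strictly decrease toward C-terminus")
        labels = [m.label for m in motifs]
        if len(set(labels)) != len(labels):
            raise ValueError("motif labels must be unique")

    def __getitem__(self, label: str) -> PPRMotif:
        for m in self.motifs:
            if m.label == label:
                return m
        raise KeyError(f"no motif labelled {label!r} in factor {self.name!r}")

    @property
    def positions(self) -> tuple[int, ...]:
        """Target offsets read by the array, N- to C-terminal."""
        return tuple(motif_position(m) for m in self.motifs)

    @property
    def span(self) -> tuple[int, int]:
        """(lowest, highest) target offset covered by the array."""
        pos = self.positions
        return min(pos), max(pos)


def classify_pair(predicted: frozenset[str] | set[str], observed: str) -> str:
    """Classify an observed nucleotide against a predicted set.

    ``match`` if the observed base is in the predicted set; ``transition`` if
    it is the purine-purine or pyrimidine-pyrimidine partner of a predicted
    base (and not a match); ``transversion`` otherwise; ``none`` when the
    predicted set is empty or the observed symbol is a pad/ambiguity code.
    If any predicted nucleotide makes it a match, match wins; else if any
    makes it a transition, transition wins.
    """
    if not predicted:
        return "none"
    obs = normalize_base(observed)
    if obs not in _TRANSITION_PARTNER:
        # pads ('-') and N carry no observable nucleotide
        return "none"
    pred = {normalize_base(p) for p in predicted}
    if obs in pred:
        return "match"
    if any(_TRANSITION_PARTNER[p] == obs for p in pred):
        return "transition"
    return "transversion"


def _render_set(pred: frozenset[str]) -> str:
    return "/".join(sorted(pred))


def juxtapose(factor: EditingFactor, window) -> pd.DataFrame:
    """Align a factor's PPR array with a target window.

    Returns a table with one row per motif (N- to C-terminal):
    ``motif, position, predicted, observed, class, canonical``.

    Raises an out-of-range error naming the first uncovered position when the
    window is too short for the array.
    """
    rows = []
    for motif in factor.motifs:
        pos = motif_position(motif)
        if pos < window.lo or pos > window.hi:
            raise IndexError(
                f"window [{window.lo}..{window.hi}] does not cover motif "
                f"{motif.label} at position {pos}"
            )
        observed = window.base_at(pos)
        predicted = motif.prediction()
        rows.append(
            {
                "motif": motif.label,
                "position": pos,
                "predicted": _render_set(predicted),
                "observed": observed,
                "class": classify_pair(predicted, observed),
                "canonical": motif.canonical,
            }
        )
    return pd.DataFrame(rows)


def mutate_motif(
    factor: EditingFactor, label: str, new_aa5: str, new_aaL: str
) -> EditingFactor:
    """Return a copy of ``factor`` with one motif's 5/L identities replaced.

    The original factor is unmodified; an unknown label raises ``KeyError``.
    """
    factor[label]  # raise KeyError early for unknown labels
    motifs = tuple(
        replace(m, aa5=new_aa5, aaL=new_aaL) if m.label == label else m
        for m in factor.motifs
    )
    return replace(factor, motifs=motifs)


def match_tally(factor: EditingFactor, windows: Iterable) -> pd.DataFrame:
    """Per-motif counts of match/transition/transversion over many windows.

    Rows classified ``none`` (no prediction, or pad/N observed) are counted in
    their own column so that per-motif counts always sum to the number of
    windows.
    """
    labels = [m.label for m in factor.motifs]
    tally = pd.DataFrame(
        0,
        index=pd.Index(labels, name="motif"),
        columns=["match", "transition", "transversion", "none"],
    )
    for window in windows:
        table = juxtapose(factor, window)
        for _, row in table.iterrows():
            tally.loc[row["motif"], row["class"]] += 1
    return tally
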