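"""Readers and writers for the pipeline's plain-text interchange formats.

Everything tabular is TSV (protein names may contain commas); FASTA goes
through Biopython.  Tables are schema-validated on read and malformed rows
are reported with their line number.  Sequence data is normalised to the
uppercase DNA alphabet on input.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import PILEUP_COLUMNS, TranscriptAnnotation
from .code import EditingFactor, PPRMotif
from .profile import NUCLEOTIDES, ConsensusProfile, TargetWindow, consensus_string

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_transcriptome",
    "read_pileups",
    "write_pileups",
    "read_windows",
    "write_windows",
    "parse_factor_text",
    "read_factor",
    "write_factor",
    "read_profile",
    "write_profile",
    "write_meme",
    "read_config",
    "write_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "transcript_id", "gene", "protein_name", "cds_start", "cds_end", "num_reads",
]
WINDOW_COLUMNS = ["gene", "transcript", "position", "sequence", "rate"]
PROFILE_COLUMNS = ["offset", "fA", "fC", "fG", "fT", "consensus_char", "decile"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> uppercase-DNA mapping (ids kept verbatim)."""
    records: dict[str, str] = {}
    mixed_case = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            mixed_case = True
        records[rec.id] = seq.upper().replace("U", "T")
    if mixed_case:
        logger.info("mixed-case sequences in %s normalised to uppercase", path)
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _read_tsv(path: str | Path, columns: Sequence[str],
              numeric: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} in "
                f"column {col!r} at line {line}"
            )
        df[col] = converted
    return df


def _write_tsv(path: str | Path, df: pd.DataFrame,
               header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript annotation

def read_annotations(path: str | Path,
                     sequences: Mapping[str, str]) -> list[TranscriptAnnotation]:
    """Annotation TSV + sequences -> TranscriptAnnotation records."""
    df = _read_tsv(path, ANNOTATION_COLUMNS,
                   numeric=["cds_start", "cds_end", "num_reads"])
    out = []
    for i, row in df.iterrows():
        tid = row["transcript_id"]
        if tid not in sequences:
            raise ValueError(
                f"{path}: transcript {tid!r} (line {i + 2}) absent from FASTA"
            )
        out.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene=row["gene"],
                protein_name=row["protein_name"],
                sequence=sequences[tid],
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                num_reads=float(row["num_reads"]),
            )
        )
    return out


def write_annotations(path: str | Path,
                      annotations: Sequence[TranscriptAnnotation],
                      header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "gene": a.gene,
                "protein_name": a.protein_name,
                "cds_start": a.cds_start,
                "cds_end": a.cds_end,
                "num_reads": a.num_reads,
            }
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    )
    _write_tsv(path, df, header_comment)


def read_transcriptome(fasta_path: str | Path,
                       annotation_path: str | Path) -> dict[str, TranscriptAnnotation]:
    seqs = read_fasta(fasta_path)
    return {a.transcript_id: a for a in read_annotations(annotation_path, seqs)}


# ---------------------------------------------------------------------------
# pileups

def read_pileups(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, PILEUP_COLUMNS,
                   numeric=["position", "nA", "nC", "nG", "nT"])
    for col in ["position", "nA", "nC", "nG", "nT"]:
        df[col] = df[col].astype(int)
    return df[PILEUP_COLUMNS]


def write_pileups(path: str | Path, pileups: pd.DataFrame,
                  header_comment: str | None = None) -> None:
    missing = [c for c in PILEUP_COLUMNS if c not in pileups.columns]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    _write_tsv(path, pileups[PILEUP_COLUMNS], header_comment)


# ---------------------------------------------------------------------------
# target windows

def read_windows(path: str | Path, lo: int = -30) -> list[TargetWindow]:
    """Window TSV -> TargetWindow list; ``lo`` is the offset of the first
    sequence character (windows are written with their own lo recorded in a
    header comment, which takes precedence when present)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# lo="):
        lo = int(first.strip().split("=", 1)[1])
    df = _read_tsv(path, WINDOW_COLUMNS, numeric=["position", "rate"])
    out = []
    for _, row in df.iterrows():
        rate = None if row["rate"] != row["rate"] else float(row["rate"])  # NaN check
        out.append(
            TargetWindow(
                gene=row["gene"],
                transcript_id=row["transcript"],
                site_position=int(row["position"]),
                sequence=row["sequence"],
                lo=lo,
                edit_rate=rate,
            )
        )
    return out


def write_windows(path: str | Path, windows: Sequence[TargetWindow]) -> None:
    if not windows:
        raise ValueError("no windows to write")
    lo = windows[0].lo
    if any(w.lo != lo for w in windows):
        raise ValueError("all windows in one file must share their offset range")
    df = pd.DataFrame(
        [
            {
                "gene": w.gene,
                "transcript": w.transcript_id,
                "position": w.site_position,
                "sequence": w.sequence,
                "rate": "" if w.edit_rate is None else w.edit_rate,
            }
            for w in windows
        ],
        columns=WINDOW_COLUMNS,
    )
    _write_tsv(path, df, header_comment=f"lo={lo}")


# ---------------------------------------------------------------------------
# factor definitions

def parse_factor_text(text: str, name: str = "factor",
                      has_dyw: bool = True) -> EditingFactor:
    """One motif per line: label, class, aa5, aaL (tab-separated, N->C order,
    ``#`` comments allowed)."""
    motifs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(
                f"factor definition line {lineno}: expected 4 tab-separated "
                f"fields, got {len(fields)}"
            )
        label, motif_class, aa5, aaL = (f.strip() for f in fields)
        motif = PPRMotif.from_label(label, aa5, aaL)
        if motif.motif_class != motif_class:
            raise ValueError(
                f"factor definition line {lineno}: label {label!r} disagrees "
                f"with class {motif_class!r}"
            )
        motifs.append(motif)
    if not motifs:
        raise ValueError("factor definition contains no motifs")
    return EditingFactor(name, tuple(motifs), has_dyw=has_dyw)


def read_factor(path: str | Path, name: str | None = None,
                has_dyw: bool = True) -> EditingFactor:
    text = Path(path).read_text()
    return parse_factor_text(text, name=name or Path(path).stem, has_dyw=has_dyw)


def write_factor(path: str | Path, factor: EditingFactor) -> None:
    lines = [f"# factor: {factor.name}"]
    for m in factor.motifs:
        lines.append(f"{m.label}\t{m.motif_class}\t{m.aa5}\t{m.aaL}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# consensus profiles

def write_profile(path: str | Path, profile: ConsensusProfile,
                  header_comment: str | None = None) -> None:
    cons = consensus_string(profile)
    dec = profile.decile_map
    rows = []
    for i, (offset, row) in enumerate(profile.freq.iterrows()):
        d = dec.get(int(offset))
        rows.append(
            {
                "offset": int(offset),
                "fA": row["A"], "fC": row["C"], "fG": row["G"], "fT": row["T"],
                "consensus_char": cons[i],
                "decile": d[1] if d else 0,
            }
        )
    _write_tsv(path, pd.DataFrame(rows, columns=PROFILE_COLUMNS), header_comment)


def read_profile(path: str | Path) -> ConsensusProfile:
    df = _read_tsv(path, PROFILE_COLUMNS,
                   numeric=["offset", "fA", "fC", "fG", "fT", "decile"])
    freq = pd.DataFrame(
        {
            "A": df["fA"].to_numpy(float),
            "C": df["fC"].to_numpy(float),
            "G": df["fG"].to_numpy(float),
            "T": df["fT"].to_numpy(float),
        },
        index=pd.Index(df["offset"].astype(int), name="offset"),
    )
    return ConsensusProfile(freq)


def write_meme(path: str | Path, profile: ConsensusProfile,
               name: str = "consensus_profile") -> None:
    """Minimal MEME-format position-frequency-matrix export."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {profile.n_offsets}",
    ]
    for _, row in profile.freq.iterrows():
        lines.append(" ".join(f"{row[n]:.6f}" for n in NUCLEOTIDES))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# configuration

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def write_config(path: str | Path, config: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
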