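"""Readers and writers for the formats the pipeline touches.

Covers FASTA protein sequences (via Biopython), PSI-BLAST ASCII PSSM
profiles, two-column label tables, and the joined dataset loader.  The
package never runs PSI-BLAST itself; profiles are parsed from the ASCII
files the ``-out_ascii_pssm`` option writes (conventionally generated with
e-value 0.001, 3 iterations, against SwissProt).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in PSI-BLAST column order.
PSIBLAST_COLUMN_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

#: The 20 standard amino acids alphabetically (row order of composition features).
STANDARD_AMINO_ACIDS = tuple(sorted(PSIBLAST_COLUMN_ORDER))

#: Ambiguity codes tolerated in input sequences.
AMBIGUOUS_RESIDUES = frozenset("XBZUJO")


class FormatError(ValueError):
    """A file did not match the expected on-disk format."""


@dataclass
class ProteinRecord:
    """One protein: identifier, amino-acid sequence and optional SIP label.

    ``label`` is 1 for a self-interacting protein (SIP), 0 for a non-SIP,
    and ``None`` when unknown.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label for {self.id!r} must be 0 or 1, got {self.label!r}")


@dataclass
class PSSMMatrix:
    """A protein's N x 20 evolutionary score profile.

    ``scores`` holds the raw PSI-BLAST log-odds block (integer-valued in
    practice), one row per residue; ``residues`` is the length-N sequence
    read back from the profile; ``column_order`` preserves the 20-letter
    column header verbatim from the source file.
    """

    scores: np.ndarray
    residues: str
    column_order: Tuple[str, ...] = PSIBLAST_COLUMN_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM scores must be N x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise FormatError("PSSM must have at least one row")
        if self.scores.shape[0] != len(self.residues):
            raise FormatError(
                f"PSSM has {self.scores.shape[0]} rows but {len(self.residues)} residues"
            )
        self.column_order = tuple(self.column_order)
        if sorted(self.column_order) != sorted(PSIBLAST_COLUMN_ORDER):
            raise FormatError(
                "column_order must be a permutation of the 20 standard amino acids"
            )

    @property
    def n_residues(self) -> int:
        return self.scores.shape[0]


def read_fasta(path: os.PathLike | str) -> List[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (labels absent).

    The record id is the first whitespace-delimited header token; sequences
    are uppercased with line breaks removed.
    """
    records: List[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {entry.id!r} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    seen: set = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def write_fasta(records: Sequence[ProteinRecord], path: os.PathLike | str, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_HEADER_RE = re.compile(r"^\s*([A-Z](?:\s+[A-Z]){19,39})\s*$")


def parse_psiblast_pssm(text: str) -> PSSMMatrix:
    """Parse the ASCII PSSM that PSI-BLAST writes with ``-out_ascii_pssm``.

    The file carries two header lines, a 20- or 40-letter column header
    (log-odds block followed, in full files, by weighted-percentage
    columns), then one row per residue: index, residue letter, and at least
    20 integer columns.  Only the first 20 numeric columns (the log-odds
    block) are kept; trailing percentage/information/weight columns and the
    closing statistics lines are ignored.
    """
    lines = text.splitlines()
    column_order: Optional[Tuple[str, ...]] = None
    rows: List[List[float]] = []
    residues: List[str] = []
    for lineno, line in enumerate(lines, start=1):
        if column_order is None:
            m = _HEADER_RE.match(line)
            if m:
                letters = m.group(1).split()
                column_order = tuple(letters[:20])
            continue
        stripped = line.strip()
        if not stripped:
            if rows:
                break  # blank line after the data block ends the matrix
            continue
        parts = stripped.split()
        if not parts[0].isdigit():
            if rows:
                break  # trailing statistics (K, Lambda, ...) after the block
            continue
        if len(parts) < 2 or not parts[1].isalpha():
            raise FormatError(f"malformed PSSM row at line {lineno}: {stripped!r}")
        numeric = parts[2:]
        if len(numeric) < 20:
            raise FormatError(
                f"PSSM row {parts[0]} (line {lineno}) has {len(numeric)} numeric "
                "fields; expected at least 20"
            )
        try:
            rows.append([float(x) for x in numeric[:20]])
        except ValueError as exc:
            raise FormatError(f"non-numeric score in PSSM row at line {lineno}") from exc
        residues.append(parts[1].upper())
    if column_order is None:
        raise FormatError("PSSM file has no 20-letter column header")
    if not rows:
        raise FormatError("PSSM file contains no data rows (empty profile)")
    return PSSMMatrix(
        scores=np.array(rows, dtype=float),
        residues="".join(residues),
        column_order=column_order,
    )


def read_pssm_file(path: os.PathLike | str) -> PSSMMatrix:
    """Read and parse one PSI-BLAST ASCII PSSM file."""
    return parse_psiblast_pssm(Path(path).read_text())


def write_psiblast_pssm(pssm: PSSMMatrix, path: os.PathLike | str) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect :func:`parse_psiblast_pssm` reads.

    Emits the doubled 20-letter header and, per row, the 20 log-odds
    columns followed by 20 zero percentage columns and the two trailing
    per-row statistics, mirroring real ``-out_ascii_pssm`` output.
    """
    letters = " ".join(pssm.column_order)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + letters + "   " + letters + "\n")
        for i in range(pssm.n_residues):
            scores = "".join(f"{int(round(v)):4d}" for v in pssm.scores[i])
            percents = "".join(f"{0:4d}" for _ in range(20))
            fh.write(
                f"{i + 1:5d} {pssm.residues[i]} {scores} {percents}  0.00 0.00\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3176\n")


def read_labels(path: os.PathLike | str) -> Dict[str, int]:
    """Read a two-column (id, 0/1) label table; tab or comma delimited, header optional."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"label table {path} needs two columns (id, label)")
    first = str(df.iloc[0, 1]).strip()
    if first not in ("0", "1"):  # header row
        df = df.iloc[1:]
    labels: Dict[str, int] = {}
    for _, row in df.iterrows():
        pid, lab = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        if lab not in ("0", "1"):
            raise FormatError(f"label for {pid!r} must be 0 or 1, got {lab!r}")
        if pid in labels:
            raise FormatError(f"duplicate id {pid!r} in label table")
        labels[pid] = int(lab)
    if not labels:
        raise FormatError(f"label table {path} is empty")
    return labels


def write_labels(labels: Dict[str, int], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")


# Curated datasets retain proteins of 50-5000 residues only.
CURATED_LENGTH_RANGE = (50, 5000)


def load_dataset(
    fasta: os.PathLike | str,
    pssm_dir: os.PathLike | str,
    labels: os.PathLike | str,
    *,
    pssm_pattern: str = "{id}.pssm",
    curated: bool = False,
    strict: bool = True,
) -> Tuple[List[ProteinRecord], Dict[str, PSSMMatrix]]:
    """Join FASTA sequences, per-protein PSSM files and a label table.

    Only proteins present in all three sources are returned, each with its
    label attached.  A protein whose PSSM residue string disagrees with its
    FASTA sequence is dropped with a warning.  With ``curated=True`` the
    50-5000 residue length filter of the curated gold-standard sets is
    enforced.  In strict mode (default) a labelled protein with no PSSM
    file is a hard error; in lenient mode it is skipped with a warning.
    """
    records = read_fasta(fasta)
    label_map = read_labels(labels)
    pssm_dir = Path(pssm_dir)
    if not pssm_dir.is_dir():
        raise FileNotFoundError(f"PSSM directory not found: {pssm_dir}")

    labelled = [r for r in records if r.id in label_map]
    missing = [
        r.id for r in labelled if not (pssm_dir / pssm_pattern.format(id=r.id)).exists()
    ]
    if missing and strict:
        raise FileNotFoundError(
            f"missing PSSM files for {len(missing)} labelled proteins: "
            + ", ".join(sorted(missing))
        )

    out_records: List[ProteinRecord] = []
    pssms: Dict[str, PSSMMatrix] = {}
    for rec in labelled:
        path = pssm_dir / pssm_pattern.format(id=rec.id)
        if not path.exists():
            logger.warning("skipping %s: no PSSM file", rec.id)
            continue
        pssm = read_pssm_file(path)
        if pssm.residues.upper() != rec.sequence:
            logger.warning(
                "skipping %s: PSSM residues disagree with FASTA sequence", rec.id
            )
            continue
        if curated and not (
            CURATED_LENGTH_RANGE[0] <= len(rec.sequence) <= CURATED_LENGTH_RANGE[1]
        ):
            logger.warning(
                "skipping %s: length %d outside curated range %s",
                rec.id,
                len(rec.sequence),
                CURATED_LENGTH_RANGE,
            )
            continue
        out_records.append(
            ProteinRecord(id=rec.id, sequence=rec.sequence, label=label_map[rec.id])
        )
        pssms[rec.id] = pssm
    return out_records, pssms
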