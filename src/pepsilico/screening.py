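"""Threshold screening of externally scored peptide lists.

Bioactivity-probability scores (e.g. from a peptide-ranking server) are
consumed as data; the ranking model itself is out of scope.  Screening is
inclusive (score >= threshold), because peptides scored exactly at the
published 0.9 cut-off are retained in the source data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .peptide import Peptide, PeptideError, parse_peptide


@dataclass(frozen=True)
class RankedPeptide:
    """A peptide with an external bioactivity-probability score in [0, 1]."""

    peptide: Peptide
    score: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def screen_by_score(
    items: list[RankedPeptide], threshold: float = 0.9
) -> list[RankedPeptide]:
    """Retain peptides with score >= threshold, by descending score.

    Ties keep input order (stable sort); the input list is untouched.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    kept = [item for item in items if item.score >= threshold]
    return sorted(kept, key=lambda item: -item.score)


def read_scored_csv(path: str | Path) -> list[RankedPeptide]:
    """Read a scored peptide list from CSV with columns sequence, score, sample."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sequence", "score"} <= set(
            reader.fieldnames
        ):
            raise PeptideError(
                f"{path}: header must contain 'sequence' and 'score' columns"
            )
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    RankedPeptide(
                        peptide=parse_peptide(row["sequence"]),
                        score=float(row["score"]),
                        sample_label=(row.get("sample") or "").strip(),
                    )
                )
            except (PeptideError, ValueError) as exc:
                raise PeptideError(f"{path}, line {i}: {exc}") from exc
    return out


def read_fasta(path: str | Path, sample_label: str = "") -> list[RankedPeptide]:
    """Read unscored peptides from FASTA; every record gets score 1.0.

    Use when screening is skipped or scores are supplied separately.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append(
            RankedPeptide(
                peptide=parse_peptide(str(record.seq)),
                score=1.0,
                sample_label=sample_label or record.id,
            )
        )
    return out
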