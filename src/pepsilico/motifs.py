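"""Bioactive-fragment database and motif scanner.

The bundled database holds short (2-3 residue) fragments with documented
antioxidative or ACE-inhibitory activity, snapshotted from published motif
tables.  Scanning reports every placement of every fragment of the requested
activity as a contiguous substring of the query, including overlapping and
repeated placements; the occurrence frequency A = a / N counts placements,
not distinct sequences.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path

import pandas as pd

from .peptide import Peptide, parse_peptide

ANTIOXIDATIVE = "antioxidative"
ACE_INHIBITOR = "ACE-inhibitor"
ACTIVITIES = (ANTIOXIDATIVE, ACE_INHIBITOR)


class MotifDBError(ValueError):
    pass


@dataclass(frozen=True)
class MotifRecord:
    """An activity-annotated bioactive fragment of length 2-3."""

    fragment: Peptide
    activity: str
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.fragment) not in (2, 3):
            raise MotifDBError(
                f"fragment {self.fragment} has length {len(self.fragment)}; "
                "motifs must be di- or tripeptides"
            )
        if self.activity not in ACTIVITIES:
            raise MotifDBError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )


@dataclass(frozen=True)
class MotifOccurrence:
    """A motif placement at 1-based inclusive (start, end) in a query."""

    motif: MotifRecord
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif.fragment):
            raise MotifDBError("span length does not match motif length")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ActivityProfile:
    """All placements of fragments with one activity inside a query.

    ``a`` is the placement count and ``A = a / N`` the frequency of
    occurrence per residue of the query.
    """

    query: Peptide
    activity: str
    occurrences: tuple[MotifOccurrence, ...]

    @property
    def a(self) -> int:
        return len(self.occurrences)

    @property
    def frequency(self) -> float:
        return self.a / len(self.query)


class MotifDB:
    """Indexed collection of motif records with per-activity iteration."""

    def __init__(self, records: list[MotifRecord]):
        seen: dict[tuple[str, str], MotifRecord] = {}
        for rec in records:
            key = (str(rec.fragment), rec.activity)
            if key in seen:
                raise MotifDBError(
                    f"duplicate motif {key[0]!r} for activity {key[1]!r}"
                )
            seen[key] = rec
        self._records = dict(seen)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def fragments(self, activity: str) -> list[MotifRecord]:
        if activity not in ACTIVITIES:
            raise MotifDBError(
                f"unknown activity {activity!r}; expected one of {ACTIVITIES}"
            )
        return [r for r in self._records.values() if r.activity == activity]

    def lookup(self, fragment: str, activity: str) -> MotifRecord | None:
        return self._records.get((fragment, activity))

    @classmethod
    def from_records(cls, rows: list[dict]) -> "MotifDB":
        records = []
        for i, row in enumerate(rows, start=1):
            try:
                records.append(
                    MotifRecord(
                        fragment=parse_peptide(row["fragment"]),
                        activity=row["activity"],
                        name=row.get("name", ""),
                        provenance=row.get("provenance", ""),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise MotifDBError(f"motif record {i}: {exc}") from exc
        return cls(records)


def load_motif_db(resource: str | Path | None = None) -> MotifDB:
    """Load a motif database from TSV or JSON (bundled snapshot by default)."""
    if resource is None:
        with _ilres.files("pepsilico.resources").joinpath("motifs.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        path = Path(resource)
        if path.suffix == ".json":
            rows = json.loads(path.read_text())
            return MotifDB.from_records(rows)
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if frame.empty and list(frame.columns) == []:
            return MotifDB([])
    frame = frame.fillna("")
    return MotifDB.from_records(frame.to_dict("records"))


def scan_motifs(p: Peptide, db: MotifDB, activity: str) -> ActivityProfile:
    """Every placement of every DB fragment of one activity inside ``p``.

    Occurrences are sorted by start position, then fragment length.
    """
    seq = str(p)
    hits: list[MotifOccurrence] = []
    for rec in db.fragments(activity):
        frag = str(rec.fragment)
        start = seq.find(frag)
        while start != -1:
            hits.append(MotifOccurrence(rec, start + 1, start + len(frag)))
            start = seq.find(frag, start + 1)
    hits.sort(key=lambda occ: (occ.start, occ.end - occ.start))
    return ActivityProfile(query=p, activity=activity, occurrences=tuple(hits))


def distinct_motif_count(profile: ActivityProfile) -> int:
    """Number of distinct fragment sequences with at least one placement."""
    return len({str(occ.motif.fragment) for occ in profile.occurrences})


def profile_report(profiles: list[ActivityProfile]) -> pd.DataFrame:
    """Flat table of motif placements (query, activity, fragment, span, name)."""
    rows = []
    for prof in profiles:
        for occ in prof.occurrences:
            rows.append(
                {
                    "query": str(prof.query),
                    "activity": prof.activity,
                    "fragment": str(occ.motif.fragment),
                    "start": occ.start,
                    "end": occ.end,
                    "name": occ.motif.name,
                }
            )
    return pd.DataFrame(
        rows, columns=["query", "activity", "fragment", "start", "end", "name"]
    )
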