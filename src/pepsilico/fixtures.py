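"""Bundled verbatim study tables as structured, checksummed fixtures.

The ten tables of the source study are shipped as TSV resources and loaded
into immutable :class:`Fixture` records.  Printed cells are stored exactly
as published; where a printed coordinate is inconsistent with the sequence
it annotates (a handful of motif locations shifted by one position, one
truncated span, one row omitted from print), the row additionally carries
the corrected value and an ``erratum`` note -- printed errata are flagged,
never silently corrected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources as _ilres

import pandas as pd

TABLE_IDS = tuple(f"table{i}" for i in range(1, 11))

# sha256 of the packaged TSVs; load_fixture refuses silently altered data.
CHECKSUMS = {
    "table1": "4c4505a9b43026312358622c667c50a4dc6faea573ac475c9833bf7d09d095c8",
    "table2": "49150d2c409eda1d625df0d6829e37edf8ce4a33b806cd7811c87496fa23aa24",
    "table3": "b651bc69537ab0a900736720739c4c2d38839623db8f6afb66676babf1861873",
    "table4": "4be30056ee45a37eed1480fb0e1b8dbd70ed6c365f1ef25de5e7580e7059230e",
    "table5": "d97ae9eee2a9fcf5f3f4d9b7783b5425ac34e2242b43571214ec088f322cff6c",
    "table6": "924427086cbf304a8472b10326ee3fd787fbee2b78b55185c97ac710cab83d07",
    "table7": "3484568ff1ed51189c92a57a79e220baa40dfb210fac08c4be68d2c983b7c8ff",
    "table8": "6728013b00c33c82d5554b0405f9eaf3b7b635a71b32773fc7db7f154a16e61a",
    "table9": "40393dd5014c5676db5fb3e2f3e0dc99c8b928bdeb82bcbed84a7a7f60547336",
    "table10": "306788f06a486f8c7e72d3ad1053fa48dd2861d3c8c95576808d029d032cd5a6",
}

_DESCRIPTIONS = {
    "table1": "Screened peptide lists with bioactivity-probability scores",
    "table2": "Antioxidative motif profile, flower hydrolysate",
    "table3": "Antioxidative motif profile, internal-organs hydrolysate",
    "table4": "ACE-inhibitory motif profile, flower hydrolysate",
    "table5": "ACE-inhibitory motif profile, internal-organs hydrolysate",
    "table6": "Simulated GI digestion and released fragments, flower",
    "table7": "Simulated GI digestion and released fragments, internal organs",
    "table8": "Proteolysis descriptors DHt / A_E / W",
    "table9": "Physicochemical properties and toxicity of released dipeptides",
    "table10": "Drug-likeness (ADME) panel incl. the captopril benchmark",
}


@dataclass(frozen=True)
class Fixture:
    name: str
    description: str
    rows: tuple[dict, ...]
    sha256: str

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))


def load_fixture(name: str) -> Fixture:
    """Load one named table ("table1" ... "table10") as structured records."""
    if name not in TABLE_IDS:
        raise KeyError(f"unknown fixture {name!r}; available: {list(TABLE_IDS)}")
    raw = (
        _ilres.files("pepsilico.resources")
        .joinpath(f"tables/{name}.tsv")
        .read_bytes()
    )
    digest = hashlib.sha256(raw).hexdigest()
    if digest != CHECKSUMS[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    frame = pd.read_csv(
        _ilres.files("pepsilico.resources").joinpath(f"tables/{name}.tsv"),
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    return Fixture(
        name=name,
        description=_DESCRIPTIONS[name],
        rows=tuple(frame.to_dict("records")),
        sha256=digest,
    )


def parse_span(text: str) -> tuple[int, int]:
    """Parse a "start-end" location cell into a 1-based inclusive span."""
    start, end = text.split("-")
    return int(start), int(end)


def parse_spans(text: str) -> list[tuple[int, int]]:
    """Parse a semicolon-separated list of location cells."""
    return [parse_span(part) for part in text.split(";")] if text else []
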