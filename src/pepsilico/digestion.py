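"""Simulated gastrointestinal proteolysis.

Cleavage is rule-based and all-or-none: an enzyme cuts the bond C-terminal
to any P1 residue unless the following (P1') residue is in its exclusion
set.  The default panel (pepsin, trypsin, chymotrypsin) acts concurrently
in a single pass over the parent peptide; because the rules only inspect
the two residues flanking a bond, sequential per-enzyme re-digestion yields
the identical fragment set and is provided for completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path
from typing import Literal

import pandas as pd

from .motifs import MotifDB, MotifOccurrence, scan_motifs
from .peptide import Peptide, PeptideError, STANDARD_RESIDUES


@dataclass(frozen=True)
class CleavageRule:
    """Declarative P1/P1' bond-cleavage specificity of one protease."""

    enzyme_name: str
    ec_number: str
    p1_residues: frozenset[str]
    p1prime_exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValueError(f"{self.enzyme_name}: empty P1 residue set")
        bad = (self.p1_residues | self.p1prime_exclusions) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"{self.enzyme_name}: non-standard residues {sorted(bad)}")

    def cleaves(self, p1: str, p1prime: str) -> bool:
        return p1 in self.p1_residues and p1prime not in self.p1prime_exclusions


@dataclass(frozen=True)
class DigestResult:
    """Fragments and cleaved bonds from digesting one peptide.

    Bond ``i`` joins residues ``i`` and ``i+1`` (1-based); fragments tile
    the full sequence contiguously.  A peptide with no susceptible bonds is
    "resistant" and yields itself as its single fragment.
    """

    query: Peptide
    cleaved_bonds: frozenset[int]
    fragments: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def d_bonds(self) -> int:
        return len(self.cleaved_bonds)

    @property
    def resistant(self) -> bool:
        return not self.cleaved_bonds

    @property
    def fragment_sequences(self) -> list[str]:
        return [seq for seq, _ in self.fragments]


def load_enzyme_rules(
    rule_set: str = "gi-default", resource: str | Path | None = None
) -> list[CleavageRule]:
    """Load a named enzyme rule set from the bundled (or a user) JSON file."""
    if resource is None:
        data = json.loads(
            _ilres.files("pepsilico.resources").joinpath("enzymes.json").read_text()
        )
    else:
        data = json.loads(Path(resource).read_text())
    sets = data["rule_sets"]
    if rule_set not in sets:
        raise PeptideError(
            f"unknown enzyme rule set {rule_set!r}; available: {sorted(sets)}"
        )
    return [
        CleavageRule(
            enzyme_name=e["name"],
            ec_number=e["ec"],
            p1_residues=frozenset(e["p1"]),
            p1prime_exclusions=frozenset(e.get("p1prime_block", [])),
        )
        for e in sets[rule_set]["enzymes"]
    ]


def cleavage_sites(p: Peptide, rules: list[CleavageRule]) -> frozenset[int]:
    """Union over rules of susceptible bond indices (1 <= i <= N-1)."""
    if not rules:
        raise ValueError("at least one cleavage rule is required")
    seq = str(p)
    return frozenset(
        i
        for i in range(1, len(seq))
        for rule in rules
        if rule.cleaves(seq[i - 1], seq[i])
    )


def digest(
    p: Peptide,
    rules: list[CleavageRule],
    mode: Literal["concurrent", "sequential"] = "concurrent",
) -> DigestResult:
    """Cut at every susceptible bond and return the fragment partition."""
    if mode == "concurrent":
        sites = cleavage_sites(p, rules)
    elif mode == "sequential":
        sites = frozenset()
        for rule in rules:
            sites = sites | cleavage_sites(p, [rule])
    else:
        raise ValueError(f"unknown digestion mode {mode!r}")
    seq = str(p)
    bounds = [0, *sorted(sites), len(seq)]
    fragments = tuple(
        (seq[a:b], (a + 1, b)) for a, b in zip(bounds, bounds[1:])
    )
    return DigestResult(query=p, cleaved_bonds=sites, fragments=fragments)


def released_active_fragments(
    result: DigestResult, db: MotifDB, activity: str
) -> list[tuple[str, tuple[int, int]]]:
    """Digestion fragments whose entire sequence is a DB motif of ``activity``."""
    profile = scan_motifs(result.query, db, activity)  # validates activity
    del profile
    return [
        (seq, span)
        for seq, span in result.fragments
        if db.lookup(seq, activity) is not None
    ]


def digest_report(
    results: list[DigestResult], db: MotifDB, activities: list[str]
) -> pd.DataFrame:
    """Table mirroring the published digestion layout, one row per peptide."""
    rows = []
    for res in results:
        active: list[tuple[str, tuple[int, int], str]] = []
        for activity in activities:
            active += [
                (seq, span, activity)
                for seq, span in released_active_fragments(res, db, activity)
            ]
        rows.append(
            {
                "peptide": str(res.query),
                "fragmentation": "_"
                if res.resistant
                else "-".join(res.fragment_sequences),
                "fragment_spans": ""
                if res.resistant
                else ";".join(f"{a}-{b}" for _, (a, b) in res.fragments),
                "cleaved_bonds": ";".join(map(str, sorted(res.cleaved_bonds))),
                "active_fragments": ";".join(seq for seq, _, _ in active),
                "active_spans": ";".join(f"{a}-{b}" for _, (a, b), _ in active),
                "activities": ";".join(act for _, _, act in active),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "CleavageRule",
    "DigestResult",
    "MotifOccurrence",
    "cleavage_sites",
    "digest",
    "digest_report",
    "load_enzyme_rules",
    "released_active_fragments",
]
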