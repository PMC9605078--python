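"""Amino-acid reference data and sequence-level physicochemical computations.

The residue table (masses, hydropathy scales, pKa sets) is loaded from a
versioned JSON resource bundled with the package.  Average residue masses are
stored at the two-decimal precision conventionally printed by peptide
property calculators; the water mass (18.02 Da average) is stored once.

Conventions
-----------
* ``net_formal_charge`` is an integer formal count at neutral pH: basic
  residues (K, R) and the free amine each contribute +1, acidic residues
  (D, E) and the free carboxyl each -1; histidine is treated as neutral.
* ``isoelectric_point`` solves the Henderson-Hasselbalch net charge for zero
  by bisection on pH in [0, 14].  The default pKa set is ``"sillero"``; an
  ``"emboss"``-style set is available by name.
* Scale means (hydrophobicity, hydrophilicity) are arithmetic means of
  per-residue values; rounding happens only at presentation time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as _ilres
from typing import Iterator, Literal

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

MassMode = Literal["average", "monoisotopic"]


class PeptideError(ValueError):
    """Raised for invalid peptide text or unknown resource names."""


def _load_resource_json(name: str) -> dict:
    with _ilres.files("pepsilico.resources").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PKaSet:
    """Named set of ionisation constants for termini and side chains."""

    name: str
    n_terminus: float
    c_terminus: float
    side_chains: dict[str, float]  # residue -> pKa (D, E, C, Y, H, K, R)


class AminoAcidTable:
    """Per-residue reference data for the 20 standard amino acids."""

    def __init__(self, data: dict):
        self.version: str = data["version"]
        self.water_average_mass: float = data["water_average_mass"]
        self.water_monoisotopic_mass: float = data["water_monoisotopic_mass"]
        self.residues: dict[str, dict] = data["residues"]
        self.scales: dict[str, dict] = data["scales"]
        self.pka_sets: dict[str, PKaSet] = {
            name: PKaSet(name, d["n_terminus"], d["c_terminus"], dict(d["side_chains"]))
            for name, d in data["pka_sets"].items()
        }
        missing = STANDARD_RESIDUES - set(self.residues)
        if missing:
            raise PeptideError(f"amino-acid table missing residues: {sorted(missing)}")
        for code, rec in self.residues.items():
            if rec["average_mass"] <= 0 or rec["monoisotopic_mass"] <= 0:
                raise PeptideError(f"non-positive mass for residue {code}")

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "AminoAcidTable":
        return cls(_load_resource_json("amino_acids.json"))

    def residue_mass(self, code: str, mode: MassMode = "average") -> float:
        key = "average_mass" if mode == "average" else "monoisotopic_mass"
        return self.residues[code][key]

    def scale(self, name: str) -> dict[str, float]:
        if name not in self.scales:
            raise PeptideError(
                f"unknown scale {name!r}; available: {sorted(self.scales)}"
            )
        return self.scales[name]

    def pka_set(self, name: str) -> PKaSet:
        if name not in self.pka_sets:
            raise PeptideError(
                f"unknown pKa set {name!r}; available: {sorted(self.pka_sets)}"
            )
        return self.pka_sets[name]

    def charge_class(self, code: str) -> str:
        return self.residues[code]["charge_class"]


DEFAULT_PKA_SET = "sillero"
DEFAULT_HYDROPHOBICITY_SCALE = "eisenberg-consensus"
DEFAULT_HYDROPHILICITY_SCALE = "hopp-woods"


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence of standard one-letter residue codes."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("peptide sequence is empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in STANDARD_RESIDUES:
                raise PeptideError(
                    f"invalid residue {ch!r} at position {pos}: "
                    "only the 20 standard one-letter codes are accepted"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_bonds(self) -> int:
        """Number of peptide bonds, D = N - 1."""
        return len(self.sequence) - 1

    def count(self, residue: str) -> int:
        return self.sequence.count(residue)


def parse_peptide(raw_text: str) -> Peptide:
    """Parse free text into an uppercased, validated :class:`Peptide`."""
    text = "".join(raw_text.split()).upper()
    if not text:
        raise PeptideError("peptide sequence is empty")
    return Peptide(text)


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def molecular_weight(
    p: Peptide, mode: MassMode = "average", table: AminoAcidTable | None = None
) -> float:
    """Peptide mass in Da: sum of residue masses plus one water."""
    table = table or AminoAcidTable.default()
    water = (
        table.water_average_mass if mode == "average" else table.water_monoisotopic_mass
    )
    return sum(table.residue_mass(aa, mode) for aa in p) + water


def net_formal_charge(p: Peptide, table: AminoAcidTable | None = None) -> int:
    """Integer formal charge at neutral pH (free termini, His neutral)."""
    table = table or AminoAcidTable.default()
    basic = sum(1 for aa in p if table.charge_class(aa) == "basic")
    acidic = sum(1 for aa in p if table.charge_class(aa) == "acidic")
    return (basic + 1) - (acidic + 1)


# Side-chain charge signs for the Henderson-Hasselbalch model.
_BASIC_SIDE = frozenset("KRH")


def hh_net_charge(
    p: Peptide, ph: float, pka_set: PKaSet | str = DEFAULT_PKA_SET,
    table: AminoAcidTable | None = None,
) -> float:
    """Fractional Henderson-Hasselbalch net charge at a given pH."""
    table = table or AminoAcidTable.default()
    if isinstance(pka_set, str):
        pka_set = table.pka_set(pka_set)

    def positive(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def negative(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = positive(pka_set.n_terminus) + negative(pka_set.c_terminus)
    for aa in p:
        pka = pka_set.side_chains.get(aa)
        if pka is None:
            continue
        charge += positive(pka) if aa in _BASIC_SIDE else negative(pka)
    return charge


def isoelectric_point(
    p: Peptide, pka_set: PKaSet | str = DEFAULT_PKA_SET,
    table: AminoAcidTable | None = None, tol: float = 1e-4,
) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    always converges; ``tol`` is the bracketing width at termination.
    """
    table = table or AminoAcidTable.default()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if hh_net_charge(p, mid, pka_set, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_scale_value(
    p: Peptide, scale: str, table: AminoAcidTable | None = None
) -> float:
    """Arithmetic mean of per-residue scale values (full precision)."""
    table = table or AminoAcidTable.default()
    values = table.scale(scale)
    return sum(values[aa] for aa in p) / len(p)


@dataclass(frozen=True)
class PropertyProfile:
    """One row of the physicochemical summary for a peptide."""

    peptide: Peptide
    hydrophobicity: float
    hydrophilicity: float
    net_charge: int
    pi: float
    molecular_weight: float
    hydrophobicity_scale: str = DEFAULT_HYDROPHOBICITY_SCALE
    hydrophilicity_scale: str = DEFAULT_HYDROPHILICITY_SCALE
    pka_set: str = DEFAULT_PKA_SET
    extras: dict = field(default_factory=dict)
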