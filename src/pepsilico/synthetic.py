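"""Synthetic peptide-identification data with collagen-like composition.

The raw LC-MS/MS peptide lists behind hydrolysate studies are rarely
deposited, so this module generates stand-ins with the statistical
structure the pipeline assumes: short (7-15 residue), glycine/proline-rich
sequences as produced by collagenous tissue, each carrying a pseudo
bioactivity score in [0, 1].  The score is a logistic function of the
fraction of glycine, proline and hydrophobic residues -- a clearly labelled
surrogate whose only purpose is to exercise threshold screening on a
non-trivial distribution; it is NOT a re-implementation of any
bioactivity-ranking network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peptide import Peptide, parse_peptide
from .screening import RankedPeptide

#: Collagen-like residue frequencies modelled on hydrolysate peptide
#: composition: ~30% Gly, ~20% Pro, remainder over the residues observed.
DEFAULT_FREQUENCIES: dict[str, float] = {
    "G": 0.30, "P": 0.20, "A": 0.06, "M": 0.06, "S": 0.05, "F": 0.05,
    "R": 0.04, "L": 0.04, "D": 0.04, "Q": 0.03, "T": 0.03, "I": 0.03,
    "K": 0.03, "E": 0.02, "W": 0.02,
}

_HYDROPHOBIC = frozenset("AVLIMFW")
_SCORE_RESIDUES = frozenset("GP") | _HYDROPHOBIC


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic peptide-list generator."""

    n_peptides: int = 100
    length_range: tuple[int, int] = (7, 15)
    frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCIES)
    )
    score_steepness: float = 6.0
    score_midpoint: float = 0.55
    seed: int = 0
    sample_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_peptides < 0:
            raise ValueError("n_peptides must be non-negative")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("residue frequencies must be non-negative")


def pseudo_score(p: Peptide, steepness: float = 6.0, midpoint: float = 0.55) -> float:
    """Logistic surrogate score from the G/P/hydrophobic residue fraction."""
    x = sum(1 for aa in p if aa in _SCORE_RESIDUES) / len(p)
    return 1.0 / (1.0 + math.exp(-steepness * (x - midpoint)))


def generate_peptides(spec: GeneratorSpec) -> list[RankedPeptide]:
    """Reproducible list of scored collagen-like peptides."""
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.frequencies)
    probs = np.array([spec.frequencies[r] for r in residues])
    probs = probs / probs.sum()  # guard tiny float drift
    lo, hi = spec.length_range
    out: list[RankedPeptide] = []
    for _ in range(spec.n_peptides):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        peptide = parse_peptide(seq)
        out.append(
            RankedPeptide(
                peptide=peptide,
                score=pseudo_score(peptide, spec.score_steepness, spec.score_midpoint),
                sample_label=spec.sample_label,
            )
        )
    return out
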