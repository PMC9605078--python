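"""Physicochemical profiling and a pluggable toxicity-prediction interface.

The physicochemical profile aggregates the sequence-level computations
(molecular weight, formal charge, pI, hydropathy means) into one record per
peptide.  Toxicity prediction is an interface: predictors are registered by
id, and the bundled default is a deliberately simple composition heuristic
-- NOT a re-implementation of any trained classifier -- that flags peptides
as toxic-leaning when at least half of their residues are cysteine,
histidine or asparagine, the residues reported as enriched in toxic
peptides.  Every call carries its predictor id so surrogate status is
explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .peptide import (
    DEFAULT_HYDROPHILICITY_SCALE,
    DEFAULT_HYDROPHOBICITY_SCALE,
    DEFAULT_PKA_SET,
    AminoAcidTable,
    Peptide,
    PropertyProfile,
    isoelectric_point,
    mean_scale_value,
    molecular_weight,
    net_formal_charge,
    round_half_away,
)

NON_TOXIC = "non-toxic"
TOXIC = "toxic"


@dataclass(frozen=True)
class ToxicityCall:
    label: str
    predictor_id: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.label not in (NON_TOXIC, TOXIC):
            raise ValueError(f"unknown toxicity label {self.label!r}")
        if not self.predictor_id:
            raise ValueError("predictor_id must not be empty")


Predictor = Callable[[Peptide], ToxicityCall]
_REGISTRY: dict[str, Predictor] = {}


def register_predictor(predictor_id: str):
    def deco(fn: Predictor) -> Predictor:
        _REGISTRY[predictor_id] = fn
        return fn

    return deco


def available_predictors() -> list[str]:
    return sorted(_REGISTRY)


DEFAULT_PREDICTOR = "composition-heuristic-v1"
_TOXIC_ENRICHED = frozenset("CHN")


@register_predictor(DEFAULT_PREDICTOR)
def _composition_heuristic(p: Peptide) -> ToxicityCall:
    # Surrogate rule: toxic-leaning when >= 50% of residues are C, H or N.
    frac = sum(1 for aa in p if aa in _TOXIC_ENRICHED) / len(p)
    if frac >= 0.5:
        return ToxicityCall(
            TOXIC,
            DEFAULT_PREDICTOR,
            f"{frac:.0%} of residues are C/H/N (toxic-enriched); heuristic "
            "surrogate call, not a trained-model prediction",
        )
    return ToxicityCall(
        NON_TOXIC,
        DEFAULT_PREDICTOR,
        f"only {frac:.0%} of residues are C/H/N; heuristic surrogate call",
    )


def predict_toxicity(p: Peptide, predictor: str = DEFAULT_PREDICTOR) -> ToxicityCall:
    """Deterministic toxicity label from a registered predictor."""
    if predictor not in _REGISTRY:
        raise ValueError(
            f"unknown predictor {predictor!r}; registered: {available_predictors()}"
        )
    return _REGISTRY[predictor](p)


def property_profile(
    p: Peptide,
    pka_set: str = DEFAULT_PKA_SET,
    hydrophobicity_scale: str = DEFAULT_HYDROPHOBICITY_SCALE,
    hydrophilicity_scale: str = DEFAULT_HYDROPHILICITY_SCALE,
    table: AminoAcidTable | None = None,
) -> PropertyProfile:
    """Aggregate MW, charge, pI and hydropathy means for one peptide."""
    table = table or AminoAcidTable.default()
    return PropertyProfile(
        peptide=p,
        hydrophobicity=mean_scale_value(p, hydrophobicity_scale, table),
        hydrophilicity=mean_scale_value(p, hydrophilicity_scale, table),
        net_charge=net_formal_charge(p, table),
        pi=isoelectric_point(p, pka_set, table),
        molecular_weight=molecular_weight(p, "average", table),
        hydrophobicity_scale=hydrophobicity_scale,
        hydrophilicity_scale=hydrophilicity_scale,
        pka_set=pka_set,
    )


def physchem_report(
    peptides: list[Peptide],
    predictor: str = DEFAULT_PREDICTOR,
    **profile_kwargs,
) -> pd.DataFrame:
    """Table of physicochemical properties and toxicity calls."""
    rows = []
    for p in peptides:
        prof = property_profile(p, **profile_kwargs)
        call = predict_toxicity(p, predictor)
        rows.append(
            {
                "peptide": str(p),
                "prediction": call.label,
                "predictor_id": call.predictor_id,
                "hydrophobicity": round_half_away(prof.hydrophobicity),
                "hydrophilicity": round_half_away(prof.hydrophilicity),
                "charge": prof.net_charge,
                "pi": round_half_away(prof.pi),
                "molecular_weight": round_half_away(prof.molecular_weight),
            }
        )
    return pd.DataFrame(rows)
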