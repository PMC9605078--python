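"""Quantitative proteolysis descriptors.

For a peptide of N residues (D = N - 1 bonds) digested in silico:

* ``DHt`` -- theoretical degree of hydrolysis, the percentage of peptide
  bonds cleaved: ``d / D * 100``.
* ``A_E`` -- frequency of release of fragments with a given activity:
  (number of liberated fragments that are themselves database motifs) / N.
  Released fragments are counted per instance.
* ``W`` -- relative frequency of release, ``A_E / A``, where ``A = a / N``
  is the motif occurrence frequency of the undigested parent.  Since both
  numerator and denominator share N, W equals released count over
  occurrence count.  When A = 0, W is reported as 0 with a flag.

Values are held at full precision; presentation rounds half away from zero
to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .digestion import DigestResult, released_active_fragments
from .motifs import ActivityProfile, MotifDB
from .peptide import round_half_away


@dataclass(frozen=True)
class DescriptorSet:
    """DHt / A_E / W for one peptide and one activity, with traceback."""

    peptide: str
    activity: str
    dht: float  # percent of bonds cleaved, [0, 100]
    ae: float
    w: float
    a_occurrences: int
    released_count: int
    w_undefined: bool = False  # True when the parent has no occurrences

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_away(self.dht, ndigits),
            round_half_away(self.ae, ndigits),
            round_half_away(self.w, ndigits),
        )


def theoretical_degree_of_hydrolysis(result: DigestResult) -> float:
    """DHt = cleaved bonds / total bonds * 100."""
    n_bonds = result.query.n_bonds
    if n_bonds == 0:
        raise ValueError("single-residue peptide has no peptide bonds")
    return result.d_bonds / n_bonds * 100.0


def release_frequency(result: DigestResult, db: MotifDB, activity: str) -> float:
    """A_E = released active-fragment instances / residue count."""
    released = released_active_fragments(result, db, activity)
    return len(released) / len(result.query)


def relative_release_frequency(
    result: DigestResult, profile: ActivityProfile, db: MotifDB
) -> float:
    """W = A_E / A; 0 when the parent contains no motif occurrences."""
    if str(result.query) != str(profile.query):
        raise ValueError(
            f"digest result ({result.query}) and activity profile "
            f"({profile.query}) refer to different peptides"
        )
    if profile.a == 0:
        return 0.0
    released = released_active_fragments(result, db, profile.activity)
    return (len(released) / len(result.query)) / profile.frequency


def describe(
    result: DigestResult, profile: ActivityProfile, db: MotifDB
) -> DescriptorSet:
    """Assemble the full descriptor set for one peptide and activity."""
    released = released_active_fragments(result, db, profile.activity)
    ae = len(released) / len(result.query)
    undefined = profile.a == 0
    w = 0.0 if undefined else ae / profile.frequency
    return DescriptorSet(
        peptide=str(result.query),
        activity=profile.activity,
        dht=theoretical_degree_of_hydrolysis(result),
        ae=ae,
        w=w,
        a_occurrences=profile.a,
        released_count=len(released),
        w_undefined=undefined,
    )


def descriptor_report(sets: list[DescriptorSet]) -> pd.DataFrame:
    """Full-precision descriptor table with printed-rounded companions."""
    rows = []
    for ds in sets:
        dht, ae, w = ds.rounded()
        rows.append(
            {
                "peptide": ds.peptide,
                "activity": ds.activity,
                "dht_percent": ds.dht,
                "ae": ds.ae,
                "w": ds.w,
                "dht_percent_2dp": dht,
                "ae_2dp": ae,
                "w_2dp": w,
                "occurrences": ds.a_occurrences,
                "released": ds.released_count,
                "w_undefined": ds.w_undefined,
            }
        )
    return pd.DataFrame(rows)
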