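"""Drug-likeness (ADME) panel computed on molecular graphs.

The panel mirrors the descriptors a web-based oral-drug-likeness evaluator
reports for small molecules: topological polar surface area by fragment
contributions, hydrogen-bond donor/acceptor counts, rotatable bonds,
fraction of sp3 carbons, an atom-contribution log P estimate, ESOL water
solubility, the rule-of-five filter, a rule-based oral bioavailability
score, a gastrointestinal-absorption class from the white region of the
lipophilicity/polarity egg plot, and the six-axis bioavailability radar.

Descriptor conventions calibrated for this chemical space (small linear
peptides with free termini, plus captopril):

* TPSA sums published fragment contributions over every N, O and S
  environment (sulfur treated as polar).
* HBD counts N/O heavy atoms bearing at least one hydrogen (a thiol is not
  a donor here).
* HBA counts N and O atoms, excluding nitrogens single-bonded to a carbon
  that carries a double bond to O or N (amide, amidine and guanidine N-H
  nitrogens) and aromatic N-H; the guanidine =NH imine nitrogen counts.
* ROTB counts acyclic single bonds between heavy atoms of heavy-degree
  >= 2, including backbone amide C-N bonds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as _ilres

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

from .chem import AROMATIC_BOND, MolecularGraph
from .peptide import round_half_away

POLAR_ELEMENTS = ("N", "O", "S")


class AtomEnvironmentError(ValueError):
    """Raised when a polar atom has no fragment-contribution entry."""


@lru_cache(maxsize=1)
def _tpsa_table() -> dict[str, float]:
    data = json.loads(
        _ilres.files("pepsilico.resources").joinpath("tpsa_fragments.json").read_text()
    )
    return data["contributions"]


def _environment_signature(g: MolecularGraph, idx: int) -> str:
    atom = g.atoms[idx]
    bonds = [bond for _, bond in g.neighbors(idx)]
    if atom.aromatic:
        n_arom = sum(1 for b in bonds if b.order == AROMATIC_BOND)
        n_single = len(bonds) - n_arom
        shape = f"a{n_arom}" + (f"s{n_single}" if n_single else "")
    else:
        n_single = sum(1 for b in bonds if b.order == 1.0)
        n_double = sum(1 for b in bonds if b.order == 2.0)
        n_triple = sum(1 for b in bonds if b.order == 3.0)
        shape = f"s{n_single}d{n_double}t{n_triple}"
    flavor = "ar" if atom.aromatic else "al"
    return f"{atom.element}|{flavor}|H{atom.n_hydrogens}|{shape}|c{atom.formal_charge}"


def tpsa(g: MolecularGraph) -> float:
    """Topological polar surface area (A^2) by fragment-contribution sums."""
    table = _tpsa_table()
    total = 0.0
    for atom in g.atoms:
        if atom.element not in POLAR_ELEMENTS:
            continue
        sig = _environment_signature(g, atom.index)
        if sig not in table:
            raise AtomEnvironmentError(
                f"no TPSA contribution for atom environment {sig!r} "
                f"(atom {atom.index} of {g.provenance})"
            )
        total += table[sig]
    return total


def _is_excluded_acceptor_n(g: MolecularGraph, idx: int) -> bool:
    atom = g.atoms[idx]
    if atom.aromatic:
        return atom.n_hydrogens > 0  # pyrrole-like N-H
    for neighbor, bond in g.neighbors(idx):
        if bond.order != 1.0 or neighbor.element != "C":
            continue
        for nn, nb in g.neighbors(neighbor.index):
            if nb.order == 2.0 and nn.element in ("O", "N"):
                return True  # amide / amidine / guanidine N
    return False


def hbond_counts(g: MolecularGraph) -> tuple[int, int]:
    """(acceptor count, donor count) under the calibrated conventions."""
    hba = 0
    hbd = 0
    for atom in g.atoms:
        if atom.element in ("N", "O") and atom.n_hydrogens > 0:
            hbd += 1
        if atom.element == "O":
            hba += 1
        elif atom.element == "N" and not _is_excluded_acceptor_n(g, atom.index):
            hba += 1
    return hba, hbd


def rotatable_bonds(g: MolecularGraph) -> int:
    """Acyclic single bonds between heavy atoms each of heavy-degree >= 2.

    Backbone amide C-N bonds count; bonds to terminal heavy atoms (OH, SH,
    NH2, methyl) do not.
    """
    count = 0
    for bond in g.bonds:
        if bond.order != 1.0 or bond.in_ring:
            continue
        if g.heavy_degree(bond.i) >= 2 and g.heavy_degree(bond.j) >= 2:
            count += 1
    return count


def fraction_csp3(g: MolecularGraph) -> float:
    """sp3 carbon count over total carbon count."""
    carbons = [a for a in g.atoms if a.element == "C"]
    if not carbons:
        raise ValueError(f"{g.provenance}: no carbon atoms")
    return sum(1 for a in carbons if a.hybridization == "sp3") / len(carbons)


def aromatic_proportion(g: MolecularGraph) -> float:
    return sum(1 for a in g.atoms if a.aromatic) / len(g.atoms)


def logp_estimate(g: MolecularGraph) -> float:
    """Wildman-Crippen atom-contribution log P (octanol/water).

    A deterministic substitute for the proprietary estimators of upstream
    web tools; suitable for ordering and banding, not for exact match.
    """
    mol = Chem.MolFromSmiles(g.smiles)
    if mol is None:  # graphs are always built from valid SMILES
        raise ValueError(f"cannot re-derive molecule for {g.provenance}")
    return Crippen.MolLogP(mol)


# ESOL: Delaney-style linear solubility model.
def esol_logs(
    mw: float, logp: float, rotb: int, aromatic_prop: float
) -> tuple[float, str]:
    """Estimated log of molar water solubility and its qualitative class."""
    logs = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * aromatic_prop
    return logs, solubility_class(logs)


def solubility_class(logs: float) -> str:
    if logs >= 0:
        return "Highly soluble"
    if logs >= -2:
        return "Very soluble"
    if logs >= -4:
        return "Soluble"
    if logs >= -6:
        return "Moderately soluble"
    if logs >= -10:
        return "Poorly soluble"
    return "Insoluble"


_SOLUBLE_OR_BETTER = ("Highly soluble", "Very soluble", "Soluble")


def lipinski_filter(
    hbd: int, hba: int, mw: float, logp: float
) -> tuple[bool, list[str]]:
    """Rule-of-five violations; pass means at most one violation."""
    violations = []
    if hbd > 5:
        violations.append(f"HBD {hbd} > 5")
    if hba > 10:
        violations.append(f"HBA {hba} > 10")
    if mw >= 500:
        violations.append(f"MW {mw:.1f} >= 500")
    if logp > 5:
        violations.append(f"logP {logp:.2f} > 5")
    return len(violations) <= 1, violations


def charge_class(g: MolecularGraph) -> str:
    """"anion" / "cation" / "neutral" from acidic vs basic site counts.

    Acidic sites are carboxyl groups; basic sites are free (sp3, non-amide)
    amines plus guanidine/amidine carbons counted once per group.
    """
    acids = 0
    basics = 0
    for atom in g.atoms:
        if atom.element == "C" and not atom.aromatic:
            has_carbonyl_o = any(
                n.element == "O" and b.order == 2.0 for n, b in g.neighbors(atom.index)
            )
            has_hydroxyl = any(
                n.element == "O" and b.order == 1.0 and n.n_hydrogens == 1
                for n, b in g.neighbors(atom.index)
            )
            if has_carbonyl_o and has_hydroxyl:
                acids += 1
            if any(
                n.element == "N" and b.order == 2.0 for n, b in g.neighbors(atom.index)
            ):
                basics += 1  # guanidine / amidine group
        elif (
            atom.element == "N"
            and not atom.aromatic
            and atom.hybridization == "sp3"
            and not _is_excluded_acceptor_n(g, atom.index)
        ):
            basics += 1  # free amine
    if acids > basics:
        return "anion"
    if basics > acids:
        return "cation"
    return "neutral"


def bioavailability_score(
    charge: str, tpsa_value: float, lipinski_pass: bool
) -> float:
    """Rule-based probability class of >= 10% oral bioavailability."""
    if charge == "anion":
        if tpsa_value <= 75:
            return 0.85
        if tpsa_value <= 150:
            return 0.56
        return 0.11
    return 0.55 if lipinski_pass else 0.17


@dataclass(frozen=True)
class GIAEllipse:
    """White-region ellipse of the TPSA/logP absorption plot (config data)."""

    center_tpsa: float = 71.051
    center_logp: float = 2.292
    width: float = 142.081
    height: float = 8.740
    angle_deg: float = -1.031


DEFAULT_GIA_ELLIPSE = GIAEllipse()


def gi_absorption(
    tpsa_value: float, logp: float, ellipse: GIAEllipse = DEFAULT_GIA_ELLIPSE
) -> str:
    """"High" when (TPSA, logP) falls inside the absorption ellipse."""
    theta = math.radians(ellipse.angle_deg)
    dx = tpsa_value - ellipse.center_tpsa
    dy = logp - ellipse.center_logp
    x = dx * math.cos(theta) + dy * math.sin(theta)
    y = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (x / (ellipse.width / 2)) ** 2 + (y / (ellipse.height / 2)) ** 2 <= 1
    return "High" if inside else "Low"


@dataclass(frozen=True)
class RadarAxis:
    axis: str
    value: float
    in_range: bool
    note: str = ""


@dataclass(frozen=True)
class AdmeProfile:
    compound: str
    mw: float
    rotb: int
    hba: int
    hbd: int
    tpsa: float
    logp: float
    esol_logs: float
    esol_class: str
    fsp3: float
    bioavailability_score: float
    lipinski_pass: bool
    lipinski_violations: tuple[str, ...]
    gia_class: str
    charge_class: str
    radar: tuple[RadarAxis, ...] = field(default=())

    @property
    def soluble_or_better(self) -> bool:
        return self.esol_class in _SOLUBLE_OR_BETTER


def radar_assessment(profile: AdmeProfile) -> tuple[RadarAxis, ...]:
    """Six-axis oral-bioavailability window.

    Published axis windows: lipophilicity -0.7 < logP < 5.0; size
    150 < MW < 500; polarity 20 < TPSA < 130; insolubility |log S| < 6
    (the magnitude form -- ESOL log S of soluble compounds is negative);
    saturation 0.25 < Fsp3 <= 1; flexibility 0 <= ROTB <= 9 (count axes
    closed at their attainable endpoints).
    """
    return (
        RadarAxis("LIPO", profile.logp, -0.7 < profile.logp < 5.0),
        RadarAxis("SIZE", profile.mw, 150 < profile.mw < 500),
        RadarAxis("POLAR", profile.tpsa, 20 < profile.tpsa < 130),
        RadarAxis(
            "INSOLU",
            profile.esol_logs,
            abs(profile.esol_logs) < 6,
            note="window applied to |log S|; the nominal 0 < log S < 6 form "
            "would reject every soluble compound",
        ),
        RadarAxis("INSATU", profile.fsp3, 0.25 < profile.fsp3 <= 1),
        RadarAxis("FLEX", profile.rotb, 0 <= profile.rotb <= 9),
    )


def adme_profile(
    g: MolecularGraph,
    compound: str | None = None,
    ellipse: GIAEllipse = DEFAULT_GIA_ELLIPSE,
) -> AdmeProfile:
    """Assemble the full drug-likeness panel for one molecular graph."""
    mw = g.average_mass()
    hba, hbd = hbond_counts(g)
    rotb = rotatable_bonds(g)
    tpsa_value = tpsa(g)
    logp = logp_estimate(g)
    logs, sol_class = esol_logs(mw, logp, rotb, aromatic_proportion(g))
    passed, violations = lipinski_filter(hbd, hba, mw, logp)
    charge = charge_class(g)
    profile = AdmeProfile(
        compound=compound or g.provenance,
        mw=mw,
        rotb=rotb,
        hba=hba,
        hbd=hbd,
        tpsa=tpsa_value,
        logp=logp,
        esol_logs=logs,
        esol_class=sol_class,
        fsp3=fraction_csp3(g),
        bioavailability_score=bioavailability_score(charge, tpsa_value, passed),
        lipinski_pass=passed,
        lipinski_violations=tuple(violations),
        gia_class=gi_absorption(tpsa_value, logp, ellipse),
        charge_class=charge,
    )
    return AdmeProfile(**{**profile.__dict__, "radar": radar_assessment(profile)})


def adme_report(profiles: list[AdmeProfile]) -> pd.DataFrame:
    """Table mirroring the published drug-likeness layout."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "compound": p.compound,
                "rotb": p.rotb,
                "hba": p.hba,
                "hbd": p.hbd,
                "esol_logs": round_half_away(p.esol_logs),
                "esol_class": p.esol_class,
                "tpsa": round_half_away(p.tpsa),
                "logp": round_half_away(p.logp),
                "fsp3": round_half_away(p.fsp3),
                "bioavailability_score": p.bioavailability_score,
                "lipinski": f"{'Yes' if p.lipinski_pass else 'No'} "
                f"({len(p.lipinski_violations)})",
                "gia": p.gia_class,
                "radar_flags": ";".join(
                    ax.axis for ax in p.radar if not ax.in_range
                ),
            }
        )
    return pd.DataFrame(rows)
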