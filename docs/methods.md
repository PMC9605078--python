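# Methods

This note documents the models, conventions and design choices behind
`pepsilico`, in the order the pipeline runs them.

## Sequence-level physicochemistry

**Masses.** Molecular weight is the sum of residue masses plus one water.
The default mode uses average residue masses stored at two-decimal
precision (G 57.05, P 97.12, …, water 18.02 Da), the precision at which
peptide property calculators conventionally print and round; monoisotopic
masses are provided for mass-spectrometric use. Mass additivity holds
exactly: MW(ab) = MW(a) + MW(b) − 18.02.

**Charge.** The reported charge is an integer formal count at neutral pH:
(+1 per Lys/Arg, +1 for the free α-amine) − (−1 per Asp/Glu, −1 for the free
carboxyl), with histidine neutral (imidazole pKa ≈ 6.4 is below neutral pH).
This integer convention is deliberately a different layer from the
fractional Henderson–Hasselbalch charge used for pI, and from the neutral
structural drawing used for molecular graphs (below).

**Isoelectric point.** pI solves Σ charges(pH) = 0 for the
Henderson–Hasselbalch charge over both termini and the ionisable side
chains (D, E, C, Y, H, K, R). The charge is strictly decreasing in pH, so
bisection on [0, 14] to a 1e-4 bracket always converges; for peptides
without ionisable side chains the root is analytically the midpoint of the
two terminal pKa values. Two named pKa sets ship with the package: the
default `sillero` set (N-term 8.2, C-term 3.2, R 12.0, …) and an
`emboss`-style set. The default was chosen as the candidate set with the
smallest absolute error against the three reference pI values the package
reproduces (5.88, 3.88, 10.11 — max error 0.20 pH); pI values are treated
as pKa-set dependent with a ±0.35 pH band.

**Hydropathy scales.** Hydrophilicity is the Hopp–Woods mean, which
reproduces the reference values exactly. The upstream tool behind the
reference hydrophobicity column does not name its scale; the package ships
the Eisenberg normalized-consensus scale as default (residual ≤ 0.02
against the five reference dipeptides, documented as best-effort ±0.15) and
Kyte–Doolittle as an alternative. Scale means are arithmetic means per
residue; all descriptors are held at full precision and rounded
half-away-from-zero to two decimals only at presentation time.

## Screening

Scores are consumed as data (CSV column `score`); no ranking model is
implemented. The comparison is inclusive (≥ threshold) because peptides
scored exactly at the 0.9 cut-off belong to the retained set in the
reference data. Screening is stable (descending score, input order on
ties), monotone in the threshold, and idempotent.

## Motif database and scanner

The bundled database is a snapshot of 43 (fragment, activity) records —
3 antioxidative, 40 ACE-inhibitory di-/tripeptides — each with its source
description and provenance string; it is data, not a live-database client.
Records equal in sequence but different in source are stored once per
(fragment, activity). The scanner reports **every placement** of every
fragment of the requested activity, overlapping and repeated placements
included; the occurrence frequency A = a/N counts placements. Placement
counting (rather than distinct-sequence counting) is forced by the release
arithmetic: W = 0.14 for GPGMMGP requires a = 7, i.e. GP counted at both of
its sites. Coordinates are 1-based inclusive.

Several printed location cells in the source tables are internally
inconsistent with the sequences they annotate (a systematic +1 shift on
three peptides, one truncated span, and one omitted row recoverable from
the release arithmetic). The scanner always reports true coordinates; the
fixture module stores the printed cells verbatim alongside corrected
companions and an erratum note, so regressions target the corrected values
explicitly and nothing is silently rewritten.

## Simulated digestion

Cleavage rules are declarative data: a set of P1 residues whose C-terminal
bond is cut, and an optional set of P1′ residues that block the cut. The
bundled `gi-default` panel is pepsin {F, L}, trypsin {K, R}, chymotrypsin
{F, W, Y, M, L}, all with **empty** P1′ exclusions — the minimal specificity
model consistent with every reference fragmentation (cuts after Trp and Phe
occur even before proline, so "not before P" exclusions must not be
applied; Tyr is included by convention and never occurs in the bundled
data). Enzymes act concurrently in one pass; because each rule inspects
only the two residues flanking a bond, sequential per-enzyme re-digestion
provably yields the same site union and is provided only as an option.
Cleavage is all-or-none with no kinetics or pH model. Single-residue
fragments are legal but can never be active (motifs have length ≥ 2); a
peptide with zero susceptible bonds is reported resistant, as itself.

## Release descriptors

DHt = d/D × 100 with d the cleaved-bond count and D = N − 1. A_E counts
released fragments whose entire sequence matches a database motif of the
requested activity, divided by N; released instances are counted per
occurrence (two identical released fragments count twice — a convention, as
no bundled datum distinguishes it). W = A_E/A, algebraically equal to
released count over occurrence count; when A = 0 the quotient is undefined
and W is reported as 0 with an explicit flag.

## Toxicity interface

Toxicity is a pluggable predictor registry. The bundled default
(`composition-heuristic-v1`) labels a peptide toxic-leaning when ≥ 50% of
its residues are Cys, His or Asn — the residues reported as enriched in
toxic peptides — and non-toxic otherwise. It is a deterministic,
clearly-labelled surrogate: every call carries its predictor id, and no
equivalence with any trained SVM is claimed. Its positive class is
exercised only by constructed sequences, since the reference data contain
no toxic example.

## Molecular graphs and the ADME panel

Peptide structures are assembled from bundled side-chain SMILES templates
on a standard backbone (free amine N-terminus, free acid C-terminus,
proline ring closed through the backbone nitrogen) and parsed with RDKit
into the package's own graph type. The arginine guanidine is drawn
**neutral** (one =NH, one NH, one NH₂): the TPSA decomposition of
prolyl-arginine (140.33 Å² = 78.43 + 12.03 + 23.85 + 26.02) requires the
neutral tautomer, while the +1 of the sequence-level charge column lives in
the formal-count model — two intentionally different layers.

Descriptor conventions, calibrated on the six reference compounds (five
dipeptides + captopril) and valid for this chemical space:

* **TPSA** — sum of published fragment contributions over every N, O and S
  environment (S polar; thiol 38.80 Å², tertiary amide N 3.24 Å², …). An
  atom environment without a table entry raises an error naming it.
* **HBD** — count of N/O heavy atoms bearing ≥ 1 H (group counting; a thiol
  is not a donor: captopril has HBD 1).
* **HBA** — N + O atoms, excluding nitrogens single-bonded to a carbon that
  carries a double bond to O or N (amide, amidine and guanidine N–H) and
  aromatic N–H; the guanidine imine =NH counts. Whether the upstream
  definition uses this or a richer typing is indistinguishable on these six
  molecules.
* **ROTB** — acyclic single bonds whose endpoints each have heavy-atom
  degree ≥ 2, **including** backbone amide C–N bonds (the unique simple
  convention reproducing all six reference counts).
* **log P** — Wildman–Crippen atom contributions (RDKit). The upstream
  estimators are proprietary-weighted, so log P is matched only in ordering
  and band (captopril within ±1.5 of 0.62 is verified); printed log P values
  are not regression targets.
* **ESOL** — log S = 0.16 − 0.63·logP − 0.0062·MW + 0.066·ROTB − 0.74·AP
  (AP = aromatic-atom proportion), with the usual class ladder (≥ 0 highly
  soluble, ≥ −2 very soluble, ≥ −4 soluble, …). Because the log P substitute
  differs from the upstream one, solubility is asserted only at class level
  (soluble-or-better).
* **Rule of five** — violations for HBD > 5, HBA > 10, MW ≥ 500,
  log P > 5; pass means ≤ 1 violation.
* **Bioavailability score** — anions by TPSA band (≤ 75 → 0.85,
  75–150 → 0.56, > 150 → 0.11); non-anions 0.55 if rule-of-five passing,
  else 0.17. The anion/cation/neutral class is derived from the graph
  (carboxyl groups vs free amines + guanidine/amidine groups).
* **GI absorption** — membership of (TPSA, log P) in the white-region
  ellipse (centre (71.051, 2.292), full axes 142.081 × 8.740, tilt −1.031°),
  stored as configuration. Note the ellipse is thin in log P: points with
  TPSA near 0 but log P far from ~2 fall outside, so "low TPSA" alone does
  not guarantee the High class.
* **Radar** — six open windows: lipophilicity (−0.7, 5), size (150, 500) Da,
  polarity (20, 130) Å², insolubility |log S| < 6, saturation Fsp³ in
  (0.25, 1], flexibility ROTB in [0, 9]. The insolubility window is applied
  to |log S| (the nominal "0 < log S < 6" form would reject every soluble
  compound, whose ESOL log S is ≤ 0); the count axes are closed at their
  attainable endpoints. With the Crippen substitute, strongly polar
  dipeptides (log P < −0.7) are flagged on the lipophilicity axis as well as
  polarity; the panel reports all flags rather than forcing a single-axis
  verdict.

## Synthetic data

The generator emulates the statistical shape of a collagen-hydrolysate
identification list: i.i.d. per-position residues from a collagen-like
frequency profile (G 0.30, P 0.20, the remainder over the residues observed
in such data, chosen once as defaults), lengths uniform on 7–15, and a
pseudo-score that is a logistic function (steepness 6, midpoint 0.55) of
the G/P/hydrophobic residue fraction. It reproduces composition and score
distribution, not mass spectra, retention times, identification FDR, or any
real ranking model — so passing tests on synthetic data demonstrate
pipeline mechanics and invariants, not biological validity of scores.
Generation is fully seeded and reproducible.

## Numerical choices and degenerate inputs

Bisection tolerance 1e-4 pH; descriptor rounding half-away-from-zero at
2 dp, presentation-only; empty inputs yield empty (zero-count) reports;
single-residue peptides digest to themselves but reject DHt (no bonds);
scanning with an empty database yields an empty profile; W is flagged, not
NaN, when A = 0. Report determinism for a fixed config is tested
end-to-end.

## Problem sizes

Everything runs at desk scale: 14 screened peptides (11 distinct), a
43-record motif database, six reference molecules, and property sweeps of
1000 random peptides against a brute-force scanning oracle. The full test
suite completes in a few seconds on one CPU.

## Known limitations

* Cleavage specificity is context-free (P1/P1′ only), all-or-none, and
  kinetics-free; real gastric digestion is none of these.
* The toxicity heuristic and the Crippen log P are labelled substitutes for
  trained upstream models; their exact values should not be quoted as
  predictions of those tools.
* The motif database is a static snapshot; absence of a motif means absence
  of evidence in the snapshot, not inactivity.
* Hydroxyproline and other modified residues are out of scope; sequences
  are restricted to the 20 standard codes.
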