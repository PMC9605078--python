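"""Threshold screening of a scored peptide list.

Loads the bundled hydrolysate peptide lists (two by-product samples, each
peptide carrying a bioactivity-probability score in [0, 1]) and keeps the
peptides at or above the 0.9 cut-off.  The retained counts per sample are
the starting point of every downstream stage.
"""

from pepsilico import RankedPeptide, load_fixture, parse_peptide, screen_by_score

items = [
    RankedPeptide(
        peptide=parse_peptide(row["sequence"]),
        score=float(row["score"]),
        sample_label=row["sample"],
    )
    for row in load_fixture("table1").rows
]

for sample in ["flower", "internal organs"]:
    kept = screen_by_score([i for i in items if i.sample_label == sample], 0.9)
    print(f"{sample}: {len(kept)} peptides at score >= 0.9")
    for item in kept:
        print(f"  {item.score:.2f}  {item.peptide}")

print(
    "\nEach retained peptide is a candidate precursor of bioactive fragments;"
    "\nthe score is the probability the ranking model assigns to bioactivity."
)
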