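"""Bioactive-motif profiling of peptide sequences.

Scans query peptides against the bundled database of short (2-3 residue)
antioxidative and ACE-inhibitory fragments and reports every placement,
the occurrence count a, and the occurrence frequency A = a / N.
"""

from pepsilico import (
    ACE_INHIBITOR,
    ANTIOXIDATIVE,
    distinct_motif_count,
    load_motif_db,
    parse_peptide,
    scan_motifs,
)

db = load_motif_db()

for seq, activity in [
    ("GPPGPQWPLDF", ANTIOXIDATIVE),
    ("APDMAFPR", ACE_INHIBITOR),
    ("GPPGASGPLGIAGSM", ACE_INHIBITOR),
]:
    profile = scan_motifs(parse_peptide(seq), db, activity)
    hits = ", ".join(
        f"{occ.motif.fragment}({occ.start}-{occ.end})" for occ in profile.occurrences
    )
    print(f"{seq} [{activity}]")
    print(f"  {hits or '(none)'}")
    print(
        f"  a = {profile.a} placements, {distinct_motif_count(profile)} distinct,"
        f" A = a/N = {profile.frequency:.2f}"
    )

print(
    "\nA is the motif occurrence frequency per residue of the parent peptide;"
    "\noverlapping and repeated placements all count."
)
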