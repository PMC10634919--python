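"""Sequence analysis of the EWS low-complexity domain.

Loads the bundled 264-residue LCD sequence, prints its amino-acid
composition, scans tyrosine spacing motifs (YxY / YxxY pairs drive
aromatic stickiness), and constructs the YxY-targeting double mutant.
"""

from pathlib import Path

from lcdphase.sequence import (
    MutationSet,
    apply_mutations,
    composition_profile,
    find_tyrosine_motifs,
    motif_counts,
    read_fasta,
    residue_positions,
)

DATA = Path(__file__).resolve().parent / "data"

seq = read_fasta(DATA / "ews_lcd.fasta")[0]
print(f"{seq.name}: {len(seq)} residues")

comp = composition_profile(seq).sort_values(ascending=False)
print("\nTop residue types (percent abundance):")
print(comp.head(6).round(1).to_string())

counts = motif_counts(seq)
print(f"\nTyrosines: {counts['total_tyrosines']}  "
      f"YxY pairs: {counts['YxY']}  YxxY pairs: {counts['YxxY']}  "
      f"isolated: {counts['isolated']}")
for hit in find_tyrosine_motifs(seq):
    if hit.kind != "isolated":
        print(f"  {hit.kind} at ({hit.first_position}, {hit.second_position})")

# the lone YxY pair sits at Y170/Y172; mutating it weakens self-association
double = MutationSet.from_strings(["Y170S", "Y172S"], label="Y170S_Y172S")
mutant = apply_mutations(seq, double)
print(f"\nAfter {double.label}: "
      f"{motif_counts(mutant)['total_tyrosines']} tyrosines, "
      f"{motif_counts(mutant)['YxY']} YxY pairs remain")
print("tyrosine-free stretch:",
      max(zip(
          (b - a for a, b in zip([0] + residue_positions(mutant, 'Y')['Y'],
                                 residue_positions(mutant, 'Y')['Y'])),
          residue_positions(mutant, 'Y')['Y'])),
      "(gap length, position of next tyrosine)")
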