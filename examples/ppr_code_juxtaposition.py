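"""Juxtapose a PLS-type PPR array with a target window.

Builds the PPR56-like factor preset, constructs a target whose upstream
sequence carries the code-predicted nucleotide at every canonical repeat,
and prints the alignment table.  Then it mutates repeat S-7 (T,D -> T,N)
and shows how the prediction at target position -10 flips from G to A.
"""

from ppredit import TargetWindow, juxtapose, make_factor, motif_position, mutate_motif

factor = make_factor("PPR56-like")

bases = {o: "A" for o in range(-30, 6)}
bases[0] = "C"
for m in factor.motifs:
    if m.prediction():
        bases[motif_position(m)] = sorted(m.prediction())[0]
window = TargetWindow("nad4-like", "construct", 40,
                      "".join(bases[o] for o in range(-30, 6)), lo=-30)

print("Native array vs a fully code-matching target:")
print(juxtapose(factor, window).to_string(index=False))

mut = mutate_motif(factor, "S-7", "T", "N")
row = juxtapose(mut, window)
row = row[row["motif"] == "S-7"].iloc[0]
print(f"\nAfter S-7 TD>TN the repeat at position {row['position']} predicts "
      f"{row['predicted']} and the old G target is now a '{row['class']}'.")
print("Each row pairs one repeat with one nucleotide; 'match' means the "
      "observed base is the one the 5/L code predicts.")
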