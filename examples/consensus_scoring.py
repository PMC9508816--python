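"""Build a consensus profile from editing-site windows and score candidates.

Constructs 100 windows with a 43% A at offset -14 and a 74% G at -13
(balanced elsewhere), builds the decile consensus and scores two candidate
windows against it.  The printed scores are decile sums: an offset
contributes its 10%-floored dominant frequency (40..90) when the candidate
carries the consensus nucleotide there.
"""

from ppredit import build_profile, consensus_string, matching_score, max_score
from ppredit.profile import TargetWindow


def window(bases: dict[int, str]) -> TargetWindow:
    chars = {o: "ACGT"[o % 4] for o in range(-30, 6)}
    chars[0] = "C"
    chars.update(bases)
    return TargetWindow("g", "t", 100,
                        "".join(chars[o] for o in range(-30, 6)), lo=-30)


windows = []
for i in range(100):
    bases = {o: "ACGT"[(i + o) % 4] for o in range(-30, 6) if o != 0}
    bases[-14] = "A" if i < 43 else "CGT"[i % 3]
    bases[-13] = "G" if i < 74 else "ACT"[i % 3]
    windows.append(window(bases))

profile = build_profile(windows, bounds=(-17, -1))
print("consensus (-17..-1):", consensus_string(profile))
print("thresholded offsets:", profile.decile_map)
print("maximum score:      ", max_score(profile))

good = window({-14: "A", -13: "G"})
partial = window({-14: "A", -13: "T"})
print("A@-14 and G@-13 ->", matching_score(good, profile), "points")
print("A@-14 only      ->", matching_score(partial, profile), "points")
print("A score of 110/110 means the candidate matches every consensus "
      "position at its decile weight (40 + 70).")
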