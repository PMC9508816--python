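"""Scan a transcriptome for candidate editing sites and compare to calls.

Plants three consensus-matching sites in a random transcriptome, scans every
cytidine with the decile matching score, and joins the top candidates with
the sites an end-to-end calling run actually recovers — mirroring the
comparison of predicted vs observed targets.
"""

from ppredit import (
    PlantedSite,
    build_profile,
    make_transcriptome,
    max_score,
    predicted_vs_observed,
    call_offtargets,
    scan_transcriptome,
)
from ppredit.profile import TargetWindow
from ppredit.simulate import simulate_pileups


def consensus_windows(n=100):
    spec = {-14: ("A", 55), -13: ("G", 74), -10: ("G", 80), -7: ("A", 65),
            -4: ("T", 90)}
    out = []
    for i in range(n):
        bases = {o: "ACGT"[(i + o) % 4] for o in range(-30, 6)}
        bases[0] = "C"
        for o, (nt, count) in spec.items():
            others = [b for b in "ACGT" if b != nt]
            bases[o] = nt if i < count else others[i % 3]
        out.append(TargetWindow(f"g{i}", f"t{i}", 50,
                                "".join(bases[o] for o in range(-30, 6))))
    return out


profile = build_profile(consensus_windows(), bounds=(-17, -1))
anns, truth = make_transcriptome(
    5, 1000, [PlantedSite(0.5)] * 3, seed=41, profile=profile
)

candidates = scan_transcriptome(anns, profile, min_score=200)
print(f"profile max score: {max_score(profile)}")
print("top candidates:")
print(candidates.head(5)[["transcript_id", "position", "score"]]
      .to_string(index=False))

pileups = simulate_pileups(anns, truth, coverage=100, error=0.001, seed=41)
calls, _ = call_offtargets(pileups, anns, profile=profile)
cmp = predicted_vs_observed(candidates, calls)
print("\npredicted vs observed:", cmp["counts"])
print("High-score candidates that are never called mirror the non-edited "
      "candidate class; here only the planted sites carry editing signal.")
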