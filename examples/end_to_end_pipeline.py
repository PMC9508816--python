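"""Run the whole pipeline from files on disk.

Writes a simulated dataset (FASTA + annotation + pileups) into a temporary
directory, then runs the staged pipeline: abundance reference filter ->
replicate-consensus calling -> pooled filters -> context extraction ->
labelling -> consensus profile -> matching-score annotation.  Artifacts are
TSVs stamped with the configuration hash.
"""

import tempfile
from pathlib import Path

import pandas as pd

import ppredit.io as pio
from ppredit import PlantedSite, make_transcriptome, pipeline_run
from ppredit.simulate import simulate_pileups

workdir = Path(tempfile.mkdtemp(prefix="ppredit_demo_"))
anns, truth = make_transcriptome(
    6, 600, [PlantedSite(e) for e in (0.1, 0.3, 0.5, 0.8)], seed=23
)
pileups = simulate_pileups(anns, truth, coverage=100, error=0.001, seed=23)
pio.write_fasta(workdir / "t.fasta", {a.transcript_id: a.sequence for a in anns})
pio.write_annotations(workdir / "ann.tsv", anns)
pio.write_pileups(workdir / "pileups.tsv", pileups)

artifacts = pipeline_run(
    {
        "transcriptome_fasta": str(workdir / "t.fasta"),
        "annotation": str(workdir / "ann.tsv"),
        "pileups": str(workdir / "pileups.tsv"),
        "out_dir": str(workdir / "out"),
    }
)
print("artifacts:")
for name, path in artifacts.items():
    print(f"  {name}: {path}")

calls = pd.read_csv(artifacts["calls"], sep="\t", comment="#")
print("\ncall report:")
print(calls[["label", "accession", "position", "region", "replicates",
             "editing_percent", "matching_score"]].to_string(index=False))
print("\nmatching_score rates each call against the consensus built from "
      "the calls themselves; planted efficiencies were 10-80%.")
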