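# ppredit

Analysis toolkit for **C-to-U RNA editing by PLS-type pentatricopeptide-repeat
(PPR) editing factors** expressed in a heterologous transcriptome.

Plant organelle editing factors such as PPR56 recognise their target RNA
through an array of PPR repeats, one nucleotide per repeat, read off two
amino-acid positions (5 and L) per repeat:

```
T/S + N : A      T/S + D : G      N + S : C      N + D : U      N + N : C/U
```

Repeats are numbered backwards from the C-terminus; the terminal S2-1 repeat
pairs with position −4 upstream of the edited cytidine (position 0), so
repeat *n* reads position −(*n* + 3).  When such a factor is expressed in a
foreign transcriptome it edits *off-targets* — cytidines whose sequence
environment resembles its binding preference.  `ppredit` implements the
dry-lab layer of that kind of experiment:

- **`ppredit.code`** — PPR motifs and arrays, the 5/L code, array/target
  juxtaposition (match / transition / transversion per repeat), single-motif
  mutagenesis and per-repeat match tallies.
- **`ppredit.profile`** — consensus profiles over editing-site environments
  (offsets −30..+5) and the **decile matching score**: an offset where a
  unique nucleotide dominates at ≥ 40% contributes its frequency floored to
  a 10% step (40…90) whenever a candidate window carries that nucleotide;
  a profile's maximum score is the sum over all thresholded offsets.
- **`ppredit.calling`** — replicate-filtered off-target calling from
  per-site A/C/G/T counts: detection in ≥ 2 factor replicates and no
  control replicate, then pooled filters (control C background > 99%,
  control T background < 0.5%, coverage ≥ 20 in sample and control, pooled
  efficiency ≥ 1.5%), pooled edit rates, −30..+5 context extraction and
  `geneeU…` nomenclature labels (e.g. `nad4eU272SL`, `MKNK1eU-55`).
- **`ppredit.scan`** — slide the matching score over every cytidine of a
  transcriptome to rank candidate targets and compare them with observed
  calls.
- **`ppredit.simulate`** — synthetic factors, transcriptomes with planted
  sites, replicate pileups (Poisson coverage, binomial editing, uniform
  error background) and Sanger-like peak pairs, so the whole pipeline is
  testable without any external data.
- **`ppredit.pipeline` / `ppredit.cli`** — the staged pipeline and a thin
  `ppredit` command (`simulate`, `call`, `profile`, `score`, `scan`,
  `label`, `run`).

## Worked example

`examples/offtarget_calling.py` simulates six transcripts with five planted
sites (efficiencies 5–80%), three factor and three control replicates at
coverage 100 and error 10⁻³, and calls sites end to end:

```
planted truth:                           calls:
transcript  position  efficiency        label            region  editing_percent
T001        284       0.05              gene001eU165RR   CDS      5.42
T002        268       0.10              gene002eU149PL   CDS      9.40
T003        514       0.30              gene003eU+35     3'UTR   32.03
T004        348       0.50              gene004eU229LF   CDS     43.56
T005        334       0.80              gene005eU215SF   CDS     81.40
```

All five planted sites are recovered, none else; `editing_percent` is the
pooled T/(A+C+G+T) over the factor replicates and tracks the planted
efficiencies.  The label encodes the region and, for CDS sites, the
1-based CDS position plus the amino-acid change caused by the C-to-U edit.

`examples/consensus_scoring.py` shows the scoring rule itself: with a 43%
A at −14 and a 74% G at −13 the profile thresholds are `(A, 40)` and
`(G, 70)`; a window carrying both scores 110/110, one carrying only the A
scores 40.

The other examples demonstrate juxtaposition/mutagenesis
(`ppr_code_juxtaposition.py`), transcriptome scanning
(`transcriptome_scan.py`) and the file-based pipeline
(`end_to_end_pipeline.py`).

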