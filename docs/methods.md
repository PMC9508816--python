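# Methods

## The recognition model

A PLS-type editing factor is modelled as an ordered array of PPR repeats
(classes P, L, S with a terminal P2–L2–S2 triplet), each carrying the two
specificity-determining amino acids at positions 5 and L.  The core code
maps five (5, L) combinations to nucleotide preferences (T/S+N → A,
T/S+D → G, N+S → C, N+D → U, N+N → C/U); every other combination yields an
explicit empty prediction.  L-type repeats are not covered by the core
code: when their (5, L) pair happens to be in the table they are still
scored, but their rows are flagged non-canonical, and we deliberately do
not invent rules for combinations such as MD, LD or VD — their preferences
are treated as empirical observations in the consensus profile only.

Juxtaposition places the terminal S2-1 repeat at offset −4 upstream of the
edited cytidine (offset 0), one nucleotide per repeat, so repeat *n* reads
offset −(*n* + 3).  Observed bases are classified per repeat as match
(observed ∈ predicted set), transition (purine↔purine or
pyrimidine↔pyrimidine partner of a predicted base), transversion
(anything else) or none (empty prediction, pad, or N).  When a predicted
set contains several bases, match wins over transition wins over
transversion; for the {C, U} prediction an observed purine is a
transversion because neither pyrimidine's transition partner is a purine.

The internal alphabet is DNA (A, C, G, T); U is accepted on input and
normalised to T because transcriptome FASTA and pileup tables are
DNA-alphabet.  Rendering back to RNA is a display concern only.

The bundled `"PPR56-like"` preset is a synthetic stand-in for a natural
13-repeat array: repeats with published 5/L identities use them
(S2-1 ND, L2-2 VD, P2-3 ND, S-4 TN, L-5 LD, P-6 ND, S-7 TD, P-9 TN,
S-10 TD, L-11 MD); the remaining repeats (L-8, P-12, S-13), whose
identities the preset does not model from data, carry placeholder values
(L-8 AD has no code prediction; P-12 TN and S-13 ND are canonical-looking
placeholders).

## Consensus profiles and the matching score

Editing-site environments are summarised as windows over offsets −30..+5
(the default extraction: 30 nt upstream, 5 nt downstream, `'-'`-padded at
transcript ends).  Per offset, nucleotide frequencies are computed over
the windows; pads and N are excluded from numerator *and* denominator.
With deduplication enabled, windows sharing gene **and** sequence count
once, so identical target sequences in transcript variants of one gene do
not inflate the consensus.

An offset is *thresholded* when a unique nucleotide dominates with
frequency ≥ 40%; its weight is the frequency floored to the nearest 10%
step.  Numerical choices:

- **Decile cap.**  Frequencies ≥ 90% (including 100%) map to decile 90;
  the step ladder is 40, 50, …, 90 and never 100.
- **Ties.**  Two nucleotides tied at the top (within 1e−9) leave the
  offset unthresholded — "dominating" implies a unique dominant.  A
  floating-point guard (+1e−9 before flooring) keeps frequencies like
  70/100 on their intended rung.
- **Scoring bounds.**  The profile span used for scoring is a parameter
  (pipeline default −17..+5, covering the array span plus the downstream
  positions with observable bias).  Offset 0 is trivially 100% C in any
  profile built from editing-site windows and therefore contributes a
  constant 90 to every score and to the maximum when it lies inside the
  bounds; comparisons between windows are unaffected.  Bounds that
  exclude 0 (e.g. −17..−1) score the upstream environment alone.

The matching score of a window is the integer sum of decile weights at
thresholded offsets whose nucleotide the window carries; the maximum score
is the sum over all thresholded offsets, attained exactly by the
consensus-matching window.  Scores are monotone: converting one
non-matching thresholded offset to matching adds exactly that offset's
decile.

Profile comparisons (`profile_shift_report`) list every offset where the
thresholded nucleotide or its decile differs, with symmetric-difference
semantics, which is how re-targeted factor variants are compared.

## Off-target calling

The caller consumes per-site, per-replicate A/C/G/T counts for a
factor-expressing group and a mandatory control group (tag-only or
deaminase-dead constructs), plus the transcriptome the reads were mapped
to.  Transcripts first pass an abundance filter (`num_reads ≥ 10` by
default), mirroring the construction of a customized mapping reference
from sufficiently expressed transcripts.

Per-replicate detection is deliberately simple and documented: a site is
detected in a replicate when it has ≥ 2 T reads making up ≥ 1% of the
reads.  This replaces an external statistical variant caller; the
downstream replicate-consensus and pooled filters dominate specificity, so
the simple rule suffices at the simulated error rates.  A site becomes a
candidate when the reference base is C, detection holds in ≥ 2 factor
replicates, and in **no** control replicate.

Candidates then face four pooled-count filters, evaluated jointly so the
outcome is independent of filter order:

| filter | meaning | default |
|---|---|---|
| (i) | control C fraction (clean background) | > 0.99 |
| (ii) | control T fraction (no pre-existing T) | < 0.005 |
| (iii) | pooled coverage in factor *and* control | ≥ 20 reads |
| (iv) | pooled editing efficiency | ≥ 0.015 |

"Pooled" means counts summed across replicates per group.  A site without
control coverage cannot demonstrate a clean background and fails
(i)–(iii).  Edit rates always pool reads before dividing
(ΣT / Σtotal), never average per-replicate ratios; replicates with zero
coverage simply contribute nothing to either sum.  Sanger-style
quantification is the peak ratio T/(T+C).

Labels are 1-based and human-facing while all internal coordinates are
0-based half-open.  CDS sites get `gene` + `eU` + CDS position + the
amino-acid change from applying C→T in the containing codon (standard
genetic code; stop gains print `*`); UTR sites use `eU-n` (5′, nearest
upstream base = 1) and `eU+n` (3′, first base after the stop = 1).
Calls are reported per transcript; collapsing transcript variants of a
gene is deferred to the profile-building dedupe flag.

An optional interpretation of excluding candidates whose best-scoring
alignment is offset from the edited C ("binding-shift" candidates) was
considered but is not applied: no defined rule exists for it, so the
caller reports all passing sites.

## Scanning

The scanner computes the matching score at every position of every
transcript with a vectorised shift-and-compare per thresholded offset,
then keeps reference-C positions with score ≥ `min_score`, sorted by
(score desc, transcript, position) with lexicographic tie-breaks for
determinism.  Windows overlapping transcript ends are scored with pads
contributing zero and flagged `truncated` instead of being discarded.  Any
frequency profile can serve as the matrix; the mechanism, not particular
matrix values, is what the module provides.

## Synthetic data

The generator emulates the *structure* of the experiment at the
pileup-summary level:

- transcriptomes of uniform-composition random transcripts (configurable
  composition vector), each with a central CDS and UTRs and an abundance
  value, default 100, that passes the reference filter;
- planted C-to-U sites with per-site constant efficiencies, placed
  non-overlappingly, optionally with consensus-matching environments whose
  construction-time matching score is recorded in a truth table;
- per replicate and site: total reads ~ Poisson(λ), T reads at planted
  sites in factor replicates ~ Binomial(total, e + ε(1−e)), and each
  non-reference base elsewhere (and everywhere in controls)
  ~ Binomial(total, ε/3), with ε < 0.01;
- Sanger-like peak pairs whose ratio is the efficiency plus Gaussian
  noise.

Default condition for end-to-end validation: 3 factor + 3 control
replicates, λ = 100, ε = 10⁻³, planted efficiencies spanning 5–80% on a
six-transcript, 600-nt-per-transcript fixture (λ = 500 where rate accuracy
rather than detection is probed).  These sizes keep every simulation in
the test suite in the seconds range while leaving the binomial/Poisson
statistics representative.

Randomness: a single master seed fans out to per-replicate NumPy
`SeedSequence` keys `[seed, group, replicate]`, so adding replicates never
perturbs existing ones and every generator is a pure function of its
arguments.

What the synthetic data does **not** emulate — and what passing tests
therefore cannot show about real data: alignment and duplicate-removal
artifacts, strand issues, non-uniform coverage along transcripts, real
transcript-end effects, overdispersed editing efficiencies (a
beta-distributed option exists for robustness checks but is off by
default), RNA secondary structure, SNP sites, and genuine biological
off-target spectra.  Paper-scale off-target counts require the deposited
sequencing data and an external alignment stack and are out of scope
here; the validation surface is planted-site recovery, null behaviour and
score algebra on synthetic fixtures.

## Known limitations

- The per-replicate detection rule is a documented simplification, not a
  statistical test; at error rates approaching the 1% detection threshold
  its false-positive behaviour would need re-examination.
- L-type repeat preferences enter only through observed consensus
  profiles, never through the code.
- Only C→T on the transcript strand is considered; inputs are assumed
  transcript-aligned, so opposite-strand G→A handling is out of scope.
- The file contract is TSV pileup summaries, not SAM/BAM/VCF.
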