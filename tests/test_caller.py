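"""Replicate-consensus calling, pooled filters, rates, context and labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ppredit import (
    ConfigurationError,
    FilterThresholds,
    TranscriptAnnotation,
    apply_filters,
    call_sites,
    edit_rate,
    extract_context,
    label_site,
    parse_site_label,
    per_replicate_call,
    reference_filter,
    sanger_rate,
    shared_offtargets,
)
from ppredit.calling import OffTargetCall


def make_annotation(sequence, tid="T001", gene="geneA", cds_start=None,
                    cds_end=None, num_reads=100.0):
    n = len(sequence)
    if cds_start is None:
        cds_start = n // 5
    if cds_end is None:
        cds_end = cds_start + ((3 * n // 5) // 3) * 3
    return TranscriptAnnotation(
        transcript_id=tid, gene=gene, protein_name=f"{gene} protein",
        sequence=sequence, cds_start=cds_start, cds_end=cds_end,
        num_reads=num_reads,
    )


def pileup_rows(tid, pos, reps):
    """reps: list of (replicate_id, group, nA, nC, nG, nT)."""
    return pd.DataFrame(
        [
            {"transcript_id": tid, "position": pos, "replicate_id": r,
             "group": g, "nA": a, "nC": c, "nG": gg, "nT": t}
            for r, g, a, c, gg, t in reps
        ]
    )


# ---------------------------------------------------------------------------
# reference filter / per-replicate detection

def test_reference_filter_threshold_and_order():
    anns = [make_annotation("C" * 60, tid=f"T{i}", num_reads=nr)
            for i, nr in enumerate([12, 9, 10])]
    kept = reference_filter(anns, min_reads=10)
    assert [a.transcript_id for a in kept] == ["T0", "T2"]
    assert reference_filter(anns, min_reads=100) == []
    assert reference_filter(anns, min_reads=0) == anns


@pytest.mark.parametrize(
    "counts,expected",
    [({"C": 48, "T": 2}, True),        # 2 edited reads at 4%
     ({"C": 99, "T": 1}, False),       # only one edited read
     ({"C": 0, "T": 0}, False),        # zero coverage is not-detected
     ({"C": 500, "T": 4}, False),      # 0.8% < 1% per-replicate rate
     ({"C": 198, "T": 2}, True)],      # exactly 1%
)
def test_per_replicate_detection(counts, expected):
    assert per_replicate_call(counts) is expected


# ---------------------------------------------------------------------------
# replicate-consensus candidate calling

SEQ = "A" * 50 + "C" + "A" * 49  # C at position 50


def _reps(factor_called, control_called, n_factor=3, n_control=3):
    reps = []
    for i in range(n_factor):
        t = 5 if i < factor_called else 0
        reps.append((f"F{i+1}", "factor", 0, 95 - t + 5, 0, t))
    for i in range(n_control):
        t = 5 if i < control_called else 0
        reps.append((f"C{i+1}", "control", 0, 100 - t, 0, t))
    return reps


@pytest.mark.parametrize(
    "factor_called,control_called,is_candidate",
    [(3, 0, True),    # called in 3/3 factor reps, clean controls
     (2, 0, True),    # minimum two replicates
     (1, 0, False),   # one replicate is not enough
     (2, 1, False),   # any control detection vetoes the site
     (0, 0, False)],
)
def test_replicate_consensus_rule(factor_called, control_called, is_candidate):
    ann = make_annotation(SEQ)
    pileups = pileup_rows("T001", 50, _reps(factor_called, control_called))
    cand = call_sites(pileups, [ann])
    assert (len(cand) == 1) is is_candidate


def test_call_sites_requires_reference_c():
    ann = make_annotation(SEQ)
    pileups = pileup_rows("T001", 51, _reps(3, 0))  # reference A there
    assert len(call_sites(pileups, [ann])) == 0


def test_call_sites_controls_mandatory():
    ann = make_annotation(SEQ)
    pileups = pileup_rows("T001", 50, _reps(3, 0))
    with pytest.raises(ConfigurationError):
        call_sites(pileups[pileups["group"] == "factor"], [ann])


# ---------------------------------------------------------------------------
# pooled filters (i)-(iv)

GOOD_FACTOR = {"A": 0, "C": 58, "G": 0, "T": 2}          # cov 60, rate 3.3%
GOOD_CONTROL = {"A": 3, "C": 995, "G": 0, "T": 2}        # C 99.5%, T 0.2%

FILTER_TRUTH_TABLE = [
    # (factor counts, control counts, expected violations)
    (GOOD_FACTOR, GOOD_CONTROL, ()),
    ({"A": 0, "C": 970, "G": 0, "T": 30}, GOOD_CONTROL, ()),
    ({"A": 0, "C": 3920, "G": 0, "T": 80}, GOOD_CONTROL, ()),
    ({"A": 0, "C": 40, "G": 0, "T": 2}, GOOD_CONTROL, ()),           # 4.8%
    ({"A": 0, "C": 990, "G": 0, "T": 10}, GOOD_CONTROL, ("iv",)),    # 1.0%
    ({"A": 0, "C": 17, "G": 0, "T": 2}, GOOD_CONTROL, ("iii",)),     # cov 19
    (GOOD_FACTOR, {"A": 15, "C": 983, "G": 0, "T": 2}, ("i",)),      # C 98.3%
    (GOOD_FACTOR, {"A": 0, "C": 993, "G": 0, "T": 7}, ("ii",)),      # T 0.7%
    (GOOD_FACTOR, {"A": 0, "C": 19, "G": 0, "T": 0}, ("iii",)),      # ctrl cov
    ({"A": 0, "C": 19, "G": 0, "T": 0}, GOOD_CONTROL, ("iii", "iv")),
]


def test_filter_truth_table_exact_survivors():
    """Of ten hand-built candidates exercising criteria (i)-(iv), exactly the
    four constructed survivors pass."""
    results = [apply_filters(f, c) for f, c, _ in FILTER_TRUTH_TABLE]
    assert [passed for passed, _ in results] == [
        not expected for _, _, expected in FILTER_TRUTH_TABLE
    ]
    assert sum(passed for passed, _ in results) == 4
    for (_, violated), (_, _, expected) in zip(results, FILTER_TRUTH_TABLE):
        assert set(violated) == set(expected)


def test_filters_order_independent():
    """The pass set is identical under any permutation of the four filter
    predicates: all predicates are always evaluated."""
    thresholds = FilterThresholds()
    baseline = [apply_filters(f, c, thresholds)[0] for f, c, _ in FILTER_TRUTH_TABLE]

    def reordered_pass(factor, control, order):
        checks = {
            "i": lambda: sum(control.values()) > 0
            and control["C"] / sum(control.values()) > thresholds.ref_c_min,
            "ii": lambda: sum(control.values()) > 0
            and control["T"] / sum(control.values()) < thresholds.ref_t_max,
            "iii": lambda: sum(factor.values()) >= thresholds.min_coverage
            and sum(control.values()) >= thresholds.min_coverage,
            "iv": lambda: sum(factor.values()) > 0
            and factor["T"] / sum(factor.values()) >= thresholds.min_rate,
        }
        return all(checks[k]() for k in order)

    for order in itertools.permutations(["i", "ii", "iii", "iv"]):
        got = [reordered_pass(f, c, order) for f, c, _ in FILTER_TRUTH_TABLE]
        assert got == baseline


def test_missing_control_coverage_fails_with_coverage_reason():
    passed, violated = apply_filters(GOOD_FACTOR, {"A": 0, "C": 0, "G": 0, "T": 0})
    assert not passed
    assert "iii" in violated


# ---------------------------------------------------------------------------
# rates

def test_edit_rate_pools_before_dividing():
    """(5/50) and (10/50) pool to 15/100, not the 0.15/0.2 average midpoint."""
    reps = [{"C": 45, "T": 5}, {"C": 40, "T": 10}]
    assert edit_rate(reps) == pytest.approx(0.15)


def test_edit_rate_zero_and_undefined():
    assert edit_rate([{"C": 40, "T": 0}]) == 0.0
    with pytest.raises(ValueError):
        edit_rate([{"C": 0, "T": 0}, {"C": 0, "T": 0}])


def test_edit_rate_matches_loop_oracle():
    rng = np.random.default_rng(3)
    reps = [
        {b: int(rng.integers(0, 50)) for b in "ACGT"} for _ in range(5)
    ]
    expected = sum(r["T"] for r in reps) / sum(sum(r.values()) for r in reps)
    assert edit_rate(reps) == pytest.approx(expected)


@pytest.mark.parametrize(
    "peak_t,peak_c,expected",
    [(560, 440, 0.56), (0, 900, 0.0), (900, 0, 1.0)],
)
def test_sanger_peak_ratio(peak_t, peak_c, expected):
    assert sanger_rate(peak_t, peak_c) == pytest.approx(expected)


def test_sanger_rate_undefined_when_both_peaks_zero():
    with pytest.raises(ValueError):
        sanger_rate(0, 0)


# ---------------------------------------------------------------------------
# context extraction

def test_extract_context_default_window():
    seq = "".join("ACGT"[i % 4] for i in range(200))
    seq = seq[:100] + "C" + seq[101:]
    ann = make_annotation(seq)
    w = extract_context(ann, 100)
    assert len(w.sequence) == 36
    assert (w.lo, w.hi) == (-30, 5)
    assert w.base_at(0) == "C"
    assert w.sequence == seq[70:106]


def test_extract_context_pads_at_transcript_start():
    seq = "A" * 10 + "C" + "A" * 20
    ann = make_annotation(seq, cds_start=0, cds_end=30)
    w = extract_context(ann, 10)
    assert w.sequence[:20] == "-" * 20  # offsets -30..-11 fall off the 5' end
    assert w.base_at(0) == "C"


def test_extract_context_construct_style_46nt():
    seq = "G" * 60 + "C" + "G" * 39
    ann = make_annotation(seq, cds_start=0, cds_end=99)
    w = extract_context(ann, 60, upstream=40, downstream=5)
    assert len(w.sequence) == 46
    assert (w.lo, w.hi) == (-40, 5)


def test_extract_context_position_out_of_range():
    ann = make_annotation("C" * 60)
    with pytest.raises(IndexError):
        extract_context(ann, 60)


# ---------------------------------------------------------------------------
# nomenclature labels

def test_cds_label_serine_to_leucine():
    """A C at CDS position 272 inside a TCA (Ser) codon labels as
    nad4eU272SL: the edit turns TCA into TTA (Leu)."""
    cds_start = 10
    seq = list("A" * 400)
    seq[cds_start + 270:cds_start + 273] = list("TCA")  # codon 91
    ann = make_annotation("".join(seq), gene="nad4", cds_start=cds_start,
                          cds_end=cds_start + 300)
    label, region = label_site(ann, cds_start + 271)
    assert label == "nad4eU272SL"
    assert region == "CDS"


def test_three_prime_utr_label():
    cds_start, cds_end = 9, 57
    seq = "A" * cds_start + "ATG" + "A" * (cds_end - cds_start - 6) + "TAA" \
        + "A" * 742 + "C" + "A" * 60
    ann = make_annotation(seq, gene="QSOX1", cds_start=cds_start, cds_end=cds_end)
    label, region = label_site(ann, cds_end + 742)
    assert label == "QSOX1eU+743"
    assert region == "3'UTR"


def test_five_prime_utr_label():
    seq = "A" * 45 + "C" + "A" * 54 + "A" * 300
    ann = make_annotation(seq, gene="MKNK1", cds_start=100, cds_end=340)
    label, region = label_site(ann, 45)
    assert label == "MKNK1eU-55"
    assert region == "5'UTR"


def test_stop_gain_label_uses_asterisk():
    cds_start = 12
    seq = list("G" * 120)
    seq[cds_start:cds_start + 6] = list("ATGCAA")  # Met, Gln
    ann = make_annotation("".join(seq), gene="AGFG", cds_start=cds_start,
                          cds_end=cds_start + 60)
    label, region = label_site(ann, cds_start + 3)  # CAA -> TAA
    assert label == "AGFGeU4Q*"
    assert region == "CDS"


def test_label_requires_reference_c():
    ann = make_annotation("A" * 60, cds_start=0, cds_end=60)
    with pytest.raises(ValueError):
        label_site(ann, 30)


def test_label_round_trip():
    """Parsing a label recovers region, in-region position and amino-acid
    change for CDS, 5'UTR and 3'UTR sites."""
    rng = np.random.default_rng(19)
    seq = list("".join(rng.choice(list("ACGT"), size=600)))
    ann = make_annotation("".join(seq), gene="GENE7", cds_start=120, cds_end=480)
    c_positions = [i for i, b in enumerate(ann.sequence) if b == "C"]
    for pos in c_positions[::5]:
        label, region = label_site(ann, pos)
        parsed = parse_site_label(label)
        assert parsed["gene"] == "GENE7"
        assert parsed["region"] == region
        if region == "CDS":
            assert parsed["position"] == pos - 120 + 1
            assert parsed["aa_change"] is not None
        elif region == "5'UTR":
            assert parsed["position"] == 120 - pos
        else:
            assert parsed["position"] == pos - 480 + 1


# ---------------------------------------------------------------------------
# shared off-targets

def _call(tid, pos):
    from ppredit import TargetWindow

    ctx = TargetWindow("g", tid, pos, "A" * 30 + "C" + "AAAAA", lo=-30)
    return OffTargetCall(
        transcript_id=tid, gene="g", position=pos, label=f"geU+{pos}",
        region="3'UTR", context=ctx, edit_rate=0.5, n_replicates_detected=3,
    )


def test_shared_offtargets_set_algebra():
    core = [_call("T1", i * 50) for i in range(1, 8)]          # 7 shared sites
    a = core + [_call("T2", 100)]
    b = core + [_call("T3", 100), _call("T3", 200)]
    c = core + [_call("T4", 100)]
    df = shared_offtargets({"native": a, "mut7": b, "mut4": c})
    inter = df[df["n_sets"] == 3]
    assert len(inter) == 7
    pairwise_ab = (df["native"] & df["mut7"]).sum()
    assert len(inter) <= pairwise_ab


def test_shared_offtargets_disjoint_and_identical():
    a = [_call("T1", 10)]
    b = [_call("T2", 20)]
    df = shared_offtargets({"a": a, "b": b})
    assert (df["n_sets"] == 1).all()
    df2 = shared_offtargets({"a": a, "b": a})
    assert (df2["n_sets"] == 2).all() and len(df2) == 1
    with pytest.raises(ValueError):
        shared_offtargets({"a": a})
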