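"""SNP calling rule, classification, annotation and summaries."""

from collections import Counter
from itertools import permutations

import pytest
from scipy import stats

from pyroest import refdata, synth
from pyroest._util import round1
from pyroest.assembly import Assembly, Contig, ReadPlacement, build_truth_pileup
from pyroest.snps import (GeneAnnotation, PileupColumn, SnpCall, annotate_call,
                          call_snps, classify_substitution,
                          degenerate_consensus, pileup, summaries_to_frame,
                          summarize_classes, summarize_gene, IUPAC_DECODE)


def column(counts_by_strain, cid="c", pos=0):
    return PileupColumn(cid, pos, {s: Counter(c)
                                   for s, c in counts_by_strain.items()})


# --- calling rule ----------------------------------------------------------

@pytest.mark.parametrize("counts,called", [
    ({"R": {"A": 3}, "S": {"G": 2}}, True),     # 3/2 at depth 5: boundary in
    ({"R": {"A": 2}, "S": {"G": 2}}, False),    # depth 4: coverage too low
    ({"R": {"A": 9}, "S": {"G": 1}}, False),    # minority allele seen once
    ({"R": {"A": 5, "G": 5}}, True),            # within-strain polymorphism
])
def test_calling_rule_boundaries(counts, called):
    calls = call_snps([column(counts)])
    assert bool(calls) == called


def test_triallelic_flagged():
    calls = call_snps([column({"R": {"A": 5, "G": 3, "T": 2}})])
    assert len(calls) == 1
    c = calls[0]
    assert (c.major_allele, c.minor_allele, c.triallelic) == ("A", "G", True)


def test_call_rule_equals_naive_scan(simulated, transcripts):
    """Caller agrees with a direct per-column re-scan on synthetic pileups."""
    reads, truths = simulated
    asm = build_truth_pileup(reads, truths, transcripts)
    for cid in list(asm.contigs)[:3]:
        cols = pileup(asm, cid)
        calls = {c.position for c in call_snps(cols)}
        naive = set()
        for col in cols:
            pooled = col.pooled
            if sum(pooled.values()) >= 5 and len(pooled) > 1:
                if sorted(pooled.values())[-2] >= 2:
                    naive.add(col.position)
        assert calls == naive


def test_thresholds_validated():
    with pytest.raises(ValueError):
        call_snps([], min_depth=0)


# --- classification --------------------------------------------------------

def test_classify_all_pairs_symmetric():
    expected = {
        frozenset("AG"): ("transition", "R"),
        frozenset("CT"): ("transition", "Y"),
        frozenset("AC"): ("transversion", "M"),
        frozenset("GT"): ("transversion", "K"),
        frozenset("CG"): ("transversion", "S"),
        frozenset("AT"): ("transversion", "W"),
    }
    for a, b in permutations("ACGT", 2):
        klass, pair, iupac = classify_substitution(a, b)
        want_class, want_iupac = expected[frozenset((a, b))]
        assert klass == want_class and iupac == want_iupac
        assert pair == "/".join(sorted((a, b)))
        assert classify_substitution(a, b) == classify_substitution(b, a)


def test_classify_rejects_bad_alleles():
    with pytest.raises(ValueError):
        classify_substitution("A", "A")
    with pytest.raises(ValueError):
        classify_substitution("A", "N")


# --- pileup ----------------------------------------------------------------

def test_pileup_uniform_and_split(transcripts):
    t = transcripts[0]
    seq = t.sequence
    contig = Contig(t.transcript_id, seq)
    for i in range(5):
        contig.placements.append(ReadPlacement(
            f"r{i}", t.transcript_id, 0, len(seq), "+", seq, "R"))
    asm = Assembly({t.transcript_id: contig})
    cols = pileup(asm, t.transcript_id)
    assert all(c.depth == 5 and len(c.pooled) == 1 for c in cols)
    # one read differing at one site
    mutated = list(seq)
    mutated[10] = "A" if seq[10] != "A" else "G"
    contig.placements.append(ReadPlacement(
        "rX", t.transcript_id, 0, len(seq), "+", "".join(mutated), "S"))
    cols = pileup(asm, t.transcript_id)
    assert cols[10].depth == 6 and sorted(cols[10].pooled.values()) == [1, 5]


def test_pileup_skips_pad_columns():
    contig = Contig("c", "AC*GT")
    contig.placements = [ReadPlacement("r", "c", 0, 5, "+", "AC*GT", "R")]
    asm = Assembly({"c": contig})
    cols = pileup(asm, "c")
    assert [c.position for c in cols] == [0, 1, 2, 3]
    assert "".join(next(iter(c.pooled)) for c in cols) == "ACGT"
    with pytest.raises(KeyError):
        pileup(asm, "nope")


# --- annotation ------------------------------------------------------------

def make_ann(seq, cds, utr3=None, strand="+", frame=0):
    return GeneAnnotation("g", "c", seq, cds, frame=frame, strand=strand,
                          utr3=utr3)


def test_annotate_synonymous_third_position():
    # GCC -> GCT is Ala -> Ala at codon position 3
    seq = "ATGGCCTAA" + "TTTT"
    ann = make_ann(seq, (0, 9), utr3=(9, 13))
    call = SnpCall("c", 5, "C", "T", 8, 2, 10)
    out = annotate_call(call, ann)
    assert (out.region, out.codon_position, out.effect) == ("CDS", 3, "synonymous")
    assert (out.substitution_class, out.iupac) == ("transition", "Y")


def test_annotate_replacement_first_position():
    # AAA (Lys) -> CAA (Gln) at codon position 1
    seq = "ATGAAATAA"
    ann = make_ann(seq, (0, 9))
    out = annotate_call(SnpCall("c", 3, "A", "C", 7, 3, 10), ann)
    assert (out.codon_position, out.effect) == (1, "replacement")
    assert out.substitution_class == "transversion"


def test_annotate_utr3_call():
    seq = "ATGGCCTAA" + "GCGC"
    ann = make_ann(seq, (0, 9), utr3=(9, 13))
    out = annotate_call(SnpCall("c", 11, "G", "A", 6, 4, 10), ann)
    assert (out.region, out.codon_position, out.effect) == ("UTR3", None, None)


def test_annotate_reverse_strand():
    # reverse-strand gene: CDS on the minus strand reads ATG GCC TAA
    from pyroest._util import revcomp
    fwd_cds = "ATGGCCTAA"
    seq = revcomp(fwd_cds)
    ann = make_ann(seq, (0, 9), strand="-")
    # plus-strand position 3 is minus-strand codon2 pos3 (the GCC codon's C)
    out = annotate_call(SnpCall("c", 3, "G", "A", 8, 2, 10), ann)
    # G on plus == C on minus; G->A plus == C->T minus: Ala->Ala synonymous
    assert (out.codon_position, out.effect) == (3, "synonymous")


def test_annotate_out_of_range():
    ann = make_ann("ATGTAA", (0, 6))
    with pytest.raises(ValueError):
        annotate_call(SnpCall("c", 99, "A", "G", 3, 2, 5), ann)


# --- summaries -------------------------------------------------------------

def test_summary_conservation_identities(simulated, transcripts):
    # the published survey rows flagged inconsistent violate syn+rep == Ts+Tv
    # by construction; the identity must hold for every other printed row ...
    for s in refdata.gene_summaries():
        if s.gene_id not in refdata.INCONSISTENT_GENES:
            assert s.syn_count + s.rep_count == s.coding_total
        assert sum(s.ts_by_pos) == s.ts_total
        assert sum(s.tv_by_pos) == s.tv_total
    # ... and unconditionally for summaries derived from actual calls
    reads, truths = simulated
    asm = build_truth_pileup(reads, truths, transcripts)
    for t in transcripts:
        if t.transcript_id not in asm.contigs:
            continue
        ann = GeneAnnotation(t.transcript_id, t.transcript_id, t.sequence,
                             t.cds, utr3=t.utr3)
        calls = [annotate_call(c, ann)
                 for c in call_snps(pileup(asm, t.transcript_id))]
        s = summarize_gene(calls, ann)
        assert s.syn_count + s.rep_count == s.coding_total


def test_published_per_gene_bp_per_snp():
    printed = refdata.printed_bp_per_snp()
    mismatched = []
    for s in refdata.gene_summaries():
        if round1(s.bp_per_snp) != printed[s.gene_id]:
            mismatched.append(s.gene_id)
    assert set(mismatched) == refdata.INCONSISTENT_GENES


def test_summarize_gene_from_calls():
    seq = "ATGGCCAAATAA" + "GCGCGC"
    ann = GeneAnnotation("g", "c", seq, (0, 12), utr3=(12, 18))
    calls = [
        SnpCall("c", 5, "C", "T", 8, 2, 10),    # syn transition pos3
        SnpCall("c", 6, "A", "C", 7, 3, 10),    # rep transversion pos1
        SnpCall("c", 13, "C", "T", 6, 4, 10),   # UTR3 transition
    ]
    s = summarize_gene(calls, ann)
    assert s.ts_by_pos == (0, 0, 1) and s.tv_by_pos == (1, 0, 0)
    assert (s.syn_count, s.rep_count) == (1, 1)
    assert (s.utr3_ts, s.utr3_tv) == (1, 0)
    assert s.bp_per_snp == pytest.approx(12 / 3)
    empty = summarize_gene([], ann)
    assert empty.coding_total == 0 and empty.bp_per_snp is None


def test_summarize_classes_single_transition():
    seq = "ATGGCCTAA"
    ann = GeneAnnotation("g", "c", seq, (0, 9))
    s = summarize_gene([SnpCall("c", 5, "C", "T", 8, 2, 10)], ann)
    table, _ = summarize_classes([s])
    coding = table.set_index("dna_class").loc["coding"]
    assert (coding.ts, coding.tv, coding.pct_tv) == (1, 0, 0.0)
    with pytest.raises(ValueError):
        summarize_classes([])


def test_summaries_frame_columns():
    df = summaries_to_frame(refdata.gene_summaries())
    assert len(df) == 20
    assert df["cds_len"].sum() == refdata.POLYMORPHISM_TOTALS["coding_bp"]
    assert (df["ts_total"] + df["tv_total"]).equals(df["coding_total"])


# --- degenerate consensus --------------------------------------------------

def test_degenerate_consensus_round_trip():
    consensus = "ACGTACGTACGT"
    calls = [SnpCall("c", 1, "C", "T", 8, 2, 10),
             SnpCall("c", 6, "G", "T", 7, 3, 10)]
    out = degenerate_consensus(consensus, calls)
    assert out[1] == "Y" and out[6] == "K"
    assert degenerate_consensus(consensus, []) == consensus
    for call in calls:
        assert IUPAC_DECODE[out[call.position]] == \
            frozenset((call.major_allele, call.minor_allele))


# --- recovery and error bound ----------------------------------------------

def test_false_call_rate_bounded_under_sequencing_error(transcripts):
    """With 1% per-base error and no planted variants, the false-call rate
    per bp stays below 10x the two-hit binomial tail at the mean depth."""
    ab = synth.AbundanceTable.random(transcripts, 0, 0, seed=51)
    reads, truths = synth.simulate_reads(
        transcripts, ab, n_reads_per_strain=2500, error_rate=0.01,
        decoration_probs={}, seed=52)
    asm = build_truth_pileup(reads, truths, transcripts)
    n_bp = 0
    n_false = 0
    depths = []
    for cid in asm.contigs:
        cols = pileup(asm, cid)
        calls = call_snps(cols)
        n_false += len(calls)
        n_bp += len(cols)
        depths += [c.depth for c in cols]
    mean_depth = sum(depths) / len(depths)
    # probability that >= 2 reads show the same specific wrong base
    tail = stats.binom.sf(1, round(mean_depth), 0.01 / 3)
    assert n_false / n_bp < 10 * max(tail, 1e-12) + 3 / n_bp
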