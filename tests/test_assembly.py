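"""Assembly model tests: ACE I/O, truth pileups, statistics, redundancy."""

import numpy as np
import pytest

from pyroest import synth
from pyroest.assembly import (Assembly, Contig, ReadPlacement, assembly_stats,
                              build_truth_pileup, length_ratio_table,
                              mean_depth, read_ace, redundancy_scan,
                              write_ace)

MINIMAL_ACE = """AS 1 2

CO ctg1 12 2 0 U
ACGT*ACGTACG

BQ
30 30 30 30 30 30 30 30 30 30 30

AF r1|strain=R U 1
AF r2|strain=S C 3

RD r1|strain=R 8 0 0
ACGT*ACG

QA 1 8 1 8
DS CHROMAT_FILE: r1 PHD_FILE: r1.phd.1 TIME: 0

RD r2|strain=S 10 0 0
GT*ACGTACG

QA 1 10 1 10
DS CHROMAT_FILE: r2 PHD_FILE: r2.phd.1 TIME: 0
"""


@pytest.fixture
def minimal_ace(tmp_path):
    p = tmp_path / "mini.ace"
    p.write_text(MINIMAL_ACE)
    return p


def test_read_ace_minimal(minimal_ace):
    asm = read_ace(minimal_ace)
    assert list(asm.contigs) == ["ctg1"]
    c = asm.contigs["ctg1"]
    assert c.padded_consensus == "ACGT*ACGTACG"
    assert c.unpadded_length == 11
    p1, p2 = c.placements
    assert (p1.start, p1.end, p1.strand, p1.strain) == (0, 8, "+", "R")
    assert (p2.start, p2.end, p2.strand, p2.strain) == (2, 12, "-", "S")


def test_ace_round_trip(minimal_ace, tmp_path):
    asm = read_ace(minimal_ace)
    out = tmp_path / "rt.ace"
    write_ace(asm, out)
    again = read_ace(out)
    key = lambda a: {cid: (c.padded_consensus,
                           [(p.read_id, p.start, p.strand, p.padded_sequence)
                            for p in c.placements])
                     for cid, c in a.contigs.items()}
    assert key(asm) == key(again)


def test_read_ace_malformed(tmp_path):
    p = tmp_path / "bad.ace"
    p.write_text("AS one two\n\nCO nonsense\n")
    with pytest.raises(ValueError, match="malformed"):
        read_ace(p)


def test_unknown_strain_warns(tmp_path):
    text = MINIMAL_ACE.replace("r1|strain=R", "r1_plain")
    p = tmp_path / "u.ace"
    p.write_text(text)
    with pytest.warns(UserWarning, match="strain"):
        asm = read_ace(p)
    assert asm.contigs["ctg1"].placements[0].strain == "unknown"


# --- truth pileup ----------------------------------------------------------

def test_truth_pileup_depth_equals_interval_coverage(transcripts):
    """Per-column depth must equal direct interval-arithmetic coverage."""
    t = transcripts[0]
    ab = synth.AbundanceTable({tt.transcript_id: (1.0, 1.0)
                               if tt is t else (0.0, 0.0)
                               for tt in transcripts[:2]})
    reads, truths = synth.simulate_reads(
        transcripts[:2], ab, n_reads_per_strain=5,
        decoration_probs={}, seed=31)
    asm = build_truth_pileup(reads, truths, transcripts[:2])
    assert list(asm.contigs) == [t.transcript_id]
    contig = asm.contigs[t.transcript_id]
    cover = np.zeros(len(t.sequence), dtype=int)
    for rt in truths:
        cover[rt.start:rt.end] += 1
    assert (contig.column_depths() == cover).all()


def test_truth_pileup_empty_and_multi(transcripts):
    assert build_truth_pileup([], [], transcripts).contigs == {}
    ab = synth.AbundanceTable.random(transcripts, 0, 0, seed=3)
    reads, truths = synth.simulate_reads(transcripts, ab, 300,
                                         decoration_probs={}, seed=4)
    asm = build_truth_pileup(reads, truths, transcripts)
    used = {t.transcript_id for t in truths}
    assert set(asm.contigs) == used


def test_truth_pileup_mismatch_errors(transcripts):
    ab = synth.AbundanceTable.random(transcripts, 0, 0, seed=3)
    reads, truths = synth.simulate_reads(transcripts, ab, 5,
                                         decoration_probs={}, seed=4)
    with pytest.raises(ValueError, match="truth"):
        build_truth_pileup(reads, truths[1:], transcripts)


# --- statistics ------------------------------------------------------------

def test_mean_depth_printed_totals():
    assert mean_depth(149_406, 18_103) == 8.3
    assert mean_depth(1, 1) == 1.0


def test_assembly_stats_binning_and_profile():
    contig = Contig("c1", "A" * 255)
    contig.placements = [ReadPlacement(f"r{i}", "c1", 0, 255, "+", "A" * 255)
                         for i in range(4)]
    asm = Assembly({"c1": contig})
    st = assembly_stats(asm)
    assert st.n_contigs == 1 and st.n_reads_used == 4
    assert st.mean_depth == 4.0
    assert st.length_histogram.loc[250] == 1
    # uniform full-length coverage: flat profile at depth 4
    assert np.allclose(st.depth_profile, 4.0)


def test_assembly_stats_empty():
    st = assembly_stats(Assembly())
    assert st.n_contigs == 0 and st.mean_depth == 0.0


def test_depth_profile_integrates_to_total_bases(transcripts):
    ab = synth.AbundanceTable.random(transcripts, 0, 0, seed=3)
    reads, truths = synth.simulate_reads(transcripts, ab, 500,
                                         decoration_probs={}, seed=4)
    asm = build_truth_pileup(reads, truths, transcripts)
    # exact identity: summed column depths == summed placement lengths
    total_cols = sum(c.column_depths().sum() for c in asm.contigs.values())
    total_bases = sum(p.end - p.start for c in asm.contigs.values()
                      for p in c.placements)
    assert total_cols == total_bases


# --- redundancy scan -------------------------------------------------------

def sliding_window_oracle(subject, query, max_mismatch_frac):
    allowed = int(max_mismatch_frac * len(subject))
    for start in range(len(query) - len(subject) + 1):
        window = query[start:start + len(subject)]
        if sum(a != b for a, b in zip(subject, window)) <= allowed:
            return True
    return False


def test_redundancy_exact_containment(rng):
    a = "".join(rng.choice(list("ACGT"), size=300))
    b = a[50:150]
    df = redundancy_scan({"B": b}, {"A": a, "B": b})
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.subject_id, row.query_id, row.query_start) == ("B", "A", 50)
    # detection of exact containment does not depend on dict order
    df2 = redundancy_scan({"B": b}, {"B": b, "A": a})
    assert len(df2) == 1 and df2.iloc[0].query_id == "A"


def test_redundancy_unrelated_no_match(rng):
    a = "".join(rng.choice(list("ACGT"), size=300))
    b = "".join(rng.choice(list("ACGT"), size=300))
    assert redundancy_scan({"A": a}, {"B": b}).empty


def test_redundancy_planted_block_vs_oracle(rng):
    block = "".join(rng.choice(list("ACGT"), size=60))
    host = ("".join(rng.choice(list("ACGT"), size=100)) + block +
            "".join(rng.choice(list("ACGT"), size=100)))
    df = redundancy_scan({"blk": block}, {"host": host}, min_len=40)
    assert len(df) == 1 and df.iloc[0].query_start == 100
    assert sliding_window_oracle(block, host, 0.05)


def test_redundancy_min_len_guard():
    with pytest.raises(ValueError):
        redundancy_scan({}, {}, min_len=5, k=12)


# --- length ratios ---------------------------------------------------------

def test_length_ratio_table():
    c1 = Contig("c1", "A" * 500)
    c1.placements = [ReadPlacement("r", "c1", 0, 500, "+", "A" * 500)]
    c2 = Contig("c2", "A" * 1000)
    c2.placements = [ReadPlacement("q", "c2", 0, 1000, "+", "A" * 1000)]
    contigs = {"c1": c1, "c2": c2}
    refs = {"g1": 1000, "g2": 1000}
    df = length_ratio_table(contigs, refs, {"c1": "g1", "c2": "g2"})
    assert df.set_index("contig_id").loc["c1", "ratio"] == 0.5
    assert df.set_index("contig_id").loc["c2", "ratio"] == 1.0
    with pytest.warns(UserWarning, match="unknown reference"):
        df = length_ratio_table(contigs, refs, {"c1": "nope"})
    assert df.empty


def test_deeper_contigs_closer_to_unity(transcripts):
    """With more reads, simulated contigs span more of their transcript."""
    ab = synth.AbundanceTable.random(transcripts, 0, 0, seed=3)
    ratios = {}
    for n in (10, 400):
        reads, truths = synth.simulate_reads(transcripts, ab, n,
                                             decoration_probs={}, seed=5)
        spans = {}
        for t in truths:
            lo, hi = spans.get(t.transcript_id, (10**9, 0))
            spans[t.transcript_id] = (min(lo, t.start), max(hi, t.end))
        by_id = {t.transcript_id: t for t in transcripts}
        vals = [(hi - lo) / len(by_id[tid].sequence)
                for tid, (lo, hi) in spans.items()]
        ratios[n] = np.median(vals)
    assert ratios[400] > ratios[10]
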