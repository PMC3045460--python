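"""Published summary tables from the two-strain An. funestus 454 EST survey.

These are the printed numbers of the original study, shipped as in-package
fixtures: the per-gene polymorphism survey of 20 contigs (immunity,
detoxification and housekeeping genes), the DNA-class transition/transversion
table derived from it, the cross-species percent-similarity table, and the
global read/assembly totals.  They serve as inputs for reproduction tests and
for the acceptance script; nothing here is computed.

Known internal inconsistencies of the printed polymorphism table (kept
verbatim, flagged below): the CTLMA1 and Actin rows print a bp/SNP value that
cannot be derived from their own printed component counts (CTLMA1 needs a
coding total of 10 and a 3'UTR total of 1 where the components sum to 9 and
4; Actin needs the printed coding total 11 where its Ts+Tv components sum to
12).  The printed grand "Average" of 55.2 bp/SNP matches no tested formula.
"""

from __future__ import annotations

from .snps import GeneSnpSummary

# ---------------------------------------------------------------------------
# global sequencing / assembly totals as printed

READ_TOTALS = {
    "raw_reads": 375_619,
    "raw_bp": 68_308_429,
    "trimmed_reads": 213_410,       # reads > 30 bp after trimming
    "trimmed_bp": 40_078_792,
    "n_contigs": 18_103,
    "reads_used_in_assembly": 149_406,
}

# per-strain read counts (resistant FUMOZ-R laboratory strain vs susceptible
# Kela field strain): raw, trimmed, used in assembly
STRAIN_READS = {
    "R": {"raw": 170_861, "trimmed": 100_521, "assembled": 73_589},
    "S": {"raw": 204_758, "trimmed": 109_733, "assembled": 75_817},
}

# ---------------------------------------------------------------------------
# most differentially represented contigs (resistant count, susceptible count)

DIFF_REPR_CONTIGS = [
    ("C4346", 241, 0),
    ("C3969", 35, 0),
    ("C2639", 19, 0),
    ("C2093", 10, 0),
    ("C337", 0, 132),
    ("C140", 1, 71),
    ("C6522", 14, 210),
    ("C3146", 1, 20),
]

# ---------------------------------------------------------------------------
# per-gene polymorphism survey (20 contigs)
# columns: gene, group, cds_len, (ts1, ts2, ts3), (tv1, tv2, tv3), syn, rep,
#          utr3_len (None where not covered), utr3_ts, utr3_tv,
#          printed bp/SNP
POLYMORPHISM_ROWS = [
    ("TEP1",            "immune", 647,  (1, 2, 7),  (5, 1, 2),  10, 8,  None, 0, 0, 35.9),
    ("serine_protease", "immune", 947,  (1, 3, 9),  (2, 0, 3),  11, 7,  54,   0, 0, 52.6),
    ("trypsin",         "immune", 858,  (2, 3, 8),  (2, 1, 4),  11, 9,  69,   2, 1, 37.3),
    ("CLIPB3",          "immune", 1019, (6, 3, 6),  (4, 3, 6),  11, 17, 152,  0, 1, 35.1),
    ("APL1",            "immune", 792,  (0, 0, 4),  (1, 0, 1),  5,  1,  294,  8, 4, 44.0),
    ("glycoprotein",    "immune", 502,  (0, 1, 4),  (0, 0, 4),  8,  1,  None, 0, 0, 55.8),
    ("CLIPB4",          "immune", 532,  (0, 0, 0),  (3, 0, 4),  0,  7,  285,  3, 4, 38.0),
    ("Toll",            "immune", 1012, (1, 0, 8),  (0, 1, 3),  11, 2,  188,  0, 3, 63.2),
    ("serpin_3",        "immune", 532,  (0, 2, 3),  (0, 1, 0),  2,  4,  94,   2, 1, 59.1),
    ("serpin_5",        "immune", 494,  (0, 1, 1),  (0, 1, 0),  2,  1,  194,  2, 0, 98.8),
    ("CTLMA1",          "immune", 406,  (0, 0, 5),  (2, 0, 2),  6,  4,  81,   2, 2, 36.9),
    ("ABC_transporter", "detox",  534,  (0, 1, 4),  (0, 1, 0),  4,  2,  269,  6, 4, 33.4),
    ("HSP20",           "detox",  980,  (1, 0, 7),  (0, 1, 3),  10, 2,  329,  0, 0, 81.7),
    ("GSTe2",           "detox",  462,  (2, 0, 3),  (0, 0, 2),  5,  2,  86,   0, 0, 66.0),
    ("GSTd1-3",         "detox",  322,  (1, 0, 1),  (0, 0, 0),  1,  1,  101,  1, 2, 64.4),
    ("CPLC9",           "detox",  806,  (4, 0, 4),  (0, 1, 0),  4,  5,  124,  2, 0, 73.3),
    ("CYP6AH1",         "detox",  728,  (0, 1, 3),  (0, 0, 1),  4,  1,  87,   3, 2, 72.8),
    ("Ribosomal_60S",   "housekeeping", 639,  (0, 2, 1), (0, 0, 1), 2, 2, 99,  0, 3, 91.3),
    ("Actin",           "housekeeping", 1240, (2, 2, 4), (0, 1, 3), 6, 5, 223, 0, 1, 103.3),
    ("tubulin",         "housekeeping", 843,  (0, 1, 5), (0, 0, 3), 8, 1, 154, 0, 0, 93.7),
]

# rows whose printed bp/SNP cannot be reproduced from their own printed
# component counts (see module docstring)
INCONSISTENT_GENES = {"CTLMA1", "Actin"}

# printed per-group subtotal means of the bp/SNP column
GROUP_BP_PER_SNP = {"immune": 50.6, "detox": 65.2, "housekeeping": 96.1}

# printed DNA-class transition/transversion table
DNA_CLASS_TABLE = {
    "non_coding_3utr": {"ts": 31, "tv": 28, "pct_tv": 47.4},
    "coding": {"ts": 130, "tv": 73, "pct_tv": 35.9},
    "third_coding_position": {"ts": 87, "tv": 42, "pct_tv": 32.5},
}

# printed grand totals of the polymorphism survey
POLYMORPHISM_TOTALS = {
    "coding_bp": 14_295,
    "coding_snps": 203,
    "utr3_bp": 2_883,
    "utr3_snps": 59,
    "mean_utr3_len": 160,
}


def gene_summaries() -> list[GeneSnpSummary]:
    """The 20-gene survey as GeneSnpSummary objects built from components."""
    out = []
    for (gene, _grp, cds_len, ts, tv, syn, rep, utr_len, uts, utv,
         _printed) in POLYMORPHISM_ROWS:
        out.append(GeneSnpSummary(
            gene_id=gene, cds_len=cds_len, utr3_len=utr_len or 0,
            ts_by_pos=ts, tv_by_pos=tv, syn_count=syn, rep_count=rep,
            utr3_ts=uts, utr3_tv=utv,
        ))
    return out


def gene_groups() -> dict[str, str]:
    return {row[0]: row[1] for row in POLYMORPHISM_ROWS}


def printed_bp_per_snp() -> dict[str, float]:
    return {row[0]: row[-1] for row in POLYMORPHISM_ROWS}


# ---------------------------------------------------------------------------
# cross-species percent similarity of the same 20 genes
# columns: An. gambiae, Cx. quinquefasciatus, Ae. aegypti

SIMILARITY_ROWS = [
    ("TEP1",            "immune", 70, 40, 39),
    ("serine_protease", "immune", 77, 55, 59),
    ("trypsin",         "immune", 66, 52, 52),
    ("CLIPB3",          "immune", 62, 50, 47),
    ("APL1",            "immune", 63, 31, 29),
    ("glycoprotein",    "immune", 90, 38, 67),
    ("CLIPB4",          "immune", 68, 48, 53),
    ("Toll",            "immune", 88, 81, 78),
    ("serpin_3",        "immune", 83, 53, 48),
    ("serpin_5",        "immune", 74, 53, 50),
    ("CTLMA1",          "immune", 77, 27, 28),
    ("ABC_transporter", "detox", 77, 65, 61),
    ("HSP20",           "detox", 77, 50, 56),
    ("GSTe2",           "detox", 89, 68, 66),
    ("GSTd1-3",         "detox", 73, 41, 36),
    ("CPLC9",           "detox", 84, 47, 56),
    ("CYP6AH1",         "detox", 85, 54, 62),
    ("Ribosomal_60S",   "housekeeping", 94, 89, 79),
    ("Actin",           "housekeeping", 96, 95, 95),
    ("tubulin",         "housekeeping", 94, 93, 94),
]

SIMILARITY_SPECIES = ["An_gambiae", "Cx_quinquefasciatus", "Ae_aegypti"]

# printed per-group and overall similarity means
SIMILARITY_GROUP_MEANS = {
    "immune": {"An_gambiae": 74.4, "Cx_quinquefasciatus": 48.0, "Ae_aegypti": 50.0},
    "detox": {"An_gambiae": 80.8, "Cx_quinquefasciatus": 54.1, "Ae_aegypti": 56.1},
    "housekeeping": {"An_gambiae": 94.7, "Cx_quinquefasciatus": 92.3, "Ae_aegypti": 89.3},
    "overall": {"An_gambiae": 79.35, "Cx_quinquefasciatus": 56.5, "Ae_aegypti": 57.75},
}

# group-mean cells that are truncations rather than roundings of the cell mean
SIMILARITY_MEAN_TRUNCATED = {("detox", "Cx_quinquefasciatus"),
                             ("detox", "Ae_aegypti")}


def similarity_frame():
    import pandas as pd
    return pd.DataFrame(
        [row[2:] for row in SIMILARITY_ROWS],
        index=[row[0] for row in SIMILARITY_ROWS],
        columns=SIMILARITY_SPECIES,
    ).astype(float)
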