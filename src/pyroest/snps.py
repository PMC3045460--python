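"""SNP calling and classification from assembly pileups.

The calling rule is the conservative two-reads rule used for 454 EST data:
a site is polymorphic when it is covered by at least ``min_depth`` reads
(default 5) and the minority allele is seen at least ``min_minor`` times
(default 2).  Reads are pooled across strains for calling; per-strain tallies
remain available on every column.

Each call is classified by substitution class (transition A<->G / C<->T vs
the four transversions), base-pair class, IUPAC degenerate code, codon
position within the annotated CDS, synonymous/replacement effect under the
standard genetic code, and region (CDS vs 3'UTR).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio.Seq import Seq

from ._util import revcomp, round1, trunc1
from .assembly import Assembly

TRANSITIONS = {frozenset("AG"), frozenset("CT")}
IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
}
IUPAC_DECODE = {v: k for k, v in IUPAC.items()}


@dataclass
class PileupColumn:
    """Per-strain base counts over one unpadded consensus position."""

    contig_id: str
    position: int                       # 0-based, unpadded
    strain_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def pooled(self) -> Counter:
        total: Counter = Counter()
        for c in self.strain_counts.values():
            total.update(c)
        return total

    @property
    def depth(self) -> int:
        return sum(self.pooled.values())


@dataclass
class SnpCall:
    contig_id: str
    position: int
    major_allele: str
    minor_allele: str
    major_count: int
    minor_count: int
    depth: int
    triallelic: bool = False
    region: str | None = None           # CDS | UTR3 | other
    substitution_class: str | None = None
    pair_class: str | None = None       # e.g. "C/T"
    codon_position: int | None = None   # 1|2|3, None outside CDS
    effect: str | None = None           # synonymous | replacement, None outside CDS
    iupac: str | None = None


@dataclass
class GeneAnnotation:
    """CDS/frame/3'UTR annotation of one contig, with its unpadded sequence."""

    gene_id: str
    contig_id: str
    sequence: str
    cds: tuple[int, int]
    frame: int = 0
    strand: str = "+"
    utr3: tuple[int, int] | None = None


@dataclass
class GeneSnpSummary:
    """Per-gene cross-tabulation of coding and 3'UTR substitutions."""

    gene_id: str
    cds_len: int
    utr3_len: int
    ts_by_pos: tuple[int, int, int] = (0, 0, 0)
    tv_by_pos: tuple[int, int, int] = (0, 0, 0)
    syn_count: int = 0
    rep_count: int = 0
    utr3_ts: int = 0
    utr3_tv: int = 0

    @property
    def ts_total(self) -> int:
        return sum(self.ts_by_pos)

    @property
    def tv_total(self) -> int:
        return sum(self.tv_by_pos)

    @property
    def coding_total(self) -> int:
        return self.ts_total + self.tv_total

    @property
    def utr3_total(self) -> int:
        return self.utr3_ts + self.utr3_tv

    @property
    def bp_per_snp(self) -> float | None:
        """cds_len over all observed substitutions (coding + 3'UTR); None if 0."""
        total = self.coding_total + self.utr3_total
        return None if total == 0 else self.cds_len / total


def pileup(assembly: Assembly, contig_id: str) -> list[PileupColumn]:
    """One column per unpadded consensus position, strains tallied separately.

    Pad columns ('*' in the consensus) are skipped; pads and non-ACGT
    characters inside reads never enter the base counts.
    """
    if contig_id not in assembly.contigs:
        raise KeyError(f"unknown contig {contig_id!r}")
    contig = assembly.contigs[contig_id]
    padded = contig.padded_consensus
    columns: list[PileupColumn] = []
    upos = 0
    pad_to_col: dict[int, PileupColumn] = {}
    for ppos, base in enumerate(padded):
        if base == "*":
            continue
        col = PileupColumn(contig_id=contig_id, position=upos)
        pad_to_col[ppos] = col
        columns.append(col)
        upos += 1
    for p in contig.placements:
        for ppos in range(max(p.start, 0), min(p.end, len(padded))):
            col = pad_to_col.get(ppos)
            if col is None:
                continue
            ch = p.padded_sequence[ppos - p.start].upper()
            if ch in "ACGT":
                col.strain_counts.setdefault(p.strain, Counter())[ch] += 1
    return columns


def call_snps(
    columns: list[PileupColumn], min_depth: int = 5, min_minor: int = 2
) -> list[SnpCall]:
    """Apply the minority-allele rule to pooled per-column counts.

    Tri-allelic columns (a third allele also reaching min_minor) are called
    on the top two alleles and flagged.  Ties are broken alphabetically for
    determinism.
    """
    if min_depth < 1 or min_minor < 1:
        raise ValueError("thresholds must be >= 1")
    calls = []
    for col in columns:
        pooled = col.pooled
        depth = sum(pooled.values())
        if depth < min_depth or len(pooled) < 2:
            continue
        ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
        (major, mc), (minor, nc) = ranked[0], ranked[1]
        if nc < min_minor:
            continue
        tri = len(ranked) > 2 and ranked[2][1] >= min_minor
        calls.append(SnpCall(
            contig_id=col.contig_id, position=col.position,
            major_allele=major, minor_allele=minor,
            major_count=mc, minor_count=nc, depth=depth, triallelic=tri,
        ))
    return calls


def classify_substitution(allele_a: str, allele_b: str) -> tuple[str, str, str]:
    """(transition|transversion, pair class like 'C/T', IUPAC code)."""
    a, b = allele_a.upper(), allele_b.upper()
    if a == b or a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"alleles must be two distinct ACGT bases, got {a}/{b}")
    pair = frozenset((a, b))
    klass = "transition" if pair in TRANSITIONS else "transversion"
    return klass, "/".join(sorted(pair)), IUPAC[pair]


def annotate_call(call: SnpCall, annotation: GeneAnnotation) -> SnpCall:
    """Fill region, codon position, effect and classification on a call."""
    seq = annotation.sequence
    if not 0 <= call.position < len(seq):
        raise ValueError(f"position {call.position} outside contig "
                         f"{annotation.contig_id!r}")
    klass, pair, iupac = classify_substitution(call.major_allele,
                                               call.minor_allele)
    cs, ce = annotation.cds
    in_cds = cs <= call.position < ce
    in_utr = (annotation.utr3 is not None
              and annotation.utr3[0] <= call.position < annotation.utr3[1])
    region = "CDS" if in_cds else ("UTR3" if in_utr else "other")
    codon_position = None
    effect = None
    if in_cds:
        if annotation.strand == "+":
            off = call.position - (cs + annotation.frame)
        else:
            off = (ce - 1 - call.position) - annotation.frame
        if off >= 0:
            codon_position = off % 3 + 1
            effect = _effect(seq, call, annotation, off)
    return replace(call, region=region, substitution_class=klass,
                   pair_class=pair, codon_position=codon_position,
                   effect=effect, iupac=iupac)


def _effect(seq: str, call: SnpCall, ann: GeneAnnotation, off: int) -> str | None:
    """Synonymous/replacement by translating major- vs minor-allele codons."""
    cs, ce = ann.cds
    if ann.strand == "+":
        codon_start = cs + ann.frame + (off // 3) * 3
        if codon_start + 3 > ce:
            return None
        codon = list(seq[codon_start:codon_start + 3])
        idx = call.position - codon_start
        maj, mino = call.major_allele, call.minor_allele
    else:
        rc = revcomp(seq[cs:ce])
        pos_rc = ce - 1 - call.position
        codon_start = ann.frame + (off // 3) * 3
        if codon_start + 3 > len(rc):
            return None
        codon = list(rc[codon_start:codon_start + 3])
        idx = pos_rc - codon_start
        maj, mino = revcomp(call.major_allele), revcomp(call.minor_allele)
    codon[idx] = maj
    aa_major = str(Seq("".join(codon)).translate())
    codon[idx] = mino
    aa_minor = str(Seq("".join(codon)).translate())
    return "synonymous" if aa_major == aa_minor else "replacement"


def summarize_gene(calls: list[SnpCall], annotation: GeneAnnotation) -> GeneSnpSummary:
    """Cross-tabulate annotated calls of one gene into a summary row."""
    ts = [0, 0, 0]
    tv = [0, 0, 0]
    syn = rep = utr_ts = utr_tv = 0
    for call in calls:
        if call.contig_id != annotation.contig_id:
            raise ValueError("call does not belong to this gene's contig")
        if call.substitution_class is None:
            call = annotate_call(call, annotation)
        if call.region == "CDS" and call.codon_position is not None:
            if call.substitution_class == "transition":
                ts[call.codon_position - 1] += 1
            else:
                tv[call.codon_position - 1] += 1
            if call.effect == "synonymous":
                syn += 1
            elif call.effect == "replacement":
                rep += 1
        elif call.region == "UTR3":
            if call.substitution_class == "transition":
                utr_ts += 1
            else:
                utr_tv += 1
    cs, ce = annotation.cds
    utr_len = 0
    if annotation.utr3 is not None:
        utr_len = annotation.utr3[1] - annotation.utr3[0]
    return GeneSnpSummary(
        gene_id=annotation.gene_id, cds_len=ce - cs, utr3_len=utr_len,
        ts_by_pos=tuple(ts), tv_by_pos=tuple(tv),
        syn_count=syn, rep_count=rep, utr3_ts=utr_ts, utr3_tv=utr_tv,
    )


def summarize_classes(
    summaries: list[GeneSnpSummary], calls: list[SnpCall] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """DNA-class transition/transversion table, plus pair-class distribution.

    The class table has one row per DNA class (non-coding 3'UTR, coding,
    third coding position) with Ts and Tv counts and %Tv; percentage columns
    follow the package convention of flooring to one decimal.  The pair-class
    distribution (share of total substitutions per base pair, e.g. C/T) needs
    fully classified calls and is None when none are given.
    """
    if not summaries:
        raise ValueError("need at least one gene summary")
    utr_ts = sum(s.utr3_ts for s in summaries)
    utr_tv = sum(s.utr3_tv for s in summaries)
    cd_ts = sum(s.ts_total for s in summaries)
    cd_tv = sum(s.tv_total for s in summaries)
    p3_ts = sum(s.ts_by_pos[2] for s in summaries)
    p3_tv = sum(s.tv_by_pos[2] for s in summaries)

    def row(name, ts, tv):
        total = ts + tv
        return {"dna_class": name, "ts": ts, "tv": tv,
                "pct_tv": trunc1(100 * tv / total) if total else 0.0}

    table = pd.DataFrame([
        row("non_coding_3utr", utr_ts, utr_tv),
        row("coding", cd_ts, cd_tv),
        row("third_coding_position", p3_ts, p3_tv),
    ])
    pair_table = None
    if calls is not None:
        counts = Counter()
        for call in calls:
            if call.pair_class is None:
                raise ValueError("calls must be annotated before summarizing")
            counts[call.pair_class] += 1
        total = sum(counts.values())
        pair_table = pd.DataFrame([
            {"pair_class": pc, "count": n,
             "pct_of_total": trunc1(100 * n / total)}
            for pc, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ])
    return table, pair_table


def degenerate_consensus(consensus: str, calls: list[SnpCall]) -> str:
    """Consensus with IUPAC degenerate codes at called positions."""
    out = list(consensus)
    for call in calls:
        pair = frozenset((call.major_allele, call.minor_allele))
        out[call.position] = IUPAC[pair]
    return "".join(out)


def summaries_to_frame(summaries: list[GeneSnpSummary]) -> pd.DataFrame:
    """Gene summary table with per-gene bp/SNP (round-half-even, 1 decimal)."""
    rows = []
    for s in summaries:
        rows.append({
            "gene_id": s.gene_id, "cds_len": s.cds_len,
            "ts_1": s.ts_by_pos[0], "ts_2": s.ts_by_pos[1],
            "ts_3": s.ts_by_pos[2], "ts_total": s.ts_total,
            "tv_1": s.tv_by_pos[0], "tv_2": s.tv_by_pos[1],
            "tv_3": s.tv_by_pos[2], "tv_total": s.tv_total,
            "syn": s.syn_count, "rep": s.rep_count,
            "coding_total": s.coding_total,
            "utr3_len": s.utr3_len, "utr3_ts": s.utr3_ts,
            "utr3_tv": s.utr3_tv, "utr3_total": s.utr3_total,
            "bp_per_snp": round1(s.bp_per_snp) if s.bp_per_snp is not None
                          else float("nan"),
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[SnpCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def write_vcf(calls: list[SnpCall], path, contig_lengths=None) -> None:
    """Minimal VCF export (CHROM, 1-based POS, REF=major, ALT=minor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pyroest\n")
        for cid, ln in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={cid},length={ln}>\n")
        fh.write("##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Depth\">\n")
        fh.write("##INFO=<ID=MC,Number=1,Type=Integer,"
                 "Description=\"Minor allele count\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"DP={c.depth};MC={c.minor_count}"
            if c.substitution_class:
                info += f";CLASS={c.substitution_class}"
            if c.codon_position:
                info += f";CODON_POS={c.codon_position}"
            if c.effect:
                info += f";EFFECT={c.effect}"
            fh.write(f"{c.contig_id}\t{c.position + 1}\t.\t{c.major_allele}"
                     f"\t{c.minor_allele}\t.\tPASS\t{info}\n")
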