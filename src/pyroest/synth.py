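"""Synthetic two-strain 454-style EST data with planted truth.

Everything downstream (trimming, pileups, SNP calling, differential
representation, GO path counting) is exercised on data from this module, so
each generator records a truth table alongside its output.

The generator emulates SMART cDNA 454 reads from a two-strain experiment:
transcripts with a short 5' leader, a CDS (no internal stop codons) and a
3'UTR; strain haplotypes differing by planted substitutions with a controlled
transition fraction and third-codon-position bias; reads decorated with the
SMART PCR adapter and poly-T/poly-A tails, with optional per-base substitution
errors and homopolymer-length indels (454's characteristic error mode).

Default conditions mirror the study this pipeline targets: 182 bp mean read
length, the 23-mer SMART adapter, ~1 substitution per 70 bp of CDS and per
49 bp of 3'UTR, 62% transitions, 64% of coding substitutions at the third
codon position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .trim import SMART_ADAPTER

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
# default planted-variant conditions (study values)
DEFAULT_RATE_CDS = 1 / 70
DEFAULT_RATE_UTR = 1 / 49
DEFAULT_TS_FRACTION = 0.62
DEFAULT_POS3_FRACTION = 0.64


@dataclass
class TranscriptModel:
    """A transcript with CDS (0-based half-open, frame offset) and 3'UTR."""

    transcript_id: str
    sequence: str
    cds: tuple[int, int]
    utr3: tuple[int, int]
    frame: int = 0
    go_terms: list[str] = field(default_factory=list)

    def validate(self) -> None:
        cs, ce = self.cds
        us, ue = self.utr3
        if not (0 <= cs <= ce <= len(self.sequence)):
            raise ValueError("CDS outside sequence")
        if not (0 <= us <= ue <= len(self.sequence)):
            raise ValueError("3'UTR outside sequence")
        if (ce - cs) % 3:
            raise ValueError("CDS length not a multiple of 3")
        if us != ce:
            raise ValueError("3'UTR must start at CDS end")


@dataclass(frozen=True)
class PlantedVariant:
    """Truth record for one planted substitution."""

    transcript_id: str
    position: int
    ref_allele: str
    alt_allele: str
    strain_of_alt: str            # strain label or "shared"
    truth_class: str              # transition | transversion
    truth_codon_pos: int | None   # 1|2|3, None for UTR3
    truth_region: str             # CDS | UTR3


@dataclass
class AbundanceTable:
    """Per-transcript sampling weights for the two strains, normalized."""

    weights: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        tot_r = sum(w[0] for w in self.weights.values())
        tot_s = sum(w[1] for w in self.weights.values())
        if tot_r <= 0 or tot_s <= 0:
            raise ValueError("all-zero abundance in a strain")
        self.weights = {
            t: (wr / tot_r, ws / tot_s) for t, (wr, ws) in self.weights.items()
        }

    @classmethod
    def random(
        cls,
        transcripts: list[TranscriptModel],
        n_exclusive_r: int = 2,
        n_exclusive_s: int = 2,
        alpha: float = 1.0,
        seed: int = 0,
    ) -> "AbundanceTable":
        """Dirichlet weights with some transcripts exclusive to one strain."""
        rng = np.random.default_rng(seed)
        ids = [t.transcript_id for t in transcripts]
        if n_exclusive_r + n_exclusive_s >= len(ids):
            raise ValueError("too many exclusive transcripts")
        pick = rng.permutation(len(ids))
        excl_r = {ids[i] for i in pick[:n_exclusive_r]}
        excl_s = {ids[i] for i in pick[n_exclusive_r:n_exclusive_r + n_exclusive_s]}
        wr = rng.dirichlet([alpha] * len(ids))
        ws = rng.dirichlet([alpha] * len(ids))
        # exclusive transcripts emulate strongly differentially represented
        # contigs (hundreds of reads in one library, zero in the other), so
        # they get at least an average-sized weight in their own strain
        floor = 1.0 / len(ids)
        weights = {}
        for i, tid in enumerate(ids):
            r = 0.0 if tid in excl_s else float(wr[i])
            s = 0.0 if tid in excl_r else float(ws[i])
            if tid in excl_r:
                r = max(r, floor)
            if tid in excl_s:
                s = max(s, floor)
            weights[tid] = (r, s)
        return cls(weights)

    def exclusive_to(self, strain_index: int) -> set[str]:
        """Transcripts with weight > 0 only in the given strain (0=R, 1=S)."""
        other = 1 - strain_index
        return {
            t for t, w in self.weights.items()
            if w[strain_index] > 0 and w[other] == 0
        }


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    strand: str
    strain: str
    adapter_prefix: int = 0
    polyt_prefix: int = 0
    polya_suffix: int = 0
    adapter_suffix: int = 0
    error_positions: tuple[int, ...] = ()

    @property
    def prefix_len(self) -> int:
        return self.adapter_prefix + self.polyt_prefix

    @property
    def suffix_len(self) -> int:
        return self.polya_suffix + self.adapter_suffix


def _random_seq(
    rng: np.random.Generator, n: int, max_run: int = 5, prev: str = ""
) -> str:
    """Random nucleotides with homopolymer runs capped at max_run.

    ``prev`` is the already-generated context immediately upstream, so runs
    never exceed the cap across segment boundaries.
    """
    out: list[str] = []
    last = prev[-1] if prev else ""
    run = 0
    if last:
        run = 1
        for ch in reversed(prev[:-1]):
            if ch != last:
                break
            run += 1
    for _ in range(n):
        choices = BASES
        if run >= max_run and last:
            choices = BASES.replace(last, "")
        b = choices[rng.integers(len(choices))]
        run = run + 1 if b == last else 1
        last = b
        out.append(b)
    return "".join(out)


def _cap_runs(codon: str, prev: str, max_run: int = 5) -> bool:
    """True if appending codon to prev keeps homopolymer runs <= max_run."""
    s = prev[-(max_run):] + codon
    run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


_SENSE_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
]


def generate_transcriptome(
    n_genes: int,
    cds_len_range: tuple[int, int] = (300, 900),
    utr_len_range: tuple[int, int] = (50, 300),
    seed: int = 0,
    leader_len_range: tuple[int, int] = (0, 30),
) -> list[TranscriptModel]:
    """Random transcripts: leader + ATG...stop CDS + 3'UTR.

    CDS lengths are multiples of 3 within the requested range; the reading
    frame contains no internal stop codon and ends with TAA.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (cds_len_range, utr_len_range):
        if lo <= 0 or hi < lo:
            raise ValueError("length ranges must be positive with lo <= hi")
    if cds_len_range[1] // 3 * 3 < max(cds_len_range[0], 9):
        raise ValueError("cds_len_range admits no multiple of 3 >= 9")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_genes):
        lo_k = max((cds_len_range[0] + 2) // 3, 3)
        hi_k = cds_len_range[1] // 3
        n_codons = int(rng.integers(lo_k, hi_k + 1))
        leader = _random_seq(rng, int(rng.integers(leader_len_range[0],
                                                   leader_len_range[1] + 1)),
                             max_run=4)
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
            if _cap_runs(c, "".join(codons[-2:])):
                codons.append(c)
        codons.append("TAA")
        cds = "".join(codons)
        utr = _random_seq(rng, int(rng.integers(utr_len_range[0],
                                                utr_len_range[1] + 1)),
                          prev=cds)
        seq = leader + cds + utr
        t = TranscriptModel(
            transcript_id=f"T{i:04d}",
            sequence=seq,
            cds=(len(leader), len(leader) + len(cds)),
            utr3=(len(leader) + len(cds), len(seq)),
        )
        t.validate()
        out.append(t)
    return out


def plant_variants(
    transcripts: list[TranscriptModel],
    rate_cds: float = DEFAULT_RATE_CDS,
    rate_utr: float = DEFAULT_RATE_UTR,
    ts_fraction: float = DEFAULT_TS_FRACTION,
    pos3_fraction: float = DEFAULT_POS3_FRACTION,
    seed: int = 0,
    strains: tuple[str, str] = ("R", "S"),
    p_shared: float = 0.0,
) -> list[PlantedVariant]:
    """Plant biallelic substitutions with controlled class fractions.

    Within the CDS the per-position rate is skewed so that the expected share
    of third-codon-position variants is pos3_fraction while the overall CDS
    density stays rate_cds; the alternate allele is the transition partner
    with probability ts_fraction, else one of the two transversions.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    if not (0 <= ts_fraction <= 1 and 0 <= pos3_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if rate_cds < 0 or rate_utr < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    p3 = 3 * rate_cds * pos3_fraction
    p12 = 3 * rate_cds * (1 - pos3_fraction) / 2
    if max(p3, p12) > 1:
        raise ValueError("rate_cds too high for the requested pos3_fraction")
    out = []
    for t in transcripts:
        cs, ce = t.cds
        us, ue = t.utr3
        for pos in range(cs, ue):
            if pos < ce:
                cp = (pos - cs - t.frame) % 3 + 1
                p = p3 if cp == 3 else p12
                region = "CDS"
            else:
                cp = None
                p = rate_utr
                region = "UTR3"
            if rng.random() >= p:
                continue
            ref = t.sequence[pos]
            if rng.random() < ts_fraction:
                alt = TRANSITION[ref]
                klass = "transition"
            else:
                tv = [b for b in BASES if b != ref and b != TRANSITION[ref]]
                alt = tv[rng.integers(2)]
                klass = "transversion"
            if p_shared and rng.random() < p_shared:
                strain = "shared"
            else:
                strain = strains[rng.integers(2)]
            out.append(PlantedVariant(
                transcript_id=t.transcript_id, position=pos,
                ref_allele=ref, alt_allele=alt, strain_of_alt=strain,
                truth_class=klass, truth_codon_pos=cp, truth_region=region,
            ))
    return out


def apply_haplotype(
    transcript: TranscriptModel, variants: list[PlantedVariant], strain: str
) -> str:
    """Transcript sequence carrying the alt alleles of one strain (+ shared)."""
    seq = list(transcript.sequence)
    for v in variants:
        if v.transcript_id != transcript.transcript_id:
            continue
        if v.strain_of_alt in (strain, "shared"):
            if seq[v.position] != v.ref_allele:
                raise ValueError("variant/reference mismatch")
            seq[v.position] = v.alt_allele
    return "".join(seq)


DEFAULT_DECORATION_PROBS = {
    "adapter_prefix": 0.4,
    "polyt_prefix": 0.3,
    "polya_suffix": 0.3,
    "adapter_suffix": 0.4,
}


def simulate_reads(
    transcripts: list[TranscriptModel],
    abundances: AbundanceTable,
    n_reads_per_strain: int = 1000,
    read_len_mean: int = 182,
    read_len_sd: float | None = None,
    adapter: str = SMART_ADAPTER,
    decoration_probs: dict[str, float] | None = None,
    error_rate: float = 0.0,
    homopolymer_indel_rate: float = 0.0,
    variants: list[PlantedVariant] | None = None,
    seed: int = 0,
    strains: tuple[str, str] = ("R", "S"),
) -> tuple[list[SeqRecord], list[ReadTruth]]:
    """Simulate strain-tagged 454-style reads from strain haplotypes.

    Read layout: [adapter][poly-T][insert][poly-A][adapter-revcomp], each
    decoration present with its probability.  The insert is a uniformly placed
    window of the strain haplotype, reverse-complemented for '-' strand reads.
    Substitution errors are applied across the whole read; homopolymer
    +/-1 indels (rate per homopolymer run) only when enabled.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    probs = dict(DEFAULT_DECORATION_PROBS if decoration_probs is None
                 else decoration_probs)
    missing = set(abundances.weights) ^ {t.transcript_id for t in transcripts}
    if missing:
        raise ValueError(f"abundances do not cover transcripts: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    sd = read_len_sd if read_len_sd is not None else 0.25 * read_len_mean
    by_id = {t.transcript_id: t for t in transcripts}
    ids = sorted(by_id)
    variants = variants or []
    haplos = {
        (tid, strain): apply_haplotype(by_id[tid], variants, strain)
        for tid in ids for strain in strains
    }
    reads: list[SeqRecord] = []
    truths: list[ReadTruth] = []
    for si, strain in enumerate(strains):
        w = np.array([abundances.weights[tid][si] for tid in ids])
        if w.sum() <= 0:
            raise ValueError(f"all-zero abundance for strain {strain!r}")
        w = w / w.sum()
        picks = rng.choice(len(ids), size=n_reads_per_strain, p=w)
        for i, ti in enumerate(picks):
            tid = ids[ti]
            hap = haplos[(tid, strain)]
            rl = int(np.clip(round(rng.normal(read_len_mean, sd)),
                             30, len(hap)))
            ap = len(adapter) if rng.random() < probs.get("adapter_prefix", 0) else 0
            tp = int(rng.integers(8, 21)) if rng.random() < probs.get("polyt_prefix", 0) else 0
            pa = int(rng.integers(8, 21)) if rng.random() < probs.get("polya_suffix", 0) else 0
            asfx = len(adapter) if rng.random() < probs.get("adapter_suffix", 0) else 0
            # keep tail decorations separable from the insert: an insert that
            # itself starts with T (or ends with A) would merge with the
            # appended tail and make the decoration boundary ambiguous
            for _ in range(50):
                start = int(rng.integers(0, len(hap) - rl + 1))
                end = start + rl
                strand = "+" if rng.random() < 0.5 else "-"
                insert = hap[start:end] if strand == "+" else revcomp(hap[start:end])
                ok5 = tp == 0 or (insert[0] != "T" and
                                  (len(insert) < 2 or insert[1] != "T"))
                ok3 = pa == 0 or (insert[-1] != "A" and
                                  (len(insert) < 2 or insert[-2] != "A"))
                if ok5 and ok3:
                    break
            else:
                tp = pa = 0  # give up on tails for this pathological window
            seq = (adapter[:ap] if ap else "") + "T" * tp + insert + \
                  "A" * pa + (revcomp(adapter)[:asfx] if asfx else "")
            err_pos: list[int] = []
            if error_rate > 0:
                n_err = rng.binomial(len(seq), error_rate)
                if n_err:
                    positions = rng.choice(len(seq), size=n_err, replace=False)
                    s = list(seq)
                    for p in sorted(int(x) for x in positions):
                        s[p] = BASES.replace(s[p].upper(), "")[rng.integers(3)]
                        err_pos.append(p)
                    seq = "".join(s)
            if homopolymer_indel_rate > 0:
                seq = _homopolymer_noise(seq, homopolymer_indel_rate, rng)
            rid = f"{strain}{i:06d}|strain={strain}"
            reads.append(SeqRecord(Seq(seq), id=rid, description=""))
            truths.append(ReadTruth(
                read_id=rid, transcript_id=tid, start=start, end=end,
                strand=strand, strain=strain, adapter_prefix=ap,
                polyt_prefix=tp, polya_suffix=pa, adapter_suffix=asfx,
                error_positions=tuple(err_pos),
            ))
    return reads, truths


def _homopolymer_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    """+/-1 base length errors on homopolymer runs of length >= 2."""
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 2 and rng.random() < rate:
            run = run[:-1] if rng.random() < 0.5 else run + run[0]
        out.append(run)
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# toy GO DAG


def make_toy_godag(
    depth: int = 3,
    branching: int = 3,
    seed: int = 0,
    n_cross: int = 0,
    n_queries: int = 0,
    namespace: str = "biological_process",
    include_obsolete: bool = False,
) -> tuple[str, str]:
    """OBO text for a toy is_a DAG plus a query->term assignment TSV.

    Level-0 is the single namespace root; level d holds branching**d terms,
    each is_a one term of level d-1.  n_cross extra is_a edges point from a
    random deep term to a random strictly shallower non-parent term, so the
    graph stays acyclic but gains multi-parent terms.  Queries are assigned
    uniformly to deepest-level terms.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    root = "GO:0008150"
    levels: list[list[str]] = [[root]]
    names = {root: namespace}
    parents: dict[str, set[str]] = {root: set()}
    counter = 1
    for d in range(1, depth + 1):
        level = []
        for i in range(branching ** d):
            tid = f"GO:{counter:07d}"
            counter += 1
            names[tid] = f"term_d{d}_{i}"
            parents[tid] = {levels[d - 1][i // branching]}
            level.append(tid)
        levels.append(level)
    added = 0
    attempts = 0
    while added < n_cross and attempts < 100 * max(1, n_cross):
        attempts += 1
        d = int(rng.integers(2, depth + 1)) if depth >= 2 else 1
        child = levels[d][rng.integers(len(levels[d]))]
        pd = int(rng.integers(0, d))
        parent = levels[pd][rng.integers(len(levels[pd]))]
        if parent not in parents[child]:
            parents[child].add(parent)
            added += 1
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for level in levels:
        for tid in level:
            lines += [f"[Term]", f"id: {tid}", f"name: {names[tid]}",
                      f"namespace: {namespace}"]
            for p in sorted(parents[tid]):
                lines.append(f"is_a: {p} ! {names[p]}")
            lines.append("")
    if include_obsolete:
        lines += ["[Term]", "id: GO:9999999", "name: gone",
                  f"namespace: {namespace}", "is_obsolete: true", ""]
    obo_text = "\n".join(lines)
    leaf_terms = levels[-1]
    rows = []
    for q in range(n_queries):
        rows.append(f"Q{q:05d}\t{leaf_terms[rng.integers(len(leaf_terms))]}")
    assignments_tsv = "\n".join(rows) + ("\n" if rows else "")
    return obo_text, assignments_tsv


# ---------------------------------------------------------------------------
# truth-table serialization (TSV)


def variants_to_frame(variants: list[PlantedVariant]) -> pd.DataFrame:
    return pd.DataFrame([vars(v) for v in variants])


def truths_to_frame(truths: list[ReadTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        d = {k: v for k, v in vars(t).items() if k != "error_positions"}
        d["error_positions"] = ",".join(map(str, t.error_positions))
        rows.append(d)
    return pd.DataFrame(rows)


def transcripts_to_annotation(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    """Annotation table (0-based half-open intervals), one row per transcript."""
    return pd.DataFrame([
        {
            "contig_id": t.transcript_id,
            "cds_start": t.cds[0], "cds_end": t.cds[1], "frame": t.frame,
            "utr3_start": t.utr3[0], "utr3_end": t.utr3[1],
        }
        for t in transcripts
    ])
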