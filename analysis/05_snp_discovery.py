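#!/usr/bin/env python
"""Call SNPs from the truth pileups with the two-reads/five-reads rule,
classify them, summarize per gene and per DNA class, and compare against the
planted truth."""

from pathlib import Path

from pyroest import synth
from pyroest.assembly import build_truth_pileup
from pyroest.snps import (GeneAnnotation, annotate_call, call_snps,
                          calls_to_frame, degenerate_consensus, pileup,
                          summaries_to_frame, summarize_classes,
                          summarize_gene, write_vcf)

SEED = 7
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    transcripts = synth.generate_transcriptome(20, seed=SEED)
    variants = synth.plant_variants(transcripts, seed=SEED + 1)
    abundances = synth.AbundanceTable.random(transcripts, 2, 2, seed=SEED + 2)
    reads, truths = synth.simulate_reads(
        transcripts, abundances, n_reads_per_strain=4000,
        variants=variants, seed=SEED + 3)
    asm = build_truth_pileup(reads, truths, transcripts)

    all_calls, summaries = [], []
    fasta_lines = []
    for t in transcripts:
        if t.transcript_id not in asm.contigs:
            continue
        ann = GeneAnnotation(t.transcript_id, t.transcript_id, t.sequence,
                             t.cds, utr3=t.utr3)
        calls = [annotate_call(c, ann)
                 for c in call_snps(pileup(asm, t.transcript_id))]
        all_calls += calls
        summaries.append(summarize_gene(calls, ann))
        degen = degenerate_consensus(t.sequence, calls)
        fasta_lines.append(f">{t.transcript_id}\n{degen}\n")

    calls_to_frame(all_calls).to_csv(BASE / "snp_calls.tsv", sep="\t",
                                     index=False)
    write_vcf(all_calls, BASE / "snp_calls.vcf",
              {t.transcript_id: len(t.sequence) for t in transcripts})
    (BASE / "degenerate_consensus.fasta").write_text("".join(fasta_lines))
    summaries_to_frame(summaries).to_csv(BASE / "gene_summaries.tsv",
                                         sep="\t", index=False)
    class_table, pair_table = summarize_classes(summaries, all_calls)
    class_table.to_csv(BASE / "dna_class_table.tsv", sep="\t", index=False)
    pair_table.to_csv(BASE / "pair_class_table.tsv", sep="\t", index=False)

    planted = {(v.transcript_id, v.position) for v in variants
               if v.strain_of_alt != "shared"}
    called = {(c.contig_id, c.position) for c in all_calls}
    print(f"{len(all_calls)} SNPs called; {len(planted)} strain variants "
          f"planted; {len(called - planted)} called at unplanted sites")
    print(class_table.to_string(index=False))
    n_ts = sum(c.substitution_class == "transition" for c in all_calls)
    print(f"transition share of calls: {100 * n_ts / len(all_calls):.1f}% "
          f"(planted {100 * synth.DEFAULT_TS_FRACTION:.0f}%)")


if __name__ == "__main__":
    main()
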