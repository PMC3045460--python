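#!/usr/bin/env python
"""Generate the synthetic two-strain 454 EST data set used by the later steps.

Writes a strain-tagged read FASTA plus full truth tables (planted variants,
read provenance, CDS/3'UTR annotation) under results/synthetic/.  All later
analysis steps regenerate the same data from the same seed, so this script is
illustrative as well as functional.
"""

from pathlib import Path

from Bio import SeqIO

from pyroest import synth

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    transcripts = synth.generate_transcriptome(20, seed=SEED)
    variants = synth.plant_variants(transcripts, seed=SEED + 1)
    abundances = synth.AbundanceTable.random(
        transcripts, n_exclusive_r=2, n_exclusive_s=2, seed=SEED + 2)
    reads, truths = synth.simulate_reads(
        transcripts, abundances, n_reads_per_strain=4000,
        variants=variants, seed=SEED + 3)

    SeqIO.write(reads, OUT / "reads.fasta", "fasta")
    synth.variants_to_frame(variants).to_csv(
        OUT / "planted_variants.tsv", sep="\t", index=False)
    synth.truths_to_frame(truths).to_csv(
        OUT / "read_truth.tsv", sep="\t", index=False)
    synth.transcripts_to_annotation(transcripts).to_csv(
        OUT / "annotation.tsv", sep="\t", index=False)
    with open(OUT / "transcripts.fasta", "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n{t.sequence}\n")

    n_cds = sum(1 for v in variants if v.truth_region == "CDS")
    print(f"wrote {len(reads)} reads from {len(transcripts)} transcripts")
    print(f"planted {len(variants)} variants ({n_cds} coding), "
          f"{len(abundances.exclusive_to(0))} R-exclusive and "
          f"{len(abundances.exclusive_to(1))} S-exclusive transcripts")


if __name__ == "__main__":
    main()
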