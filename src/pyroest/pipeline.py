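"""One-call synthetic end-to-end pipeline: simulate -> trim -> assemble (truth)
-> assembly stats -> differential representation -> SNP discovery -> GO paths.

The configuration is a flat key/value mapping (readable from a YAML-ish
"key: value" text file); every run writes an effective-config file carrying
the seed and a config hash, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import assembly as asm
from . import diffrepr, gopaths, snps, synth
from .snps import GeneAnnotation
from .trim import SMART_ADAPTER, TrimSpec, trim_batch


@dataclass
class PipelineConfig:
    seed: int = 7
    n_genes: int = 20
    n_reads_per_strain: int = 4000
    read_len_mean: int = 182
    adapter: str = SMART_ADAPTER
    error_rate: float = 0.0
    min_length: int = 30
    min_depth: int = 5
    min_minor: int = 2
    rate_cds: float = synth.DEFAULT_RATE_CDS
    rate_utr: float = synth.DEFAULT_RATE_UTR
    ts_fraction: float = synth.DEFAULT_TS_FRACTION
    pos3_fraction: float = synth.DEFAULT_POS3_FRACTION
    n_exclusive_r: int = 2
    n_exclusive_s: int = 2
    go_depth: int = 3
    go_branching: int = 3
    go_queries: int = 200
    top_n: int = 20

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages on synthetic data; returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.min_depth < 1 or config.min_minor < 1:
        raise ValueError("calling thresholds must be positive")
    seed = config.seed

    # stage 1: synthetic data
    transcripts = synth.generate_transcriptome(config.n_genes, seed=seed)
    variants = synth.plant_variants(
        transcripts, rate_cds=config.rate_cds, rate_utr=config.rate_utr,
        ts_fraction=config.ts_fraction, pos3_fraction=config.pos3_fraction,
        seed=seed + 1)
    abundances = synth.AbundanceTable.random(
        transcripts, n_exclusive_r=config.n_exclusive_r,
        n_exclusive_s=config.n_exclusive_s, seed=seed + 2)
    reads, truths = synth.simulate_reads(
        transcripts, abundances, n_reads_per_strain=config.n_reads_per_strain,
        read_len_mean=config.read_len_mean, adapter=config.adapter,
        error_rate=config.error_rate, variants=variants, seed=seed + 3)
    SeqIO.write(reads, out / "reads.fasta", "fasta")
    synth.variants_to_frame(variants).to_csv(
        out / "planted_variants.tsv", sep="\t", index=False)
    synth.truths_to_frame(truths).to_csv(
        out / "read_truth.tsv", sep="\t", index=False)
    synth.transcripts_to_annotation(transcripts).to_csv(
        out / "annotation.tsv", sep="\t", index=False)

    # stage 2: trimming
    spec = TrimSpec(adapter=config.adapter, min_length=config.min_length)
    trimmed, trim_summary = trim_batch(
        [(r.id, str(r.seq)) for r in reads], spec,
        thresholds=[config.min_length, 40, 50])
    trim_summary.to_csv(out / "trim_report.tsv", sep="\t", index=False)

    # stage 3: truth assembly + stats
    assembly = asm.build_truth_pileup(reads, truths, transcripts)
    asm.write_ace(assembly, out / "assembly.ace")
    stats = asm.assembly_stats(assembly)
    with open(out / "assembly_stats.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_contigs\t{stats.n_contigs}\n")
        fh.write(f"n_reads_used\t{stats.n_reads_used}\n")
        fh.write(f"mean_depth\t{stats.mean_depth}\n")

    # stage 4: differential representation
    counts = diffrepr.count_by_strain(assembly)
    counts = diffrepr.normalize(
        counts,
        r_total=sum(1 for t in truths if t.strain == "R"),
        s_total=sum(1 for t in truths if t.strain == "S"))
    diffrepr.rank_table(counts, "R", config.top_n).to_csv(
        out / "diff_top_resistant.tsv", sep="\t", index=False)
    diffrepr.rank_table(counts, "S", config.top_n).to_csv(
        out / "diff_top_susceptible.tsv", sep="\t", index=False)

    # stage 5: SNP discovery
    all_calls = []
    summaries = []
    for t in transcripts:
        if t.transcript_id not in assembly.contigs:
            continue
        ann = GeneAnnotation(
            gene_id=t.transcript_id, contig_id=t.transcript_id,
            sequence=t.sequence, cds=t.cds, frame=t.frame, utr3=t.utr3)
        columns = snps.pileup(assembly, t.transcript_id)
        calls = [snps.annotate_call(c, ann)
                 for c in snps.call_snps(columns, config.min_depth,
                                         config.min_minor)]
        all_calls.extend(calls)
        summaries.append(snps.summarize_gene(calls, ann))
    snps.calls_to_frame(all_calls).to_csv(
        out / "snp_calls.tsv", sep="\t", index=False)
    snps.write_vcf(all_calls, out / "snp_calls.vcf",
                   {t.transcript_id: len(t.sequence) for t in transcripts})
    snps.summaries_to_frame(summaries).to_csv(
        out / "gene_summaries.tsv", sep="\t", index=False)
    class_table, pair_table = snps.summarize_classes(summaries, all_calls)
    class_table.to_csv(out / "dna_class_table.tsv", sep="\t", index=False)
    if pair_table is not None:
        pair_table.to_csv(out / "pair_class_table.tsv", sep="\t", index=False)

    # stage 6: GO paths on a toy DAG
    obo_text, assign_tsv = synth.make_toy_godag(
        depth=config.go_depth, branching=config.go_branching,
        seed=seed + 4, n_cross=2, n_queries=config.go_queries)
    (out / "toy.obo").write_text(obo_text)
    (out / "go_assignments.tsv").write_text(assign_tsv)
    dag = gopaths.load_obo_text(obo_text)
    root = next(iter(dag.roots))
    assignments = [tuple(line.split("\t"))
                   for line in assign_tsv.splitlines() if line]
    usage = gopaths.count_usage(dag, assignments, root)
    gopaths.terms_at_depth(dag, usage, 1, root).to_csv(
        out / "go_depth1.tsv", sep="\t", index=False)

    # provenance
    effective = asdict(config)
    effective["config_hash"] = config.config_hash()
    (out / "effective_config.yaml").write_text(
        yaml.safe_dump(effective, sort_keys=True))
    return out
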