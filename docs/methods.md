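# Methods

This note records the models, conventions and design choices behind
`pyroest`, in the order the pipeline runs them.

## Read trimming

SMART cDNA 454 reads carry the PCR adapter
`AAGCAGTGGTATCAACGCAGAGT` and oligo-dT-derived poly-T/poly-A tails. The
trimmer removes adapters first (they physically flank the tails in SMART
cDNA, so removing them exposes the tails), then tails on the adapter-free
core.

**Adapter rule.** At each read end, the longest substring of the adapter or
its reverse complement of length ≥ `min_adapter_match` (default 8 bp) that
aligns flush against the read end with mismatch fraction ≤
`max_adapter_error` (default 0.20) is removed; at most one removal per end.
Mismatch counting is ungapped — substitutions only, the minimal reading of
"error tolerant". The 8 bp minimum exists because the 20% tolerance would
otherwise accept meaningless 1–2 bp "matches". "Complement" is interpreted
as reverse complement, since cDNA reads come from either strand.

**Tail rule.** A run of ≥ `t_run` (default 6) consecutive T's whose first
base lies within `search_window` (default 50 bp) of the read start seeds an
expansion: the run extends rightwards through any number of gaps of exactly
one non-T base, each gap followed by at least one T; two consecutive non-T
bases terminate it. The read is trimmed from position 0 to the end of the
largest expansion (ties resolved to the right-most end, maximizing trimmed
length). Poly-A uses the mirror-image rule at the 3' end, implemented
exactly as `len(read) − polyT(reverse_complement(read))`. The window is
applied to the *start* of the seed run. Reads shorter than `min_length`
(default 30 bp) after trimming fail the length filter.

## Assembly model and statistics

Contigs hold a padded consensus (`*` pads, IUPAC codes allowed) and read
placements in 0-based half-open padded coordinates; ACE files (1-based) are
converted at the boundary. ACE parsing is delegated to Biopython's ACE
reader; the writer is ours and round-trips through it. Strain labels travel
in read names as a `|strain=X` token; reads without one count as `unknown`
with a warning.

**Depth** is reads-per-contig (total placements / contig count, one
decimal), the definition used for 454 EST assemblies; per-column coverage is
exposed separately (`column_depths`, and a 100-bin relative-position depth
profile). Contig lengths are histogrammed in 10 bp bins.

**Redundancy scan.** The published analysis screened contigs against
themselves with BLAST at E = 1 and counted subjects fully contained in a
query. Our desk-scale stand-in finds every subject that aligns *ungapped*
over its full length inside a query at mismatch fraction ≤ 5% (default),
via 12-mer seeds sampled every k bases plus extension. Exact containments
are always found (every seed matches); the mismatch-fraction threshold is
the chosen proxy for the E-value cutoff, which has no direct analogue in a
containment matcher. It is an approximation, not a BLAST reimplementation.

**build_truth_pileup** produces the assembly the downstream stages consume
when running on synthetic data: one contig per transcript, consensus equal
to the reference transcript, each read's undecorated insert placed at its
true interval (reverse-complemented back for − strand reads). It requires
indel-free reads and raises otherwise.

## Differential representation

Per-contig strain counts are normalized to library totals (per-library read
proportions; the trimmed-read totals by default — the choice of raw vs
trimmed vs assembled totals is the caller's, since proportional scaling of
one library leaves no score unchanged otherwise). The score is
(r − s)/(r + s) on the normalized values, 0/0 defined as 0. Ranking sorts by
score in the requested direction, breaking ties by larger total raw count
and then contig id, so a 241-read exclusive contig outranks a 19-read one.
No significance test is attached — with pooled life stages and single
libraries per strain the score is a screening statistic, validated in the
original study by qPCR (out of scope here).

## SNP discovery

Calling uses the conservative two-of-five rule for EST data: a column is
polymorphic when pooled coverage ≥ 5 and the second-most-frequent allele is
seen ≥ 2 times. Reads are pooled across strains (the published 31,000-site
screen pooled both strains); per-strain tallies stay on every column.
Gap/pad columns and non-ACGT characters never enter the counts; indels are
not called. Tri-allelic columns are called on the top two alleles and
flagged. Allele ranking ties break alphabetically for determinism.

Classification: transitions are A↔G and C↔T; the six allele pairs map to
IUPAC codes R/Y/M/K/S/W. Codon position is
`((pos − cds_start − frame) mod 3) + 1` on the annotated strand (reverse
strand CDS are complemented before translation); effect is synonymous when
major- and minor-allele codons translate identically under the standard
code. Per-gene summaries cross-tabulate class × codon position and report
`bp_per_snp = cds_len / (coding + 3'UTR substitutions)` — the formula that
reproduces 18 of the 20 printed per-gene values in the reference survey.
The two exceptions (CTLMA1, Actin rows) are internally inconsistent in the
printed source (their printed totals disagree with their own printed
components) and are flagged in `refdata`, not matched; the printed grand
"average" of 55.2 bp/SNP matches no tested formula and is excluded.

Display conventions: per-gene bp/SNP cells round half-to-even to one
decimal; percentage columns (%Tv) and group-mean rows are floored to one
decimal. Both conventions follow the arithmetic of the published tables
they mirror.

## GO path counting

Only `is_a` edges are traversed (standard for namespace-rooted analyses);
the DAG is checked acyclic on load, and obsolete terms are dropped. A DAG
has no single leaf-to-root distance, so counting follows *all* distinct
simple paths from an assigned term to the root: for each assignment and
each path, every node on the path — term and root inclusive — is
incremented once per path. A hit at the root itself contributes one
zero-length path. Consequently the root's counter always equals the total
path count. Each GO assignment of a query contributes independently.
Depth-binned reports use the *minimum* root-ward distance of a term.
Absolute path totals of the original study (45,021 / 88,647) depend on its
BLAST assignments and are not reproduction targets.

## Conservation scoring

Pairwise global alignment is Needleman–Wunsch with affine gaps (Gotoh's
three-matrix recursion); a gap of length L scores
`gap_open + (L−1)·gap_extend`. Traceback ties prefer diagonal, then a gap
in the second sequence, so alignments are deterministic. The original study
used ClustalW and did not define "percent similarity"; our definition —
100 × columns whose residue pair has a positive substitution-matrix score
(identities included) / columns excluding gap–gap, BLOSUM62 by default,
rounded to integers for display — is stated explicitly so results are
reproducible, and the matrix and gap costs are configurable. ClustalW's own
percentages would differ slightly; the study's exact computation is
unrecoverable, so only the aggregation of its printed per-gene values is
reproduced (group means as arithmetic means, absent cells excluded).

## Synthetic data generator

The generator emulates the study conditions: mean read length 182 bp, the
23-mer SMART adapter, planted substitution densities of 1 per 70 bp of CDS
and 1 per 49 bp of 3'UTR, a transition fraction of 0.62 and a
third-codon-position share of 0.64 among coding substitutions (the ratios
of the published survey). Transcripts are a short random 5' leader, an
ATG…TAA CDS with no internal stop, and a 3'UTR. Variants are planted by
per-position Bernoulli draws whose rates are skewed across codon positions
to achieve the third-position share while preserving overall density; each
variant's alternate allele goes to one strain (or, optionally, both —
"shared" variants are invisible to between-strain pileups and default off).
Abundances are Dirichlet draws per strain with a configurable number of
strain-exclusive transcripts; exclusives get at least an average-sized
weight in their own strain, emulating the strongly expressed
differentially represented contigs of the real experiment.

Reads are `[adapter][poly-T][insert][poly-A][adapter-revcomp]` with each
decoration present at a configurable probability, the insert a uniformly
placed window of the strain haplotype on either strand. Error model:
independent per-base substitutions plus homopolymer-length ±1 indels
(454's characteristic mode), both default 0 so oracle tests are exact.

Two deliberate simplifications keep planted truth exactly recoverable and
are *not* features of real data: transcript bodies cap homopolymer runs at
5 bp (below the 6 bp tail seed), and insert windows are resampled so a
planted tail never abuts an insert that begins with T / ends with A within
2 bp of the junction. Real reads violate both, and on them the trimmer
would (correctly, per its rule) trim genuine sequence adjacent to tails;
passing the perfect-recovery tests therefore demonstrates the algorithms'
correctness on separable decorations, not immunity to genuinely ambiguous
tail boundaries. Quality scores, flowgrams/SFF and chimeric reads are not
simulated. The true divergence of the two real strains is unknown; the
default synthetic divergence is a free parameter, not a claim about
*An. funestus*.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to give
the statistical checks adequate power: 10,000 random reads for the
trimmer-vs-enumeration oracle; 12 transcripts × 2,000 fully decorated reads
for removal precision/recall; 60 genes × 8,000 reads (≈20× depth, ≈900
planted variants) for SNP recovery and class-fraction bands; 30 transcripts
× 20,000 reads for ranking recovery; 30 random toy DAGs of ≤ 12 terms for
path counting. Everything completes in well under a minute.
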