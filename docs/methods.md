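# Methods

## Setting and units of analysis

The pipeline targets *de novo* EST experiments: two tissues, one
sequencing library each, no reference genome, no replicates. Reads are
attached to assembled **contigs**; **isotigs** are isoform paths over
contigs; a **unigene** is the set of isotigs annotated by the same
reference protein, and is the unit of counting, testing and profiling.
Annotation is trusted only below an E-value of 10⁻²⁰, applied as a
strict inequality so boundary hits are reproducibly excluded. Best-hit
ties are broken by bitscore, then E-value, then protein id — a total
order, so assignment is invariant under permutation of the hit table.

## Counting and normalization

Because isoforms of a gene share contigs, summing isotig counts would
double-count shared contigs; the unigene count is therefore the sum of
reads over the set union of its isotigs' contigs. Library size N is
the total read count of the sample over *all* contigs, annotated or
not — the denominator a sequencing experiment actually produced. (The
alternative, counting only annotated contigs, would inflate RPKM as
annotation coverage drops; with the union rule and no cross-gene
sharing, per-unigene counts sum to at most N, with equality exactly
when every contig is annotated.) Feature length for RPKM is the
annotating protein length in nucleotides, L = 3 × aa (no stop codon),
since without a genome there are no exon models. RPKM = 10⁹·C/(N·L);
report tables scale it ×1000 with two decimals. If a contig is shared
across *different* unigenes (possible only with cross-gene sharing
enabled in the simulator), it counts once in each unigene and the
Σ C ≤ N bound is logged as relaxed.

## The no-replicate exact test

Counts are modelled as Y_i ~ NB(μ_i = M_i·p_i, Φ) with variance
μ + Φμ²; Φ = 0 is the Poisson case. With a single library per
condition the dispersion cannot be estimated from the data, so Φ is an
explicit, fixed common dispersion. Default Φ = 0.1 — a typical
between-library biological CV² for bulk tissue — and every result
table records the value used. The test conditions on n = y₁ + y₂:
with pooled abundance p̂ = n/(M₁+M₂), the conditional probability of
Y₁ = k is f(k; M₁p̂, Φ)·f(n−k; M₂p̂, Φ) normalized over k = 0…n, and
the two-sided p-value is the minimum-likelihood sum — all outcomes
with conditional probability ≤ that of the observed split (with a
10⁻¹² relative tie tolerance against round-off). Doubling the smaller
tail is available behind a flag. Computation is in log space
(`logsumexp`); n = 0 returns p = 1 by convention.

At Φ = 0 the conditional law is exactly binomial(n, M₁/(M₁+M₂)); the
test suite checks agreement with an independent binomial enumeration to
10⁻¹² for all totals ≤ 50 at library ratios 1, 2 and 10. For Φ > 0 the
implementation was cross-checked against an independent Bioconductor
implementation of the same conditional NB test at fixed dispersion and
equal library sizes (agreement to 10 significant digits on spot cases);
the shipped tests use only the Python-side enumeration oracle. The
minimum-likelihood p-value is not globally monotone or smooth in Φ at
tie crossings; the suite asserts continuity on a sampled grid only.

Significance is raw p < α with α = 0.01 and **no multiple-testing
correction** — the historical criterion this pipeline reproduces. A
Benjamini–Hochberg column is emitted for reference but does not drive
the flag. Log₂ fold changes use a pseudocount of 0.5 on both counts
(after library-size normalization), keeping tissue-exclusive genes
finite for volcano displays.

## Cluster labels

NS if not significant; otherwise the side with the higher RPKM wins
(A = first sample), and a zero raw deduplicated count in the opposite
tissue makes the gene exclusive (A2/B2) rather than enriched (A1/B1).
"Exclusive" is defined on raw counts, not on RPKM below a threshold,
because published tables print an exact 0.00 for such genes. A
significant gene with identical RPKM on both sides is impossible under
the exact test and raises an error (data-corruption guard). The Venn
partition reports (A2, B2, A1+B1). TF families are assigned by a
priority-ordered, case-insensitive keyword lexicon over the annotation
description (20 families; editable TSV); keyword matching is a
documented stand-in for a curated TF classification, and rules with
duplicate priorities are rejected at load time to keep matching
unambiguous.

## GO-slim rollup and enzyme profiles

Ontologies are traversed over is_a and part_of edges only (acyclicity
is verified at load; which relations the original graph-database
tooling traversed is not documented anywhere, so this is our recorded
choice). A term rolls up to **all** reachable slim ancestors-or-self
by default; nearest-only (minimum edge distance) is available by flag,
since published slim profiles do not state which convention they used.
Term frequencies count each gene at most once per (slim) term per
namespace. Enzyme profiles join the DEGs' EC codes against a provided
(EC, pathway) table and count distinct ECs per pathway.

## The synthetic-data generator

The generator emulates the two-tissue, one-library-each 454 design:

- **Library sizes** default to 199 075 and 198 382 reads — the
  per-tissue totals of the motivating olive experiment.
- **Structure**: 1–3 isoforms per gene; each isoform has 1–4 contigs
  and reuses an existing contig of its gene with probability 0.5;
  contig lengths uniform on 200–800 nt (the motivating assembly
  averaged ~500 bases). Cross-gene contig sharing is off by default so
  unigene counts have a clean truth value.
- **Abundances**: log-normal baselines (σ = 1), a realistic dynamic
  range for bulk transcriptomes. DE fraction defaults to 0.57 and the
  exclusive share of DE genes to 0.7, the proportions observed in the
  motivating study; the symmetric effect is |log₂FC| = 2.
- **Balance by pairing**: DE genes are generated in up/down pairs that
  share a baseline, and exclusive genes in fruit/AZ-exclusive pairs,
  so both samples' abundance vectors sum to one *without*
  renormalization — null genes have a true logFC of exactly 0, and DE
  genes exactly ±the nominal effect. DE and exclusive counts are
  rounded down to even so pairs are complete.
- **Counts**: per gene and sample, one NB(M_i·p_gi, Φ) draw (Poisson at
  Φ = 0), multinomially split across the gene's contigs proportional to
  length. Every contig of a gene lies in some isotig, so the
  deduplicated unigene count reproduces the gene-level draw exactly and
  per-sample unigene totals equal the library totals.
- **Annotation**: every isotig receives one true hit to its gene's
  protein with E-value log-uniform on [10⁻¹⁸⁰, 10⁻³⁰] (below
  threshold); decoy hits (rate 0.3) land log-uniform on [10⁻¹⁸, 10⁻³]
  (above threshold) so filtering removes them. Catalog entries carry
  GO terms drawn from a generated three-namespace DAG (30 terms and 5
  slim terms per namespace), EC codes from the bundled pathway map
  (20% of genes), and TF-style descriptions for 5% of genes.
- **Determinism**: one child seed per gene (spawned from the master
  seed), so enlarging the gene panel never reshuffles earlier genes'
  structural or hit draws; index draws that depend on `n_genes` use a
  single uniform so stream consumption is bound-independent.

What the generator does **not** model: read sequences and their
homopolymer error structure, assembly artifacts (chimeras, fragmented
contigs), annotation errors below the E-value threshold, cross-gene
contig sharing (unless enabled), or correlated gene expression. Tests
passing on synthetic data therefore validate the *computational*
chain — counting, normalization, inference, classification,
profiling — not the upstream assembly/annotation biology.

## Validation design and measured scales

The suite validates each operation against an independent oracle:
brute-force union-then-sum for deduplicated counting (1,000 random
clusters), exact rational arithmetic for RPKM (10,000 random triples),
full binomial enumeration for the Φ = 0 exact test (all totals ≤ 50 ×
3 library ratios), a transitive-closure oracle for slim rollup (100
random DAGs ≤ 200 terms), brute tallies for every counting operation,
and a 10,000-gene null simulation for type-I error (the conditional
exact test rejects ~0.7% of null genes at α = 0.01 — conservative, as
expected). Parameter recovery uses 200-gene datasets (20% DE at
|log₂FC| = 2, Φ = 0.1) across library sizes 10³–10⁵. One measurement
note: the logFC *bias* of the caller is a property of the estimator,
but a single 200-gene dataset estimates it with a Monte-Carlo SD of
≈ √(2Φ)/ln2/√40 ≈ 0.1 — as large as the quantity's tolerance — so the
suite averages the bias over 10 replicate datasets at the same
conditions, putting the Monte-Carlo error (~0.03) well below the
bound; detection-rate and depth-monotonicity checks still use single
datasets. Problem sizes throughout were chosen so the full suite runs
in seconds while keeping Monte-Carlo error comfortably inside each
test's tolerance.

## Known limitations

- Fixed common dispersion instead of empirical-Bayes moderation: with
  one library per condition this is the honest option, but it makes
  significance calls depend on a user-chosen Φ; DEG counts are not
  comparable across Φ values.
- Raw-p thresholding (no FDR control) reproduces the historical
  criterion and inflates family-wise error on large panels; the BH
  column is provided for modern use.
- Protein-length RPKM mis-scales genes whose transcript length departs
  strongly from 3 × protein length (long UTRs, partial hits).
- Keyword TF classification is only as good as the lexicon; generic
  descriptions ("Transcription factor") match no family.
- The exact test conditions on totals and ignores any extra-Poisson
  variation *between* the two libraries beyond the assumed common Φ.
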