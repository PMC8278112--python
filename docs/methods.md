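# Methods

`txatlas` characterizes a multi-tissue transcriptome atlas from two inputs:
a GTF annotation (genes, transcripts, strand, biotype) and expression
matrices (transcript-level TPM and/or gene-level counts) with a
sample→tissue grouping. This note records the procedures, the conventions
they pin down, what the synthetic generator does and does not emulate, and
the design choices that were genuinely open.

## Expression calling

A feature (gene or transcript) is *expressed* in a tissue when the
arithmetic mean of its TPM over that tissue's replicates is **strictly
greater than 0.5**. The boundary matters for reproducibility: a replicate
average of exactly 0.5 is not expressed. Call sets are monotone in the
threshold by construction. When only transcript TPMs are available, a gene
is detected in a tissue iff at least one of its transcripts is; a
gene-level matrix, when supplied, takes precedence.

Detection percentages (detected/annotated genes, transcripts, per-biotype
shares) are computed from integer counts and rounded **half away from
zero** to one decimal. Python's built-in banker's rounding would differ on
.5 boundaries, so quantization uses `decimal`. Every reported percentage is
re-derivable from its stored integer numerator and denominator; this
identity is tested.

## Count normalization

Cross-sample comparability of counts uses the median-of-ratios size-factor
procedure: for each feature with strictly positive counts in every sample,
compute its geometric mean across samples; a sample's factor is the median
of its count/geometric-mean ratios over those features. Features containing
any zero are excluded (their geometric mean vanishes). If no feature is
all-positive the procedure raises — a pseudo-reference fallback is
deliberately out of scope.

One convention is added: factors are centered to **geometric mean 1**.
Raw median-of-ratios factors are only defined up to a global scale — 
re-estimating factors on an already-normalized matrix returns a constant
equal to the geometric mean of the original factors, not 1. Centering makes
the procedure exactly idempotent without changing any relative
normalization (and coincides with the uncentered result in the
single-feature and identical-column cases).

## Tissue specificity

Specificity is scored by Shannon entropy over the cross-tissue profile.
With tissue values `x_1..x_T`, `p_i = x_i / Σx` and
`H = −Σ_{p_i>0} p_i log2 p_i` (bits; `0·log 0 = 0`). The specificity score
is `log2(T) − H`, so a single-tissue feature scores `log2(T)` and a
uniformly expressed one scores 0. Base 2 is pinned for exact tests; the
ranking is base-invariant. Ordering by descending score equals ordering by
ascending entropy; ties break lexicographically by feature id so output is
platform-stable. Both "most specific" and "least specific" orderings are
exposed, since either tail is a meaningful report.

The preferred entropy input is replicate-averaged, size-factor-normalized
gene counts; TPM is accepted as an alternative input mode when counts are
unavailable. All-zero features are excluded before scoring (their entropy
is undefined).

Isoform-level specificity applies two filters before scoring: the isoform's
parent gene must be expressed in **at least two tissues** (an isoform of a
single-tissue gene is trivially "specific" through its gene, not through
isoform usage), and the isoform itself must pass the expression call in at
least one tissue.

## Opposite-strand pair geometry

All coordinates are GTF-native: 1-based, inclusive. The overlap substrate
is the **gene span** (TSS to TES, the union of the gene's transcripts or
the explicit gene line); exon/UTR-resolved overlap is out of scope. Two
relations are detected between genes on the same chromosome and opposite
strands:

* **antisense overlap** — spans overlap by `min(end) − max(start) + 1 ≥ 1`
  bp; the overlap length is recorded;
* **head-to-head (H2H)** — `|TSS_a − TSS_b| ≤ 1000` bp (inclusive bound),
  with the TSS at the span start for `+` genes and the span end for `−`
  genes. No divergent-orientation or biotype restriction is imposed beyond
  opposite strands and proximity; orientation-style filtering can be done
  downstream on the recorded distances.

The same unordered pair may hold both relations and is kept separately per
relation. Pairs are canonicalized (`gene_a < gene_b` lexicographically) and
results are sorted. Internally an interval tree (antisense) and a
sorted-TSS window search (H2H) are used; the contract — tested — is exact
equality with an exhaustive all-pairs scan. Note that antisense overlap is
invariant under reversing every gene's strand, but H2H distances are not:
flipping a strand moves the TSS to the opposite end of the span.

Pair biotype categories follow the census convention: PC–PC, PC–lncRNA,
lncRNA–lncRNA, and *other* whenever either member lies outside
{protein_coding, lncRNA}. Per (pair, tissue), the expression status is
exactly one of co-expressed (both members called), mono-expressed (exactly
one) or silent; a pair is unique to a tissue for a status iff it holds that
status in that tissue alone.

## Isoform statistics

Per (gene, tissue), the expressed-isoform count is the number of the gene's
transcripts passing the call. The per-tissue mean is taken **over genes
with at least one expressed isoform** — including fully silent genes in the
denominator would drag the statistic toward the detection rate rather than
isoform usage, and makes published per-gene averages of ~1.1–1.3
unreachable. Histograms bucket counts as 1, 2, 3 and 4+. "High-isoform"
genes are those with ≥ k (default 4) expressed isoforms in *every* tissue.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 10 tissue
groups, duplicate libraries, a single-chromosome annotation of 1000 genes
with the fifteen Ensembl biotypes in realistic proportions (69%
protein-coding, 23% lncRNA, ~3% miRNA, remainder spread thinly), and an
isoform-count distribution of P(1)=0.80, P(2)=0.15, P(3)=0.04, P(4+)=0.01.

Planted, truth-recorded structure:

* **antisense pairs** (default 10): convergent opposite-strand genes
  overlapping by a drawn 1–500 bp. Members are ≥ 1500 bp long, so their
  TSSs are always > 1 kb apart — a planted antisense pair can never double
  as H2H. (A divergent overlap would put both TSSs inside the overlap and
  conflate the relations, so only the convergent geometry is planted.)
* **H2H pairs** (default 10): divergent TSSs separated by a drawn 1–1000 bp
  with zero span overlap.
* **tissue-specific genes** (default 3 per tissue): background mean × 100
  (fold enrichment) in the target tissue, suppressed to a 0.001-count mean
  elsewhere — effectively silent, with the occasional stray simulated read.
* **tissue-specific isoforms** (default 5 genes): two-isoform genes
  expressed everywhere whose second isoform carries 50% usage in one target
  tissue and 0% elsewhere.
* **high-isoform genes**: genes drawing ≥ 4 isoforms (then 4–6 uniformly)
  receive balanced isoform usage and background-level expression, so every
  isoform passes the call in every tissue; these genes are the planted
  ≥4-everywhere truth set, making that recovery check exact rather than
  probabilistic.

All other inter-gene gaps exceed 1 kb, and a brute-force scan at generation
time asserts that no accidental antisense overlap or ≤ 1 kb TSS adjacency
exists — planted pair counts are therefore recovered exactly by
construction, which is the point: the generator tests the finders, the
finders do not define the generator.

Gene counts are Gamma–Poisson (negative binomial, `var = μ + αμ²`,
α = 0.05) around per-tissue means (background mean 500 counts), with a
per-sample lognormal library-size factor (CV 0.2). Transcript values split
each gene's count by a Dirichlet(5) usage simplex shared across tissues
(except planted structure) and are normalized per sample to 10⁶ (TPM).
Transcript lengths are treated as equal — length bias is not modeled, since
no downstream stage depends on it. A single seeded `numpy` Generator drives
every draw in a fixed order; the same seed reproduces the GTF byte-for-byte
and the matrices exactly.

What the generator does **not** emulate: read-level sampling and mapping
noise, transcript-length and GC bias, correlated expression programs across
tissues, annotation errors, and real isoform-usage variation across
tissues. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under the stated noise model, not robustness to artifacts
of real RNA-seq quantification.

## Problem sizes

The default test and acceptance workloads use 1000-gene, 20-sample
datasets, 20 seeds for recovery sweeps, and ≤ 500-gene random annotations
(20 seeds) for the brute-force equivalence checks — sizes at which the
exhaustive oracles are exact and the full suite completes in about a
minute.

## Known limitations

* Overlap is computed on gene spans; two genes whose exons do not overlap
  but whose spans do still count as an antisense pair.
* The H2H definition is purely geometric (opposite strands + TSS
  proximity); canonical bidirectional-promoter calling would additionally
  require divergent orientation.
* The percentage convention (one decimal, half away from zero) is a
  reporting choice, pinned so results are byte-stable; other tools may
  print bankers-rounded values differing by 0.1.
* `sample_similarity` operates on size-factor-normalized counts (or TPM as
  given); no variance-stabilizing transform is applied before Euclidean
  distances, which practitioners may wish to add for heatmap use.
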