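# Methods

## The measure

`kspectra` compares shotgun metagenomes without any reference database. A
sample is summarized by its **canonical k-mer spectrum**: the vector of
occurrence frequencies of all k-mers after merging each k-mer with its
reverse complement (sequencing is strand-agnostic, so `AACGT` and `ACGTT`
are one feature). With the 2-bit base code A=0, C=1, G=2, T=3 the canonical
representative of a reverse-complement pair is the numerically (equals
lexicographically) smaller code, and the number of classes is

- n = 2^(2k−1) for odd k (no k-mer is its own reverse complement),
- n = 2^(2k−1) + 2^(k−1) for even k (self-reverse-complement palindromes
  form singleton classes, counted once).

Every length-k window of every read that consists only of A/C/G/T adds one
count to its class; windows containing `N` are skipped (a deterministic
choice — randomizing ambiguous bases would inject noise into small
spectra). Counts are normalized to sum 1, and beta-diversity between two
samples x, y is the **Bray-Curtis dissimilarity**

    BC(x, y) = 1 − 2 Σᵢ min(mᵢˣ, mᵢʸ) / Σᵢ (mᵢˣ + mᵢʸ),

which is 0 for identical spectra and 1 when no k-mer class is shared.
Because reverse-complement counts are merged in *both* vectors, BC over
canonical classes is identical to BC over the full 4^k expansion; the
collapsed vectors are used for half the memory.

Supported k is 1–13 with dense storage (2^25 classes at k=13); k=11 is the
default for real-size metagenomes, the practical balance between resolution
and the ~2×10^6-element vector it implies. The validation studies below use
k=10, which at the simulated community complexity already saturates the
correlation with ground truth while halving memory and time.

## Read preprocessing

Real read sets are quality-filtered with a strict per-nucleotide rule: a
read is kept only if **every** base has Phred quality ≥ 30 (inclusive).
Published descriptions of QV≥30 filtering leave open whether a
percent-of-bases flag was used; this package implements the strict
every-base reading and exposes `min_q`. Samples are then subsampled to a
fixed count (1 million by default) by index sampling without replacement
from a seeded generator, emitting reads in original file order so output is
reproducible and independent of internal shuffle order.

## The simulator

The synthetic data generator emulates the statistical structure of a
gut-like community at desk scale:

- **Genomes** — i.i.d. random sequences at a chosen GC content. The default
  study panel is 10 unrelated 200 kb genomes with GC spread evenly over
  35–65%, the range spanned by common gut bacteria. Random sequences have
  no repeats, gene structure or codon bias; what passing tests show is that
  the measure tracks *composition*, not that real genomes are this easy to
  tell apart (real congeneric genomes are harder; see the low-diversity
  study).
- **Abundances** — per-genus draws from Normal(μᵢ, σᵢ), negatives redrawn
  (clamping would bias the mean; for the σ/μ = 0.5 used here redraws are
  rare), then normalized to sum 1. The default means are a fixed
  rank-abundance profile (0.22, 0.17, 0.13, 0.11, 0.09, 0.08, 0.06, 0.05,
  0.05, 0.04) with σᵢ = 0.5 μᵢ, giving the between-sample compositional
  variation typical of one cohort.
- **Reads** — per-genome read counts are Multinomial(budget, abundances);
  each read takes a uniform start on a uniform strand; each base is
  substituted with probability `error_rate` to a uniformly chosen
  *different* base (1% models a short-read platform). Genomes are linear
  (no wrap-around reads), there are no indels, no GC-coverage bias and no
  quality-dependent error profile. Simulated FASTQ qualities are constant
  Q40. A ground-truth table (read → genome, start, strand) is emitted.
- **SNP models** — two ways to build a 64-member family of mutated copies
  of one ancestor:
  - *independent*: each member substitutes a Binomial(L, r) set of distinct
    positions, each to a uniformly chosen different base. Two members then
    differ at an expected fraction 2r(1−r) + (2/3)r² of positions, ≈ 2r for
    small r, so r = 0.5% gives ~1% pairwise divergence.
  - *phylogenetic*: 6 rounds of "copy every genome, then mutate all
    genomes", yielding the 2^6 = 64 leaves of a complete binary copy-tree
    with tree distances recoverable from leaf indices. The per-round rate
    defaults to 0.00098: the mean tree path between two random distinct
    leaves is 2·(6 − 57/63) ≈ 10.19 mutation rounds, so this rate matches
    the independent model's ~1% expected leaf-pair divergence. The rate is
    a free parameter because no canonical value exists for it.

## Comparison statistics

- **Mantel test** — correlation (Spearman with average ranks, or Pearson)
  between the n(n−1)/2 upper-triangle entries of two labeled matrices;
  significance by jointly permuting rows and columns of one matrix. Since a
  joint permutation only rearranges the same multiset of distances, ranks
  are assigned once and each permuted statistic is a Pearson correlation of
  rank matrices. The p-value is one-tailed (greater) with the +1
  correction, so 999 permutations bound it below by 0.001. The permutation
  seed is a required argument.
- **PCoA** — classical scaling: double-center −½D², eigendecompose, return
  coordinates scaled by √eigenvalue for positive eigenvalues in decreasing
  order. Non-Euclidean input can yield negative eigenvalues; those axes are
  dropped, explained-variance fractions are taken over the positive part,
  and a `truncated` flag is set when fewer axes than requested survive.
- **k-mer difference** — for a scatter of pairs (x = reference-based
  dissimilarity, y = k-mer dissimilarity), the central trend is the
  per-bin *median* of y over 20 equal-width bins of x, linearly
  interpolated between bin centers and flat beyond; each pair's difference
  is y − trend(x). The median was chosen over the mean because the trend
  must be robust to the very outliers the statistic is meant to expose;
  empty bins are dropped from the interpolation knots. Independently of
  the trend, any pair with y > 0.5 (strict) is flagged an extreme outlier;
  samples recurring across flagged pairs are the candidates dominated by a
  component absent from the reference. The k-mers of a designated read set
  (e.g. reads recruited to crAssphage) can then be subtracted from a
  sample's raw spectrum (floored at zero) before re-normalizing.

## Hit filtering and element abundance

Alignment-hit tables (BLAST/DIAMOND outfmt 6, optionally with qlen/slen)
are filtered by e-value < 1e−5, identity ≥ 80%, alignment/query length
> 0.8 and alignment/subject length > 0.8. The identity comparison is
implemented as ≥ (a "<" direction would keep only poor alignments,
contradicting the intent of the criterion as published; the direction is
configurable). Gene relative abundance is mapped-read length for the gene
over mapped-read length for the catalog; an element's abundance is the sum
over its genes, with genes missing from the table contributing 0 under a
warning. Multi-mapped reads are counted exactly as the input table counts
them.

## Validation studies and problem sizes

The package validates itself on simulations sized for a single CPU: 10
genomes × 200 kb, 50 communities, 100,000 reads × 100 bp per community,
spectra at k=10, Mantel with 999 permutations. Three paired scenarios share
community profiles and read-sampling seeds (common random numbers, so
perturbation effects are not confounded with seed noise): error-free reads,
reads with 1% substitution errors, and reads drawn from independent-model
mutants (~1% pairwise divergence, one mutant per species per community).
A fourth, low-diversity study replaces the panel by congeneric genomes (one
ancestor, 10 mutants at 1% per-genome substitutions, ~2% pairwise) and
checks only the *ordering*: its correlation with taxonomic composition is
lower than in the high-diversity panel, because near-identical genomes
shrink the k-mer signal between communities.

## Numerical choices and limitations

- Spectrum normalization tolerance is 1e−9 on the stored flag and 1e−6 on
  Bray-Curtis inputs; dissimilarity matrices must be symmetric within
  1e−12 with an exactly zero diagonal (the TSV round-trip re-symmetrizes
  6-significant-digit rounding).
- PCoA treats eigenvalues below 1e−12 (relative) as zero.
- Subsampling and all simulation outputs are reproducible from
  (parameters, seed); derived seeds are drawn below 2^31.
- The simulator does not model indels, structural variants, paired ends,
  GC bias or realistic quality profiles; conclusions about robustness to
  *substitution* noise do not automatically extend to those.
- Abundance estimation utilities trust the input hit tables; no mapping is
  performed in-package.
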