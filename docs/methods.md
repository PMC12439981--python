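# Methods

This note documents the models and procedures implemented in `histkit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## 1. Variant nomination from homolog sets

Evolutionary variant libraries are built by comparing a histone family's
reference protein (1-based coordinates on the sequence exactly as supplied;
the built-in human H4 reference uses mature-protein numbering, so `G4D` is
the glycine at mature position 4) against a set of homolog sequences.

Filtering cascade, applied in order and tallied per rule:

1. records annotated as fragments (description contains "fragment",
   case-insensitive, or an explicit flag);
2. records matching an enzyme/chaperone keyword blocklist (defaults:
   acetyltransferase, methyltransferase, chaperone, deacetylase, demethylase,
   kinase — a configurable list, since annotation vocabularies vary);
3. records containing non-canonical letters (X, B, Z, U...), dropped with a
   logged reason;
4. records whose length differs from the reference;
5. records more than `max_diff` (default 0.20) different from the reference
   by amino-acid content, i.e. Hamming distance over length.

Because only same-length sequences survive, substitutions are called by
direct positional comparison; no alignment step is needed. This is a
deliberate simplification relative to profile-HMM alignment pipelines and is
exact within the same-length regime this package operates in. Identical
homolog sequences are deduplicated before support counting, so database
redundancy does not inflate a variant's support. The divergence fraction is
computed over all positions (ambiguous-residue records never reach this
stage because rule 3 removes them).

Library augmentation adds an alanine substitution at every non-alanine
position (a self-substitution is not a variant, so alanine positions are
skipped) and arginine/glutamate/methionine substitutions at every lysine.
Augmentation is idempotent and preserves the provenance and support of
pre-existing variants.

Double-mutant libraries are uniform without-replacement samples from all
unordered pairs of singles at distinct positions, reproducible from a seed.

## 2. Screen enrichment statistics

A sort-seq screen yields construct-by-sample counts for two conditions
(high/low signal bin, or two timepoints). Counts for construct *i* in sample
*j* are modelled as negative binomial with mean `s_j * q_ij` and dispersion
`alpha_i`, where `s_j` is a sample size factor and `q_ij` depends only on
the condition of sample *j*.

**Control-anchored normalization.** Size factors are median-of-ratios
factors computed on the spiked-in fluorescent-protein control constructs
only: `s_j = median_i counts[i,j] / geomean_i`. Anchoring on controls with
no phenotype prevents global shifts in the library (e.g. many true
repressors) from biasing the normalization. Control rows containing a zero
are skipped; if none remain the factors are undefined and an error is
raised. When a table carries no controls the same estimator runs on all
rows, with a warning.

**Dispersion.** Per-construct method-of-moments estimates pool
within-condition variances of normalized counts, correcting for the
`mean_j(1/s_j)` Poisson term. A mean-dispersion trend `a0 + a1/mu` is fit by
least squares with one 3-sigma outlier-clipping pass, and each construct's
dispersion is `0.25 * max(raw, 0) + 0.75 * trend`, clipped to `[1e-8, 10]`.
With two replicates per condition the raw estimates carry ~2 degrees of
freedom, so strong shrinkage toward the trend is essential for calibrated
tests; the weights were fixed a priori at a DESeq2-like prior strength.

**Testing.** Condition means `m_g` are unweighted means of normalized
counts (this choice makes log2fc exactly invariant when one sample's counts
are rescaled; the weighted `sum K / sum s` estimator is not). The Wald
statistic is `(ln m_hi - ln m_lo) / sqrt(1/I_hi + 1/I_lo)` with Fisher
information `I_g = sum_j mu_ij / (1 + alpha_i mu_ij)`. When a condition's
counts are all zero the Wald statistic degenerates; those constructs fall
back to the NB score test evaluated at the pooled null mean, which remains
well-defined at the boundary. No pseudocount ever enters a test statistic;
a display pseudocount of 0.5 (on the normalized scale) enters the reported
log2fc only when a condition mean is exactly zero. p-values are exactly
antisymmetric under swapping the condition labels; they are only
asymptotically invariant under depth rescaling, because the NB information
genuinely depends on raw depth.

**Hit calling.** Benjamini-Hochberg adjustment is applied across
non-control constructs (controls are excluded from adjustment and calling);
hits are constructs with `padj < 0.05`, strictly, reported with direction —
the signed FDR convention (`sign(log2fc) * padj`). Replicate concordance is
the squared Pearson correlation of per-construct log2fc, with the signed
correlation reported alongside since R² is sign-blind. Role switchers
between two genetic backgrounds are constructs significant in at least one
background whose log2fc sign flips; all other significant constructs are
stable hits. Positional enrichment reports hits-per-residue by domain
(default human H4 annotation: tail 1-25, globular 26-102) and the
tail/globular density ratio (NaN when both densities are zero, Inf when
only the denominator is).

Log2fc estimates are reported unshrunken.

## 3. Synthetic sort-seq generator

Each construct carries a latent phenotype shift `delta` in SD units of the
within-construct cell-to-cell signal spread; cell signal is Normal(delta, 1).
Gates are fixed at the pooled population's 10%/90% quantiles, computed
exactly from the abundance-weighted Gaussian mixture — mirroring FACS
practice of gating on the pooled sample, and reducing to the standard-normal
quantiles when all shifts are zero. Bin probabilities are
`p_low = Phi(z_low - delta)` and `p_high = 1 - Phi(z_high - delta)`.

Expected counts per bin are proportional to library abundance (lognormal,
sigma = 0.5, emulating uneven representation) times the bin probability,
scaled to a mean depth per construct per bin (default 1,000). Counts are
Gamma-Poisson with dispersion phi = 0.05 at the count level. Controls
(delta = 0) are appended and flagged. Replicates share abundances (one
infected pool) and draw counts independently.

Effects follow a sparse two-class model matching the binary classification
target: a fraction pi = 0.2 of singles are repressors with
delta = -1.5, doubles are additive with Normal(0, tau = 0.2) epistasis; a
continuous mode (delta ~ Normal(0, sigma)) is available for concordance-style
experiments. The defaults are stated modelling choices, not values fitted to
any particular screen.

What the generator does **not** emulate: sort-gate contamination and
multiplets, PCR jackpotting beyond the Gamma-Poisson term, barcode
cross-talk, doxycycline induction kinetics, cell-cycle or fitness coupling,
and any genomic (per-locus) structure — the phenotype is a single scalar per
construct. Passing tests therefore demonstrate correctness of the statistics
and the learnability of sequence rules under this causal structure, not
performance on any real screen.

## 4. Tail repression classifier

Tails are encoded two ways: a 30x20 one-hot matrix (columns in alphabetical
one-letter-code order) and a 30xD per-residue embedding. The default
embedder is a fixed table of four standardized physicochemical descriptors
(Kyte-Doolittle hydropathy, net charge at pH 7, side-chain volume, Grantham
polarity) expanded with a seeded orthonormal random basis to D = 16, giving
every residue a distinct signature with no model download; a protein
language-model backend can be registered under the same interface (the
embedding table seed is a fixed constant, independent of training seeds).

Each encoding feeds a 1D convolution (128 channels, kernel 5, 'valid'
padding), ReLU, and global max pooling (adaptive max pooling to width 1 —
the narrowest reading, giving one 128-vector per branch). The concatenated
256-vector passes through a 64-unit ReLU layer to a single logistic output.
The head width and pooling width were open choices and are recorded here as
such. The network, its backpropagation and Adam (lr 1e-3, default 50
epochs, minibatch 64, no early stopping) are implemented directly in NumPy,
so training is bit-reproducible from a seed on any platform.

The loss is weighted binary cross-entropy with logits: class balancing via
`pos_weight = #neg/#pos` computed on the training split, and per-sample
weights. The wild-type tail is anchored as non-repressive — appended to the
training split with weight 10, repeated 20 times (the anchoring strength was
fixed a priori; the qualitative behavior, a suppressed wild-type score, is
what the tests check) — and its predicted score is recorded after every
epoch. If a screen calls the wild type itself a repressor, the label is
forced to 0 with a warning.

Labels from a screen: repressor iff `padj < 0.05` and log2fc is negative
(depleted from the high-signal bin). Splits are 80:20, stratified by label
and seeded; constructs sharing a single mutation may appear in both splits.

Evaluation reports rank-based AUC, precision@N (default N = 100; N is
clipped with a warning on small test sets), test prevalence, and enrichment
= precision@N / prevalence, the fold improvement over random guessing at
that list size. Note an implication of global max pooling: a rule tied to an
absolute position is identifiable only through its sequence context, which
is exactly the regime of mutant libraries on a fixed wild-type background;
on context-free random sequences the architecture is positionally blind.

## 5. Greedy tail design

Starting from an anchor state (default: wild type + G4D), each round
enumerates all allowed single-substitution neighbors in deterministic order
(position ascending, then alphabetical alternative; reverting the anchor
substitution is forbidden by default), scores them in one batch, and accepts
the argmax iff it improves the current score by at least epsilon (default
0). Ties break to the first-enumerated neighbor. The search stops at the
mutation budget (default 8 additional mutations) or when no neighbor
qualifies. Later rounds may overwrite earlier mutated positions, so the
budget bounds the divergence from the anchor at `max_mutations / 30`.
The candidate set defaults to all substitutions within the tail; it can be
restricted to screen-observed mutations.

Natural-tail nomination filters a tail set to those carrying a required
substitution (e.g. D at position 4) and ranks them by predicted score,
reporting each tail's score difference from the wild type.

## 6. Reference experiment sizes and numerical choices

The packaged benchmarks use 189 singles + 3,694 doubles (the combinatorial
library scale), depth 1,000, 2 replicates, 5 seeds for stochastic
quantities; the null-calibration experiment uses 4,600 constructs (the full
library scale) and the concordance experiment 2,000 constructs. Dispersion
clipping is `[1e-8, 10]`; gate-threshold root-finding uses Brent's method on
the mixture CDF; BH adjustment delegates to statsmodels. All derived seeds
come from `numpy.random.SeedSequence`-style generator spawning from one
integer.

## 7. Known limitations

- The enrichment test is a simplified negative-binomial pipeline (no
  Cox-Reid adjustment, no dispersion MAP with outlier refitting, no lfc
  shrinkage); with very few replicates its p-values lean on the trend
  shrinkage for calibration.
- The fallback embedder is a fixed descriptor table: it carries
  physicochemical structure but none of the evolutionary context a protein
  language model provides, so absolute classifier scores are not comparable
  to language-model-based ones.
- The classifier is trained per readout; joint multi-task modelling of
  accessibility and methylation readouts is out of scope.
- Greedy search offers no guarantee of global optimality on non-submodular
  learned objectives; it is the specified design procedure, not an optimum
  finder.
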