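# Methods

## The model

Alternative splicing is treated as a stochastic minimization process:
which isoform a pre-mRNA matures into is probabilistically determined by
the binding energy of splicing factors at competing splice sites.
Extreme-value theory then suggests that isoform expression levels follow
one of the three extreme-value laws; the bounded-below case is the
Weibull (type III) distribution, and that is the law adopted here:

    W(x; a, b) = (a/b) (x/b)^(a-1) exp(-(x/b)^a),   x >= 0.

The parameterization puts the scale in the denominator (`scipy`'s
`weibull_min(c=a, scale=b)`); the rate form is never used, and a test
pins the parameterization against scipy to avoid the classic ambiguity.

The shape `a` is universal (a property of the splicing machinery), the
scale `b` is gene- and condition-specific.  Two identities connect the
parameters to observables:

- population mean: `mu = b * Gamma(1 + 1/a)`;
- gene expression: a gene with `M` isoforms and total expression `E`
  satisfies `E ~= b * M * Gamma(1 + 1/a)` (sample mean ~ population mean),
  so the unbiased scale estimate is `mean(x) / Gamma(1 + 1/a)`, not the
  bare sample mean.

The canonical shape is the root of `1 + 1/a = Gamma(1 + 1/a)` on (0, 1),
located by Brent bracketing on (0.05, 0.95) with tolerance 1e-10
(default); the root is 0.3903, i.e. 0.39 at two decimals.  It is also
the distance-minimizing shape in the grid search below, which is the
package's preferred estimator.

## Frequencies and the median matrix

The frequency of the k-th most expressed of a gene's M isoforms is
`f(k, M) = x_(k) / sum(x)`, a descending vector summing to 1.  Genes are
grouped by annotated isoform count M; the group medians form the
`mf(k, M)` matrix (ranks 1..9, M = 1..30 by default, cells with k > M
masked).  Matrices from experiment, simulation and the closed-form
approximation share this layout and are compared by the Euclidean
distance over unmasked cells; cells masked in either operand contribute
zero, so sparse empirical matrices remain comparable to dense simulated
ones.

## Monte-Carlo simulation

A gene with M isoforms is simulated as M independent draws from
`W(a, 1)` (the scale cancels in frequencies) converted to a sorted
frequency vector.  Draws use the inverse CDF
`x = b(-ln(1-u))^(1/a)`; rows whose draws all underflow to exactly zero
(probability ~1e-5 per gene at a = 0.39, M = 1) are dropped, since a
zero-expression gene has no frequencies.  All stochastic operations take
an explicit seed; per-(seed, shape, M) sub-streams make every result
reproducible bit for bit and every grid profile smooth to re-runs.

Defaults: 10,000 genes per M for median matrices (enough that the median
Monte-Carlo error per cell is ~0.002-0.005); 100,000 genes per M for
quantile thresholds and tail probabilities, where the target is a tail
statistic rather than a median.

### Shape estimation by grid search

For each candidate shape on a grid (0.01..0.99, step 0.01 by default)
the simulated median matrix is built and its distance to the observed
matrix recorded; the argmin is the estimate, ties breaking toward
smaller a.  The median is robust to outliers and the per-gene
scale-estimation bias affects data and simulation identically, which is
why this route beats curve fitting.

### Dominance thresholds

The significant-dominance threshold for genes with M isoforms is the
95th percentile (alpha = 0.05) of the *pooled* isoform frequencies —
every rank, not just rank 1 — over simulated genes, computed with linear
interpolation between order statistics.  A randomly selected isoform
exceeds the threshold with probability alpha.  For M = 2 the pooled tail
has the closed form `P(f > t) = 1 / (1 + (t/(1-t))^a)` giving a
threshold of ~0.9995; the two-isoform *dominant* tail is
`P(f(1,2) >= t) = 2 / (1 + (t/(1-t))^a)` (the odds of the ratio of two
Weibull variates raised to the a-th power are logistic), used as an
independent analytic check on the simulation.

M = 1 is excluded from threshold computation (the frequency is
identically 1).

## The closed-form median formula

The median frequencies are approximated by

    mf(k, M) = exp(-(1 + k/M)^2) / (k * H_M),
    H_M = sum_{m=1..M} (1/m) exp(-(1 + m/M)^2),

so each column sums to one by construction.  `(1/k) exp(-(1 + k/M)^2)`
is the rank's frequency index.  The formula is an empirical
approximation to the simulation median — no derivation from the Weibull
model exists (sums of Weibull variates have no closed-form
distribution) — so agreement is asserted in tests (Euclidean distance to
the 10,000-rep simulated matrix at a = 0.39 below 0.2; observed ~0.14),
never assumed in code.

## Curve fitting and its bias

`fit_shape_curvefit` fits `(a, b)` by least squares of observed bin
probabilities against the model's bin masses (CDF differences
renormalized to the binned range), over 50 equal-width bins up to the
99th percentile.  Bin masses rather than midpoint densities are fitted
because the density diverges at zero for a < 1 and midpoint evaluation
misstates the first bin by orders of magnitude.  On raw Weibull draws
the fit recovers the shape to ~0.01; on per-gene *scaled* values it is
biased (the scale is re-estimated from few isoforms per gene, and the
naive scaling bounds scaled values by M), which is documented behavior
and the motivation for the grid-search estimator.  The Weibull
probability plot uses median-rank plotting positions
`(i - 0.3)/(n + 0.4)`.

## Expression tables and profiles

Cufflinks (`tracking_id`/`gene_id`/`FPKM`) and Salmon
(`Name`/`Length`/`EffectiveLength`/`TPM`/`NumReads`, plus a
transcript-to-gene map) dialects are parsed into a long table.  The
annotated isoform count M always comes from the annotation, never from
the observed isoforms: annotated isoforms absent from the table enter
with expression zero and rank last.  Genes with total expression <= 1
(FPKM > 1 rule) are excluded, per sample.  Rank ties break
lexicographically by transcript id for reproducibility.

### KL divergence and entropy

Binned frequency distributions (40 equal-width bins on [0, 1] by
default) are compared by `KLd(P||Q) = sum P ln(P/Q)` in nats — the
information lost when the model Q approximates the data P.  Empty Q bins
receive pseudo-mass 1e-9 before renormalization.  Entropy is reported in
the conventional nonnegative form `-sum P ln P`.

### Switch detection

For a condition pair, a cell subset votes on a gene only when the gene
passes the expression filter under both conditions in that subset; a
vote is a switch when the rank-1 isoform identity differs.  Genes are
reported in strata by switch count, restricted to consistent switchers
(switch votes in every evaluable subset), with a partial flag when the
gene was evaluable in fewer subsets than exist.

## Synthetic data

The generator reproduces the study's simulated-data conditions:
expression laws `N(20, 2)` (negative control, truncated at zero — the
truncated mass at 10 sigma is negligible) and `W(0.39, 10)`; paired-end
reads of 100 bp per mate with a fixed 100 bp insert (the fragment is
exactly 300 bp; a stated *average* insert without a variance is realized
as a constant to keep the geometry exact); pair count
`R = int(E*L/100/2 + 0.5)` (round half up); uniform random fragment
starts ("uniform coverage" as uniform sampling, not tiling); constant
base quality 'I' (Phred 40); 10 replicates by default, replicate r
seeded by (seed, r).  Transcripts shorter than the fragment are skipped
and logged.  Synthetic transcriptomes use uniform base composition and
carry no error model, PCR duplication or positional bias — so passing
tests demonstrate correctness of the statistical pipeline, not
robustness to mapper artifacts or quantifier EM behavior.  Truth-based
re-quantification (exact substring matching, 25-mer seeded) replaces an
external aligner/quantifier stack; it recovers each expression level to
the rounding granularity 200/L by construction.

## Problem sizes and tolerances in the test suite

Unit tests use 10^3-10^5 draws with fixed seeds; tolerances are three
Monte-Carlo standard errors where an analytic value exists, and the
spec-level bands otherwise (thresholds ±0.02 at 10^5 genes per M).  The
end-to-end recovery test generates 15,000 genes (~500 per isoform
count): at ~100 genes per M the sampling noise of the observed medians
can shift the grid argmin beyond one step, while at 500 per M the noise
term is an order of magnitude below the one-grid-step distance signal.
Full-grid searches run at 10,000 reps per M per grid point (~25 s per
search on one CPU).

## Known limitations

- The closed-form formula's status is empirical; no convergence or error
  bound is claimed.
- The pipeline models quantification output, not quantification itself:
  EM ambiguity, multi-mapping and annotation incompleteness are outside
  scope (users supply any annotation; M depends on it).
- The expression filter conditions frequencies on total expression for
  small M; this mirrors real analyses but slightly biases low-M groups
  relative to unfiltered simulation.
- Shapes are restricted to a in (0, 1] in the simulation configuration —
  the regime of the splicing model; the Weibull core itself accepts any
  a > 0.
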