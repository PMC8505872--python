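# Methods

## Scope and model of the analysis

The package reconstructs a candidate-gene discovery chain for heterophylly:
five two-condition RNA-seq contrasts in a heterophyllous tetraploid
(*C. palustris*) — four leaf-primordium comparisons against the submerged
control (aerial; AgNO₃-, ABA- and uniconazole-P-treated submerged plants)
and one mature-leaf comparison — plus one contrast in a non-heterophyllous
diploid relative (*C. terrestris*), joined by an ortholog map. Assembly,
read mapping, ORF prediction, orthology inference and TF-family lookup are
treated as upstream inputs: the package consumes gene-level counts,
annotation flags and the ortholog table, and generates synthetic versions
of all of them.

A single direction convention is used throughout: every log₂ fold-change is
log₂(treatment / submerged control). "Down-regulated in submerged leaves"
therefore appears as call `up` in a treated-vs-submerged table, and
"up-regulated in submerged leaves" as call `down`. The same convention
applies to the *C. terrestris* aerial-vs-submerged contrast, so
same-direction matching between a candidate and its ortholog compares like
with like.

## Differential expression

TPM is computed per sample as 10⁶·(count/length)/Σ(count/length); genes
with TPM < 1 in *all* samples are removed before any testing. The floor
(default 1) is configurable.

Between-sample normalization is TMM: log-ratios M and log-intensities A
against a reference sample (the one whose depth-scaled upper quartile is
closest to the mean upper quartile), the extreme 30% of each M tail and 5%
of each A tail discarded by rank, and the surviving M values averaged with
the usual inverse-asymptotic-variance weights. Factors are rescaled to
geometric mean 1; effective library size = raw depth × factor. The original
analysis chain used an iterative DEG-elimination normalization wrapped
around TMM; this package deliberately implements the single TMM pass — the
decision rule downstream is identical and the desk-scale simulations
contain no global expression shift that would distinguish the two.

Dispersion is a single common φ in the NB parameterization
var = μ + φμ². Per gene, within-group means and variances of
effective-size-normalized counts give the method-of-moments estimate
(v − m)/m², pooled over replicated groups; the common φ is the median over
genes with positive mean, floored at 0. The estimator is crude per gene but
the median over thousands of genes is stable; a small downward bias (the
median of a right-skewed per-gene distribution) is acceptable because the
exact test's operating characteristics are verified directly by simulation
(type-I error within [0.03, 0.07] at nominal 0.05).

The two-group test conditions on the grand total. Summing i.i.d. NB(μ, φ)
counts over a group of size n gives NB with size n/φ, so under equal means
the group-A total given total s is BetaBinomial(s, n_A/φ, n_B/φ) —
independent of μ and of the NB success probability. The implementation
enumerates the conditional log-pmf for totals up to a cap (default 5000,
configurable) and sums the probabilities of all outcomes no more likely
than the one observed (ties included with a 10⁻¹² log-space guard); at
φ = 0 the conditional law is Binomial(s, n_A/(n_A+n_B)). Above the cap a
normal approximation with the beta-binomial mean and variance and a
continuity correction doubles the smaller tail. Unequal effective depths
are handled by scaling each sample's counts to the common effective size
and rounding before summation; grand total 0 returns p = 1 with a warning.
Fold-changes are computed from normalized group means with a pseudo-count
of 0.5 per group mean, bounding estimates when a group is all zero.

Multiple testing is Benjamini–Hochberg; DEG calls require q < 0.05 *and*
|log₂FC| > 1, both strict, signed by the fold-change.

## The cascade

Shared categories over the four primordium comparisons: SHARED4 = DEG with
the same sign in all four; SHARED3_NOT_UNI = same-sign DEG in aerial, AgNO₃
and ABA but *no* DEG call under uniconazole. "Consistent change" is read as
same log₂FC sign because the analysis separates down- and up-regulated
intersections. The categories are disjoint by construction and everything
else is NONE.

Stage specificity is assigned over the full candidate set (before
exclusion): a candidate that is a DEG of either sign in the mature
comparison is `dev_and_mature`, otherwise `dev_specific`.

Cross-species exclusion applies two ordered rules, consistency first:

1. `ct_consistent_deg` — the comparable ortholog is a *C. terrestris* DEG
   with the same direction as the candidate.
2. `downreg_ct_unexpressed` — the candidate is down in submerged primordia
   (direction `up` under the convention above) and its ortholog's TPM is
   below the floor in every *C. terrestris* sample.

Candidates with no comparable ortholog are always retained. Both one-to-one
and multi(tetraploid)-to-one(diploid) links count as comparable; each
tetraploid gene carries at most one link, and a diploid DEG excludes every
tetraploid co-ortholog candidate it links to (per-link test) — the source
analysis is silent on this point and the per-link reading is the
conservative one for a candidate list.

TF candidates are retained genes with both an ORF flag and a TF flag; a TF
flag without an ORF is ignored. Genes "up in submerged leaves" among them
are those with direction `down`.

Because *C. terrestris* genes removed by the low-expression filter never
reach the DE test, the pipeline re-indexes the diploid DEG table to the
full diploid universe with call `none` — a gene filtered as unexpressed is
by definition not a DEG, and the exclusion rules need its row present.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per term; terms annotating
fewer than `min_term_size` (default 5) population genes are removed
*before* testing, so BH runs over the filtered list only — omitting rare
terms is part of the hypothesis family definition, not a post-hoc filter.
Under-representation is not computed. Namespaces can be tested separately
by passing separate term maps.

## Morphometrics

Descriptors follow the ImageJ conventions: circularity 4πA/P² clipped at 1
(fine polygons can exceed 1 numerically), solidity as area over convex-hull
area, and the aspect ratio of the ellipse sharing the region's second-order
central moments. Moments are integrated over the polygon *interior* with
Green's-theorem closed forms, not over the vertex set, so the result is
independent of vertex density. The "smallest bounding rectangle" is the
minimum-area rotated rectangle over the convex hull (its sides are the
rotation-free cell length and width), not the axis-aligned box.

Welch's *t* reports the Welch–Satterthwaite df; the degenerate case of two
zero-variance groups with equal means returns p = 1 by convention. Hedges'
g uses the pooled SD and the small-sample correction J = 1 − 3/(4ν − 1)
with ν = n_A + n_B − 2. Tukey HSD is the Tukey–Kramer studentized-range
procedure; an optional compact letter display is derived greedily from the
pairwise decisions at α. PCA standardizes descriptors to unit variance
(their units differ — µm², µm, dimensionless — so unscaled PCA would be
dominated by area); explained variances then sum to the number of
descriptors kept, and zero-variance descriptors are dropped with a warning.

## Synthetic data

Counts are NB(mean, φ) with mean = baseline × 2^(planted log₂FC) × depth
factor; planted fold-changes are defined relative to the submerged control
of the same stage. The default study design is the real one: five
primordium conditions plus two mature-leaf conditions for the tetraploid
and two primordium conditions for the diploid, three biological replicates
per cell. Defaults φ = 0.05 and lognormal baselines (median ≈ 80 counts)
are configuration choices in a plausible bulk-RNA-seq range, not claims
about the deposited libraries, whose depths and dispersions are not stated;
planted candidate genes use baseline 100 and |log₂FC| = 2. Orthology is
simulated per diploid gene — two tetraploid co-orthologs with the
duplication probability (capped at 1-to-2, the tetraploid-vs-diploid case),
else one — plus an orphan fraction of the tetraploid universe. Exclusion-
category genes are planted on one-to-one links so each carries its own
diploid ortholog; "unexpressed" orthologs use a near-zero baseline (0.005)
because a single stray count at desk-scale depth would already lift TPM
above the floor. Cell contours come from r(θ) parameterizations (lobed:
r = R(1 + a·sin kθ)) with smooth low-frequency radial noise — vertex-wise
noise at realistic vertex densities self-intersects, radial noise keeps
contours star-shaped and hence simple. All randomness flows from one
explicit seed through a named generator.

The worked-example fixture (`planted_cascade_fixture`) plants DEG *tables*
directly (signed calls with consistent q and log₂FC values passed through
the calling rule), at the category sizes of the published analysis by
default; it exercises the cascade's set arithmetic exactly and is the basis
of the acceptance script. What it does not exercise — sampling noise,
normalization, power — is covered by the simulated-counts path.

## What passing tests do and do not show

The simulations demonstrate internal consistency: the pipeline recovers
what the generator planted, at the planted effect sizes, under NB sampling
with a common dispersion and no outliers, batch effects, isoform ambiguity
or mapping bias. Real libraries violate several of these assumptions
(gene-wise dispersions, composition effects beyond what TMM removes,
fragmented transcriptome assemblies splitting genes), so desk-scale
recovery rates do not transfer to real data; the published real-data DEG
counts depend on the deposited reads and are out of scope here. Test
problem sizes (2 000 genes, 3 replicates, five seeds) were chosen as the
smallest sizes at which the binomial noise on the measured rates is well
inside the asserted bands.

## Numerical choices

Exact-test enumeration in log space with logsumexp normalization; tie
inclusion with a 10⁻¹² additive log guard. TMM falls back to the untrimmed
weighted mean if trimming empties a tiny gene set. Circularity and solidity
are clipped at 1. The rotated-rectangle width of a degenerate (collinear)
contour raises rather than returning 0. BH is delegated to statsmodels;
scipy provides the hypergeometric tail, Welch's *t* and the studentized-
range distribution; shapely provides hulls and minimum rotated rectangles;
scikit-learn provides the PCA backend. The conditional exact test, TMM,
the dispersion estimator, polygon interior moments and Hedges' g are
implemented here.
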