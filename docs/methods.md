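# Methods

This note documents the statistical models, the numerical choices behind
them, and what the synthetic data generator does and does not emulate.

## Pipeline model

The analysis chain treats haplotype-assisted genomic prediction as four
stages over a dosage matrix (individuals × biallelic markers), a marker
map, a pedigree and partially observed phenotypes.

**Marker selection.** Minor allele frequency is computed from dosage sums,
f = Σx/(2n), maf = min(f, 1−f), over all genotyped individuals (training
and validation); markers with maf < 0.05 are excluded and equality is kept.
LD is the squared Pearson correlation of dosage vectors (composite,
Rogers–Huff-style LD): it needs no phase, and for the r² = 1 decision it
coincides with the haplotype-level definition whenever one marker is a
deterministic copy or complement of another. Complete-LD subsets are the
connected components, within a chromosome, of the graph with edges where
r² ≥ 1 − tol, keeping components of size ≥ 2. |r| = 1 is transitive, so in
exact arithmetic components are cliques; the tolerance (default 1e−9 on
1 − r²) only absorbs floating-point error. All intra-chromosome pairs are
evaluated — at ~2M pairs per 1998-marker chromosome a full correlation
matrix is cheap and avoids any window heuristic.

**Haplotype inference.** Within a subset of L SNPs (L ≤ 12 enforced; ≤ 8 in
practice), haplotype frequencies are maximum-likelihood estimates under
random pairing: the EM algorithm of gene counting, where the E-step
distributes each phase-ambiguous genotype over its compatible ordered
haplotype pairs proportionally to current frequency products and the M-step
sets frequencies to expected counts / 2n. The candidate space is restricted
to haplotypes compatible with at least one observed genotype. Convergence
is |Δ log L| < 1e−8 with at most 1000 iterations; the log-likelihood is
asserted non-decreasing at every step and frequencies sum to 1 to 1e−10.
The default start is the product of single-marker allele frequencies
(deterministic and symmetric); because the multinomial pair likelihood has
local maxima on small samples, ten further EM runs are started from
Dirichlet(1) points drawn with a fixed internal seed and the run with the
highest final log-likelihood wins — results remain deterministic across
calls. Each individual is then assigned the compatible unordered pair
(h₁, h₂) maximising f(h₁)f(h₂)(2 if h₁ ≠ h₂), with exact ties broken by the
lexicographically smallest pair and the posterior reported as that mass
over the total compatible mass; the assigned pair must reproduce the
observed dosages exactly (hard assertion). Haplotypes with estimated
frequency below 1% are omitted from the design (equality kept); an
individual carrying a dropped haplotype simply has that copy unrepresented,
with no re-assignment. This EM stage stands where a Bayesian phasing
sampler could be used: subsets are short enough for exact enumeration, the
estimator is deterministic, and only point frequencies and one phase per
individual are consumed downstream.

**Prediction models.** The design matrix X counts copies (0/1/2) of each
retained haplotype; when a subset retains all its haplotypes its columns
sum to 2, so [1 X] is structurally rank-deficient. The fixed model
therefore uses the minimum-norm least-squares solution (SVD pseudo-inverse,
singular-value cutoff 1e−10·σ_max) rather than dropping reference
haplotypes — this keeps "breeding value = sum of carried haplotype
effects" well defined for every individual, and the fit itself (the
projection) is unaffected by the choice. Residual variance is
RSS/(n − rank). The random models solve Henderson's mixed-model equations

    [ n    1'X          ] [μ]   [1'y]
    [ X'1  X'X + λD     ] [g] = [X'y],   λ = σ²_e/σ²_g,  D = diag(1/s_k),

with s_k = 1 (RM1) or s_k = L_k/m_k (RM2; subset length over its
retained-haplotype count — the scale is pluggable: `length_over_count`,
`length`, `none`). Any constant factor in the homogeneous prior is absorbed
by the estimated variance component, so RM1 fixes s = 1 and lets REML set
the scale; when all s_k are equal RM2 is algebraically identical to RM1.
The animal model replaces X with the 0/1 incidence Z onto pedigree
positions and λD with λA⁻¹, where A is built by the tabular method
(a_ij = ½(a_is + a_id), a_jj = 1 + ½a_sd) over the validated, topologically
ordered pedigree; A⁻¹ is obtained by Cholesky solves against A with no
structural shortcuts, so inbred pedigrees are exact. The coefficient matrix
is positive definite for λ > 0 and solved by Cholesky.

**Variance components.** For the single-genetic-component model
y = 1μ + u + e, u ~ N(0, σ²_g K) (K = X diag(s) X' or Z A Z'), the
restricted likelihood is maximised directly on K's spectrum: project out
the intercept with an orthonormal basis B, eigendecompose B'KB once, and
profile σ²_e out of the restricted likelihood, leaving a 1-D problem in the
ratio r = σ²_g/σ²_e solved by a log-spaced grid (161 points over
10⁻¹⁰..10¹⁰) plus bounded Brent refinement. This was chosen over iterative
EM-REML because it is deterministic, finds the global optimum of the
profiled likelihood on the search interval, and costs one O(n³)
decomposition instead of one per iteration — material for the
~3000-individual animal model. σ²_g is floored at 1e−8·Var(y). A fixed λ
may be supplied instead, bypassing estimation.

**Evaluation.** Pearson correlations with Fisher-z confidence intervals,
tanh(atanh r ± z_{1−α/2}/√(n−3)), and two-sided p-values from
t = r√((n−2)/(1−r²)) on n−2 df. This CI form reproduces published
correlation intervals computed at n = 1000 and n = 2000 to four decimals,
so it is adopted as the reference method. Tables are computed separately on
the training (known-phenotype) and validation (masked) individuals, and —
because "accuracy" can mean either — predictions are correlated both with
observed/masked phenotypes and with true breeding values when a truth
bundle is available.

## Synthetic data generator

The generator emulates the shape of a mid-2000s simulated-workshop dataset:
by default 3000 individuals (200 founders, three generations of monogamous
pair mating with four offspring per pair), five chromosomes of 1998 SNPs,
2000 known and 1000 masked phenotypes, h² = 0.3. Founder allele
frequencies are Uniform(0.01, 0.5) per marker — guaranteeing markers on
both sides of the 5% MAF threshold — and founder haplotypes draw alleles
independently per marker. Offspring haplotypes arise by gene dropping with
Poisson(1) crossovers per chromosome per meiosis at uniform positions.
Perfect-LD groups are planted as exact copy or complement columns of a
freely segregating source marker (materialised after gene dropping, so no
recombination can break them): r² = 1 holds exactly, making the grouping
stage testable without tolerances. The trait is purely additive: 100 QTL
uniform over all markers with N(0,1) effects; the residual variance is
Var(BV)·(1−h²)/h² from the empirical breeding-value variance, so realised
h² matches the request. h² = 0 produces pure noise at a fallback variance
(with a warning), giving a clean null. One root seed feeds independent
per-stage streams (pedigree, layout, founders, meiosis, QTL, phenotype), so
runs are byte-identical given config + seed.

What the generator does **not** emulate: coalescent-realistic LD decay
(founders have no LD beyond the planted blocks; background LD arises only
from three generations of co-segregation), genotyping error or
missingness, sex chromosomes, non-additive gene action, or selection in
the pedigree. Consequently the planted blocks segregate exactly two
haplotypes each, so the 1% haplotype filter rarely binds on default
synthetic data — its behaviour is exercised by dedicated tests with
haplotypes simulated at controlled frequencies — and passing tests show
the pipeline's internal correctness on data of this structure, not
accuracy levels transferable to real livestock panels.

## Numerical and design choices

* MAF boundary and haplotype-frequency boundary both keep equality
  ("lower than" excludes); thresholds are flags so the strict reading is
  reproducible too.
* r² on dosages is undefined for monomorphic vectors; such markers are
  pre-filtered and otherwise raise.
* EM restart count (10) trades determinism-friendly robustness against
  runtime; restarts are skipped when every genotype is phase-unambiguous.
* The permutation null used in validation tests permutes design rows over
  individuals and refits with the variance ratio held at the observed-data
  REML estimate: re-estimating λ per permutation would dominate runtime
  without changing a location null.
* Degenerate inputs: correlations need n ≥ 4 and non-constant inputs;
  |r| = 1 reports a degenerate (r, r) interval with p = 0; variance
  estimation needs n ≥ 3; mixed models require λ positive and finite.
* Reference problem sizes: the acceptance script and the heaviest test run
  the full 3000 × 9990 configuration (≈1 minute); unit tests use a few
  hundred individuals with the same structure.

## Known limitations

* The complete-LD grouping rule (connected components) is one of several
  defensible readings; with exact duplicates they coincide with cliques,
  but at loose tolerances components may chain.
* EM phasing ignores recombination priors and long-range phase; it is
  adequate for ≤ 8-SNP subsets, not a general phaser.
* The spectral REML estimator handles one genetic component; multi-kernel
  models (e.g. haplotype + polygenic jointly) are out of scope.
* Dense linear algebra throughout: fine to ~10⁴ individuals, not tuned for
  biobank scale.
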