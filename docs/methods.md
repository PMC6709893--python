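# Methods

This note records the statistical model, the defaults and the reasoning
behind the design choices in `breedcomp`, in the spirit of a package
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Ancestry model

### Normalization and reference PCA

Genotypes are dosages `d ∈ {0,1,2}` of a per-marker counted allele (A1,
the first allele symbol observed in the source file, matching the PLINK
text convention).  With reference-panel allele frequency `p_j`, the
normalized entry is

    x = (d − 2 p_j) / sqrt(2 p_j (1 − p_j)),

the dosage standardization under Hardy–Weinberg sampling variance
`2p(1−p)`.  Missing dosages become 0 after centering (mean imputation);
markers monomorphic in the panel carry no ancestry information under
this scaling and are dropped (their names are retained on the model for
diagnostics).  Frequencies always come from the reference panel and are
never updated by target data — this is what makes estimates independent
of the composition of the target batch, in deliberate contrast to
likelihood-based admixture estimators whose output can depend on which
other individuals are analyzed together.

The panel's normalized matrix `X` (n samples × m markers) is decomposed
by thin SVD, `X = U Σ Vᵀ`.  Covariance eigenvalues are `λ = σ²/m` and
the model stores the full-spectrum sum as `trace` (a scale/rank
diagnostic).  In-sample scores are the left singular vectors `U[:, :M]`
and the SNP-weight matrix is `W = V[:, :M] Σ[:M]⁻¹`, chosen so that
`X W = U[:, :M]` exactly — the in-sample identity the test suite asserts
to 1e-8.  Eigenvector sign is fixed deterministically by making the
largest-magnitude loading of each axis positive.

### Number of axes

M = K − 1 for K breeds.  K centroids span at most K − 1 dimensions, and
with the sum-to-one constraint this makes the assignment system square
and uniquely solvable.  Retaining more axes would add directions in
which breed centroids are (in expectation) coincident, contributing only
noise to the assignment step.

### Out-of-sample shrinkage

When n ≪ m, projecting a *new* sample onto eigenvectors estimated from
the panel attenuates its score relative to in-sample scores.  The model
calibrates one multiplicative correction per axis by leave-one-out
refits: each of min(20, n) evenly spaced panel members is withheld, the
PCA refit without it, the member projected out-of-sample, and the ratio
of its full-model in-sample score magnitude to the out-of-sample
magnitude averaged per axis (clamped at ≥ 1; near-zero scores skipped).

One subtlety matters in practice: with K equally diverged breeds the
K − 1 signal eigenvalues are nearly degenerate, so the retained subspace
has an essentially arbitrary orthonormal basis and a leave-one-out refit
returns *rotated* axes.  Comparing magnitudes axis-by-axis across two
arbitrary bases produces meaningless (occasionally enormous) ratios.
The calibration therefore first aligns each leave-one-out model to the
full model by orthogonal Procrustes on the scores of the shared n − 1
samples, and measures ratios in the aligned basis.  Calibrated factors
on the default panels are ≈ 1.03 — small, because m = 7,000 ≫ n = 250 —
and the projection can be run uncorrected (`apply_shrink=False`), which
is also what self-assignment does, since in-sample scores are exact.

### Proportion estimation

Breed centroids `c_k` are the arithmetic means of each breed's in-sample
scores.  A target score `s` is assigned proportions by solving

    [c_1 … c_K]ᵀ a = s,  1ᵀ a = 1,

a K × K linear system; negative components are clipped to zero and the
vector renormalized.  The unconstrained (pre-clip) solution is kept on
the estimate (`raw`) for diagnostics.  Clip-and-renormalize was chosen
over a full non-negative quadratic program for transparency and speed;
whenever the unconstrained solution is already interior the two coincide,
and the test suite pins the solver against a 0.001-step brute-force
simplex grid search on random interior instances (agreement < 1e-3 per
component).  Coincident centroids (condition number > 1e12) raise an
error naming the breeds — this is what genuinely indistinguishable
breeds look like to the model.

## Panel curation

Candidate panels carry breed-of-registry labels that can hide recent
admixture, so membership is filtered, not assumed.  The driver runs:

1. fit + self-assign, retain own-breed proportion ≥ **0.97**;
2. cap each breed at **200** by seeded random subsampling;
3. configured breed drops and merges (e.g. collapsing two breeds the
   model cannot separate into one group label);
4. for open-herdbook breeds, replace graded-up members with pedigree
   fullbloods drawn from the candidate pool (a breed with no genotyped
   fullbloods is kept as-is with a warning);
5. fit + self-assign, remove own-breed proportion ≤ **0.60**;
6. fit + self-assign, retain ≥ **0.85**;
7. cap each breed at **50**.

Boundary semantics are read literally: "at least" retains equality,
"at most" removes it.  The model is refit after every membership change
because self-assignment proportions depend on panel composition — stale
weights would bias later passes.  Subsampling uses an independent seeded
stream per breed (seed ⊕ CRC32 of the breed name), so adding or removing
one breed never perturbs another's sample.  Every retain/remove/insert
decision, and any breed eliminated outright, is recorded in a TSV audit
trail.

Curation is a fixed point (idempotent) exactly when every final member's
refit self-assignment clears the 0.97 entry threshold.  On weakly
differentiated panels members can sit between 0.85 and 0.97, in which
case a rerun would trim further; the property is tested on panels
informative enough to clear the margin (12,000 markers, F = 0.3, and an
exactly differentiated toy panel).

## Pedigree expectations

"Fullblood" is a closed-ancestry property: every ancestral path must end
at a herdbook founder of the breed.  Founder flags are input data, never
inferred — an animal with unknown parents and no flag is a pedigree gap
and disqualifies its descendants.  Expected composition halves at each
meiosis (mean of the parents' vectors); unknown parents contribute an
explicit "unknown" pseudo-breed rather than being renormalized away,
because unknown ancestry is a real category in field data.  All
fractions are dyadic rationals and exact in binary floating point; a
grading-up series reaches 15/16 after an F1 plus three sire backcrosses.

## Admixture simulator

Per chromosome and meiosis the crossover count is Poisson with mean
(length in Mb)/100 — the ≈1 cM/Mb rule; on the packaged UMD3.1 table
chromosome 1 (158.34 Mb) gives 1.58 Morgans.  Breakpoints are uniform in
physical position with no interference and no sex-specific map, the
starting strand is a fair coin, and alleles travel with a breed-of-origin
label.  Matings draw two *distinct* parents uniformly from the previous
non-overlapping generation.

Exact ("true") composition assigns each allele the fragment from the
midpoint of the interval to the previous marker to the midpoint of the
interval to the next (chromosome ends extend to 0 and L), sums fragment
lengths per origin breed over both haplotypes, and divides by twice the
covered autosomal length.  The factor of two is a deliberate resolution
of an ambiguity: dividing per-allele sums by the haploid genome size
would total 2.0, so the diploid normalizer is used to keep compositions
on the simplex.  Fragments on each chromosome tile it exactly, so the
vector sums to 1 to machine precision, and an F1 of two pure parents is
exactly 50/50 no matter where crossovers fell.

## Synthetic fixtures

The Balding–Nichols generator stands in for proprietary multi-breed
genotype collections.  Around an ancestral frequency p ~ U(0.1, 0.9),
each breed draws `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `E[p_k] = p`
and `Var[p_k] = F p(1−p)`; haplotypes are Bernoulli draws and markers
are scattered proportionally to chromosome length.  The default panel —
K = 5 breeds, 50 per breed, 7,000 markers, F = 0.2 — mirrors a curated
50-per-breed reference genotyped on a ~7k cross-assay marker
intersection, with F = 0.2 giving breeds that are clearly but not
trivially separable (mean self-assignment ≈ 0.97–0.98).

What the generator does **not** emulate: linkage disequilibrium within
breeds (markers are exchangeable given frequencies), breed-specific
demography or migration, genotyping error, and assay-specific missing
patterns.  Passing tests therefore demonstrate correctness of the
machinery and calibration under drift-only differentiation; they do not
certify accuracy on real cattle data, where LD, selection and shared
breed history (reflected in the model as background "introgression")
all operate.

## Evaluation conventions

Per-individual accuracy is the product-moment correlation between the
true and estimated composition vectors *across breed components* (an
individual-level quantity; a cohort is then summarized by the fraction
of individuals clearing each correlation threshold).  Vectors with zero
component variance have undefined correlation and are flagged rather
than silently dropped.  Small-component pruning removes proportions
strictly below 3% and renormalizes; the boundary value is kept.

## Problem sizes and numerical choices

The test suite and acceptance script run the study-scale panel
(250 × 7,000), a 200-individual cohort per generation over 10
generations of random mating, 100 simulated F1s, 10,000 Monte-Carlo
crossover draws, and a 0.001-step simplex grid (~5·10⁵ points); the full
suite completes in well under a minute on one CPU.  Fixed tolerances:
simplex membership 1e-9, in-sample projection identity 1e-8, true
compositions sum to 1 within 1e-12, eigen-rank threshold
`σ_max · max(n,m) · ε`.  All randomness flows through
`numpy.random.Generator` seeds; per-breed subsampling streams are
decoupled as described above.

## Known limitations

- No binary PLINK (BED/BIM/FAM) or VCF input; text formats only.
- A/T and C/G strand-ambiguous markers are merged only on exact allele
  match; no strand flipping is attempted, and an apparent allele swap at
  such a marker is reported as irreconcilable.
- Global ancestry only — no local (per-segment) ancestry estimation.
- K is fixed by the panel; there is no unsupervised inference of the
  number of ancestral populations.
- The shrinkage calibration is a self-contained leave-one-out scheme; it
  is not claimed to reproduce the numerics of any external projection
  software.
- Allele frequencies assume the panel breeds are large enough that drift
  and selection between panel and targets are negligible; violations
  appear as spurious low-level assignments to unrelated breeds.
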