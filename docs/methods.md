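# Methods

`cavecharr` re-implements, as a tested library, the analysis chain used to
contrast phenotypic and neutral genetic divergence among small, fragmented
Arctic charr (*Salvelinus alpinus*) populations in groundwater-filled lava
caves: microsatellite diversity and differentiation statistics, tree and
isolation-by-distance inference, landmark-based geometric morphometrics,
mark–recapture census estimation, and a structured mixed model partitioning
among-population phenotypic variance into environment-associated (E),
genetic-structure-associated (G) and residual (O) components.  Because the
original field data are not deposited, a first-class synthetic-data module
generates all inputs with known ground truth, and every stage is verified by
recovery, calibration, or exact-oracle tests.

## Population genetics

Genotypes are diploid multi-allelic calls (missing data handled by
genotype-wise deletion per locus).  Per population we report observed
heterozygosity, Nei's unbiased expected heterozygosity
`(2n/(2n−1))(1 − Σp²)`, Weir & Cockerham's (1984) within-population *f*
(F_IS; monomorphic loci excluded), and allelic richness rarefied to *g*
genes, `Ar(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)]`.  Private allelic richness is
the expected number of alleles present in a *g*-gene draw from the focal
population and absent from independent *g*-gene draws from every other
population (product of per-population absence probabilities); the tools used
in classic workflows do not document a single canonical estimator, and this
product form is the defensible choice adopted here.

Differentiation uses three complementary statistics:

* **Weir–Cockerham θ** — ratio of summed variance components
  `Σa / Σ(a+b+c)` over alleles and loci, for any number of populations.
  Significance of pairwise θ uses a bootstrap-over-loci 95 % CI (the
  classic software description of "1000 data permutations" is ambiguous;
  the bootstrap CI is the adopted reading, and a permutation option would be
  a trivial extension).
* **Jost's D_est** — per locus with Nei–Chesser bias-corrected H_S and H_T
  and the `n/(n−1)` deme correction (n = 2); negative per-locus values are
  floored at 0 and loci combined by the harmonic mean (which is 0 whenever
  any locus is 0 — the harmonic-mean limit, stated rather than hidden).
* **Cavalli-Sforza & Edwards chord distance** —
  `D_ce = (2/(πL)) Σ_l √(2 f_l)` with `f_l = 1 − Σ_a √(p q)` clipped to
  [0, 1] against rounding.  Other chord normalizations exist; this one is
  recorded in the output metadata.

Hardy–Weinberg tests are Monte-Carlo exact-style: alleles are shuffled among
the typed individuals of a population × locus cell and the two-sided
statistic |f| compared with its permutation distribution (add-one
corrected).  Allele-frequency heterogeneity between population pairs uses a
per-locus G statistic with a Monte-Carlo null (genotypes permuted between
the two populations), combined across loci by Fisher's method, with Holm
step-down (sequential Bonferroni) adjustment across pairs.  The G/Monte-
Carlo combination targets the same hypothesis as network-algorithm exact
tests at these sample sizes while staying simple and testable.

## Trees and isolation by distance

Neighbour joining follows Saitou–Nei with the Studier–Keppler Q criterion;
negative branch lengths are clamped to zero with the deficit transferred to
the sister branch so the joined pair's path length is preserved, and Q ties
break deterministically toward the smallest label pair.  NJ is exact on
additive distances (tested to 1e-10 on five-taxon trees).  Node support
comes from bootstrap resampling of loci: chord distances and the NJ tree are
recomputed per replicate, and the majority-rule consensus carries supports
as percentages, with branch lengths averaged over the replicates containing
each bipartition.

Geographic distances are great-circle (haversine, R = 6371 km) — at this
site's sub-kilometre extent a planar approximation would differ negligibly,
but the choice is fixed for reproducibility.  GPS strings in
degree/decimal-minute form (`65°34′802″` = 65° 34.802′) are parsed
explicitly.  Isolation by distance linearizes differentiation as
`D/(1−D)` and uses Mantel correlation with simultaneous row/column
permutations (one-tailed positive by default — the directional IBD
hypothesis — two-tailed by flag).  The partial Mantel test residualizes both
matrices on a control matrix (e.g. a binary same-area/different-area
coding) and permutes the residual matrix of the first.  Differentiation
input may be the D_est matrix (the default reading) or any other bounded
differentiation measure — both are accepted because the symbol used for the
linearized statistic is not tied to one estimator.

## Geometric morphometrics

Generalized Procrustes analysis centres each configuration, scales to unit
centroid size, and rotates (reflections forbidden) onto the running
consensus; semilandmarks slide along their neighbour-chord tangents to
minimize Procrustes distance to the consensus (bending-energy sliding is a
possible alternative; the Procrustes-distance criterion is simpler and
standard).  Sliding has a flat direction — a collective displacement of a
semilandmark along the outline changes the objective negligibly — so the
common slide mode is removed at every iteration, and both the initial
reference and the output frame are canonicalized to the principal axes of
the shape.  Consequences, verified by test: aligned shapes are invariant to
arbitrary similarity transforms of the raw input to machine precision; the
non-sliding superimposition is exactly idempotent; the sliding fixed point
re-converges to ~1e-6 (its anchor along the outline is mildly
path-dependent, a property shared by all sliding implementations).
Convergence is declared when the consensus moves less than `tol`
(default 1e-10, max 100 iterations).

Shape PCA operates on the flattened aligned coordinates; component count is
capped at the similarity-reduced dimension `min(n−1, 2k−4)`, percent
variance sums to 100 over retained components, and loading signs are fixed
(largest-magnitude element positive) for determinism.  Procrustes linear
models use sequential (type-I) sums of squares in the fixed order FL,
population, FL×population, with p-values by residual randomization of the
reduced model (add-one corrected).  Discriminant classification reduces to
the leading PCs covering 95 % variance (configurable) before fitting Fisher
LDA; accuracy is reported per group both by resubstitution and leave-one-out
because classic reports rarely state which convention they used.
Mean-shape disparity is the Euclidean distance between per-population mean
aligned coordinates.  Fork length is the allometry covariate for body
models (centroid size correlates only weakly with length in this system);
head analyses run the identical pipeline on the head landmark subset.
Artifact axes (e.g. bending components) are handled by a user-supplied PC
exclusion list rather than any image correction, which is out of scope.

## The variance partition

For an individual shape score `z_ij` (individual *i*, population *j*):

```
E[z]_ij = α + β_L L_i + β_T T_j + β_O O_j + β_D D_j
          + δ_T T_j L_i + δ_O O_j L_i + δ_D D_j L_i
z_ij    = E[z]_ij + g_a,j + g_b,j L_i + c_a,j + c_b,j L_i + e_ij
```

with all covariates mean-centred and unit-scaled.  The `g` intercepts and
slopes are jointly Gaussian across populations with covariance proportional
to a similarity matrix **S** derived from the chord-distance matrix
(`S = 1 − D/max(D)` by default, an exponential kernel by flag; eigenvalues
below zero are clipped to 1e-8 and the matrix rescaled to unit diagonal,
with the repair magnitude logged).  The `c` effects are independent across
populations and `e` is the residual.  Estimation is REML on
log-parameterized variance components (L-BFGS-B, multiple starts, the
Woodbury identity reducing each objective evaluation to operations in the
random-effect dimension); fixed effects are GLS at the optimum.  The
machinery is verified to machine precision against a dense-matrix REML
oracle and against an independent mixed-model implementation in the
reducible random-intercept case.

The partition follows the fixed-effect-variance recovery approach:
`var_env = β' Ɛ_E β` with Ɛ_E the covariance of the standardized
population-level covariates (populations weighted equally, ddof = 1);
`σ_t² = var_env + var_gen + var_cave` (random slopes estimated but
excluded — they are nuisance structure, not a target);
E, G, O are the three shares of σ_t², and repeatabilities are
`σ_t²/σ_T²` and `(var_gen + var_cave)/σ_T²` with `σ_T² = σ_t² + var_resid`.
Note the residual variance and the environmental variance are given distinct
names throughout, since the same Greek symbol is traditionally overloaded
for both.  Uncertainty comes from a parametric bootstrap (simulate from the
fitted model, refit, percentile intervals).

**Identifiability.**  Separating `var_gen` (covariance structured by S)
from `var_cave` (iid) uses only ~20 effective population-level degrees of
freedom at 24 populations.  A Cramér–Rao computation over the eigenvalue
spectrum of any unit-diagonal similarity matrix bounds the standard error
of `var_gen` near 0.2–0.3 when the true components are 0.4/0.2 on a unit
among-population scale — so the G vs O split carries irreducible
uncertainty at this design size, while E (anchored by the measured
covariates) and the total among-population variance are well estimated.
The recovery experiments reproduce this: mean absolute error ≈ 0.10–0.12
for E but ≈ 0.16–0.23 for G and O at 24 populations × 30 individuals.
This mirrors the biological setting, where the same decomposition was
reported as difficult with wide uncertainty bands; conclusions should rest
on E and on the repeatabilities, with G/O read qualitatively.

## Mark–recapture

Census sizes use the two-sample Lincoln–Petersen framework with the Chapman
variant `(M+1)(C+1)/(R+1) − 1` as default — it is defined at R = 0, which
occurs in the smallest caves, and exactly unbiased when `M + C ≥ N`
(verified by exhaustive enumeration for N ≤ 12); the classic `MC/R` is
reported alongside.  The CI is a normal approximation on the Chapman
variance, floored at the number of distinct fish actually handled.
Multi-session data are pooled over adjacent session pairs into a single
two-sample tally — the simplest defensible reduction when only a
closed-population two-sample estimator is in scope (open-population models
are out of scope).  A migrant is a tag observed in two or more populations,
counted once per unordered pair.

## The synthetic generator

The generator emulates the study conditions, and its defaults are fixed at
the study scale:

* **Genetics** — 24 cave populations founded from one source gene pool
  (Dirichlet allele frequencies, 9 loci, 8 alleles each, concentration 0.6,
  giving a diverse source whose drifted caves retain 2–4 alleles per
  locus); genotyped sample sizes equal to the survey's per-cave counts
  (summing to 973) plus two source collections of 50 and 49.  Drift is
  modelled at the frequency level: a founding multinomial draw of
  `2·founders` genes, then one multinomial draw of `2N` genes per
  generation — sufficient for every statistic tested here and much faster
  than pedigree simulation.  `generations` counts *all* drift events
  including the founding draw, so heterozygosity decays exactly as
  `(1 − 1/(2N))^generations` in expectation and `generations = 0` returns
  the source frequencies unchanged.  Defaults: founders 25, 50 generations,
  N = 100.  Colonization timing and founder counts are unknown for the real
  system; these are free parameters, not estimates.
* **Connectivity** — symmetric frequency-level migrant exchange before
  reproduction, defaulting to low within-subarea gene flow (2 migrants per
  generation along chains within the five observed geographic clusters)
  plus the six observed inter-cave mover pairs with counts spanning 1–19.
  This reproduces the observed pattern of subarea-level genetic clustering
  with occasional near-homogeneous connected pairs.
* **Environment** — temperature Normal(5.52, 0.7) °C, openings uniform on
  1–7, distance to the lake uniform on 57–500 m, coordinates jittered
  around two area centres; constant columns are flagged.
* **Phenotypes** — generated directly from the mixed model above, with the
  genetic effects drawn against the *true* similarity matrix computed from
  terminal true allele frequencies through the same chord-distance-to-S map
  used in fitting, so recovery tests are self-consistent.  A helper chooses
  coefficients so the true (E, G, O) equal any requested proportions
  exactly.
* **Landmarks** — a 21-point fish template (15 fixed, 6 sliding
  semilandmarks on the dorsal and ventral outlines) deformed along two
  orthonormal axes — a trait axis (body depth/head robustness) and an
  allometric axis — each Gram–Schmidt-orthogonalized against the template's
  translation, rotation and scaling directions so the signal cannot leak
  into nuisance transforms; isotropic landmark noise (default SD 1 % of
  centroid size), then random similarity transforms.  The default
  deformation magnitudes (0.05 and 0.03 units per SD) give shape signals of
  the order seen in real fish datasets.
* **Captures** — two sessions with a common capture probability (default
  0.5); configured movers change population between sessions.

Randomness uses a single root seed with per-stage child streams
(`numpy.random.SeedSequence.spawn`), recorded in the output metadata;
identical seeds give identical outputs byte for byte.

What the generator does *not* emulate: mutation, selection, sex structure,
overlapping generations, image digitization artefacts (specimen bending),
temporally varying capture probability, or tag loss.  Green tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to those real-data complications.

## Problem sizes used in tests

The test-suite and acceptance-script problem sizes are fixed design
choices: 100 colonization replicates for the drift calibration; 500 and 200
null simulations for the Mantel and Procrustes-ANOVA type-I rates (199 and
99 permutations, which make the nominal 0.05 level exactly attainable with
the add-one correction); 50 replicates at 24 populations × 30 individuals
for the partition recovery; 1000 replicates at N = 200, p = 0.3 for the
Chapman calibration; exhaustive enumeration up to N = 12 where oracles are
combinatorial.
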