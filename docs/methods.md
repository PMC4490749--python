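# Methods

This note records the models, conventions and numerical choices behind
`boneqtl`, and what the synthetic validation does and does not establish.

## Phantoms

A phantom is a digital hollow cylinder (the cortical shell) rasterized by
the center-of-voxel inclusion test: voxel (i,j,k) is bone when its center
(i+0.5, j+0.5, k+0.5) lies between the outer radius and the (optionally
eccentric) bore.  Lacunae are solid triaxial ellipsoids carved from the
wall; canals are straight tubes parallel to Z spanning the full height.
Straight, axis-aligned primitives are deliberate: every downstream metric
then has a closed-form oracle (annulus area, ellipsoid volume and second
moments, constant shell thickness).

Placement is either a regular lattice (used to plant known
spacing-anisotropy) or rejection sampling with a minimum 2-voxel surface
gap.  The gap test is exact-conservative: for a shared fixed orientation,
two identical ellipsoids centered at c₁, c₂ are disjoint when
‖S·Rᵀ(c₁−c₂)‖ ≥ 2 + gap/c with S = diag(1/a,1/b,1/c); random orientations
fall back to bounding spheres.  Wall-containment margins use the
ellipsoid's true axis-aligned extents, so elongated lacunae (long axis
along Z) fit thin walls.  Intensities are two constants (pore/background
vs bone) plus optional additive Gaussian noise; the noise-free histogram
therefore contains exactly two values, which makes Otsu thresholding
exact on clean phantoms.

Randomness: one `numpy` Generator per phantom seeded from the spec;
per-object orientation streams are derived from it, so identical specs are
bit-identical.

Defaults emulate the measurement scale of synchrotron micro-CT of the
mouse femur mid-diaphysis: 1.4 μm voxels, lacunae with semi-axes
(7, 2.8, 2.8) μm ≈ 230 μm³, wall thickness 14 μm.  Phantom lacuna density
(~1.5·10⁵ mm⁻³) is above physiological (2–9·10⁴ mm⁻³) because the test
volumes are small; densities are ratios, so this does not bias the
estimators being validated.

## Segmentation

Bone = voxels at or above a grayscale threshold (fixed or Otsu).  Candidate
pores are non-bone voxels enclosed by the bone shell, found by 2D
hole-filling each Z-slice (the bore and canals are open along Z, so a 3D
fill would miss them).  The medullary cavity is itself a 2D hole; the
largest connected pore component is returned to background when it exceeds
10% of the filled shell volume — intra-cortical porosity is orders of
magnitude smaller than the marrow cavity, so the rule has a wide safety
margin on real anatomy and on every phantom.

Pore components are labeled with 26-connectivity and classified by volume
alone: lacuna within [lo, hi), canal at or above a minimum, anything
smaller discarded as speckle.  The defaults (lacunae 50–1000 voxels,
canals ≥ 1000 voxels at 1.4 μm) separate the default phantom's object
volumes (~84 vs ~1700 voxels) by an order of magnitude; both ranges are
parameters because real canal networks vary.  Components touching the
volume border are flagged: they stay in the density counts (their
existence is certain) but are excluded from shape statistics (their shapes
are clipped).  A flag on the lacuna accessors lets users flip this.

## Morphometry

**Shape.**  Principal half-lengths come from the voxel-center covariance:
Lᵢ = √(5λᵢ), exact for solid ellipsoids (second moment a²/5 along a
semi-axis a).  A 1/12·I term adds each voxel's own second moment so
single-voxel-thick objects keep L ≥ half a voxel.  Stretch = 1 − L₃/L₁:
0 for a sphere; both extreme rods (a ≫ b = c) and extreme plates
(a = b ≫ c) approach 1.  Voxelization keeps a (10,4,4) ellipsoid within
±0.05 of the continuous value 0.6, verified across orientations.

**Radial cortical thickness.**  Per Z-slice the bone-phase centroid is the
ray origin; `n_theta_bins` (default 360) equally spaced rays sample the
(by default hole-filled) bone mask at 0.25-voxel steps via linear
interpolation, and thickness(θ,z) runs from the first to the last 0.5
crossing, each refined by linear interpolation between samples.  Pores
count as bone by default ("shell envelope" thickness); a `solid_thickness`
flag excludes them.  Bins with no crossing are skipped with a warning;
slices whose centroid falls inside bone (the shell does not surround its
own centroid) contribute no bins; if more than half of all bins are
invalid the shell is declared not closed.  The mean and sd pool all valid
(θ,z) bins with equal weight — thickness is angle-weighted, not
volume-weighted, and slices are not averaged first.  On a concentric
digital cylinder the result is constant to < 0.25 voxel from 16 bins up.

**Distribution oblateness.**  For every lacuna centroid the unit
directions to its k = 6 nearest neighbors are pooled (neighbors tied with
the k-th distance included, so regular lattices pool symmetric sets) into
a 3×3 direction tensor with eigenvalues μ₁ ≥ μ₂ ≥ μ₃.  Directions along
which lacunae sit close contribute most near neighbors, so the neighbor
cloud is the *dual* of the spacing ellipsoid: prolate spacing (close in
two orthogonal directions) gives a planar cloud, oblate spacing a linear
one.  We report Ob = 1 − 2(μ₂−μ₃)/(μ₁−μ₃): negative = prolate spacing,
positive = oblate.  Unit directions rather than raw displacements are
used because distance² weighting lets a handful of far tied neighbors
dominate the tensor and can flip the sign on planted lattices.  When
(μ₁−μ₃)/μ₁ < 0.05 the distribution is reported isotropic with Ob = 0.
Fewer than k+1 lacunae → missing.  The statistic is a designed stand-in
for the qualitative prolate/oblate notion; only its sign and isotropy
behavior are treated as meaningful.

## Cross simulation

An F2 gamete is a Markov walk along each chromosome with Haldane
recombination r(d) = (1−e^(−2d/100))/2 — no crossover interference, which
matches the mapping HMM's Markov assumption exactly, so simulator and
estimator share one model and HMM correctness is testable to machine
precision.  A genotype is the sum of two independent gametes; missingness
is masked at a configurable rate.  The default map has 19 mouse-like
autosomes (57–103 cM, total 1435 cM) carrying 98 roughly evenly spaced
markers; cohort defaults are 755 F2 and 12 F1 animals with P(male) = 0.47.
Phenotypes are y = Σ(a·x + d·z) + interactions + sex effect + ε with
x ∈ {−1,0,+1}, z = 1(het); F1 phenotypes are intercept + ε only, which is
what makes the F1/F2 variance-ratio heritability estimator available.
QTL may sit between markers; the simulator then carries the true genotype
at the planted position internally.

The cross CSV dialect is the de-facto intercross format: row 1 column
names (phenotypes and sex first, then markers), rows 2–3 chromosome and
cM position under the marker columns, one row per individual after.

## Genotype probabilities

States {AA, AB, BB} with prior (¼,½,¼); transitions between adjacent grid
points from the two-gamete Haldane matrix; emissions 1−ε for the observed
code, ε/2 otherwise (default ε = 10⁻⁴), uniform for missing.
Forward–backward (normalized, vectorized over individuals) gives marginal
posteriors on the union of a 2 cM grid and the marker positions; backward
sampling yields posterior path draws (default 128) for imputation-style
scanning.  Draws cannot improve the forward–backward marginals — they are
provided as an alternative scanning route, not as a better estimate; the
default scan uses the probabilities directly.  An exhaustive two-gamete
enumeration oracle (exponential in positions, used on ≤ 4-position
chromosomes) pins the implementation to 10⁻¹² accuracy.

## Scans, thresholds, penalties, model search

**Extended Haley–Knott.**  At each position the phenotype is regressed on
x̂ = P(BB)−P(AA) and ẑ = P(AB) plus intercept and sex (and x̂·sex, ẑ·sex in
interactive-covariate mode; a constant sex vector falls back to additive
with a warning).  The extended form models per-individual residual
variance σ² + gᵢᵀVᵢgᵢ, where Vᵢ is the posterior covariance of (x̂ᵢ, ẑᵢ)
and gᵢ the individual's genetic coefficient vector, by iteratively
reweighted least squares: WLS for β, up to three Newton steps for σ², an
outer update of the inflation terms, iterated until the relative
log-likelihood change is below 10⁻⁸ (monotone-guarded, max 25 iterations,
converged positions dropped from the active set).  LOD is the log₁₀
likelihood ratio against the intercept+sex null, clipped at 0 (the models
are nested).  At fully typed markers the inflation vanishes and plain HK,
extended HK and the three-group ANOVA LOD (n/2)·log₁₀(RSS₀/RSS₁) coincide
to 10⁻⁶.

**Permutation thresholds.**  Phenotypes are permuted within sex strata
(sex is an interactive covariate; permuting across strata would destroy
its association), each permutation scanned genome-wide, and the threshold
taken as the type-7 (linear interpolation) 1−α quantile of the maximum
LODs.  Permutation scans use plain HK by default — identical at typed
markers, indistinguishable under the null, and orders of magnitude cheaper
batched; `method='ehk'` is available.  With n_perm = 100 the type-7
quantile sits slightly below the exchangeability-exact threshold, so the
realized type-I error is ≈ 0.055–0.06 rather than 0.050; this is a
property of the stated quantile rule, measured by the calibration
experiment, not corrected for.

**Penalties.**  For each permutation a two-locus scan over all
cross-chromosome pairs of a 10 cM coarse grid records the maxima of the
full (four interaction products), additive and single-locus LODs.
T_main = q₁₋α(max single), T_heavy = q₁₋α(max full − max single),
T_light = q₁₋α(max full − max additive), with T_light capped at T_heavy.
Two-locus fits are plain HK with precomputed per-pair Gram matrices.
Scaled-down permutation counts are flagged in the result.

**Model search.**  pLOD(model) = LOD − T_main·#loci − T_heavy·#(QTL×QTL) −
T_light·#(QTL×sex).  QTL×QTL interactions take the heavy penalty and
QTL×sex the light one — the permutation construction does not dictate the
assignment and this is the simplest choice consistent with
T_heavy ≥ T_light.  Forward steps greedily add the best locus (a genome
scan with the current model as covariates; LOD additivity of nested OLS
fits makes this exact) or the best interaction, up to `max_qtl` (default
10); backward steps delete the weakest term down to the empty model; the
best model visited anywhere wins, and nothing beating pLOD = 0 returns the
empty model.  Multiple-QTL fits are HK regressions on the expected
genotype scores.  Argmax ties break leftmost (smallest chromosome index,
then cM).

**Attribution, intervals, refinement.**  Per-term % variance = 100·(RSS
without the term − RSS full)/TSS, with a locus's interactions removed
along with it; dropped LOD analogously.  Support intervals span the
outermost grid points within `drop` (default 1.5, the conventional ≈95%
region for an intercross) of the peak.  Refinement recomputes genotype
probabilities on a 0.1 cM grid within ±15 cM of each locus and re-profiles
each position holding the others fixed, one pass in order, never
decreasing the model LOD; the dense LOD curves and their support intervals
are attached to the returned model.

## Heritability

H² = 100·max(0, 1 − Var(F1)/Var(F2)) with sample variances; selection is
strictly greater than the criterion (default 40%), so H² exactly 40 is not
selected.  With 12 F1 animals the estimator is noisy — Var(F1) has ~40%
relative error — which is a property of the emulated design, not of the
estimator; the validation uses larger F1 cohorts when testing the
estimator itself.

## Validation experiments and problem sizes

`boneqtl.experiments` regenerates everything from a seed:

- HMM vs enumeration: 8 individuals, 3 markers, every grid position.
- HK vs ANOVA: 755 animals, all markers of one chromosome, both methods.
- Type-I calibration: one null cross of 200 animals on the 19-autosome /
  98-marker map, 10 cM grid; 400 trials, each drawing a fresh N(0,1)
  phenotype, deriving its own 100-permutation threshold and scanning
  itself.  200 animals (vs 755) keeps the experiment at seconds per dozens
  of trials; calibration of a permutation test is sample-size-free.
- Recovery: 100 crosses of 755 animals, two additive QTL (a = 0.8, σ = 1)
  on chromosomes 3 and 9; penalties derived once from 256 permutations of
  the first replicate (the 95% quantile at 64 permutations is itself noisy
  enough to shift every replicate's spurious-locus rate together); success
  = exactly two loci, each within 15 cM.
- Variance attribution: a = 1, σ = 1 at a typed marker (between markers
  the expected-genotype regressor is attenuated by construction), averaged
  over 5 crosses of 2000 animals.
- Morphometry analytics and end-to-end conservation as described above.

## What the phantoms do not show

Phantoms have constant-intensity phases, no reconstruction artifacts
(rings, beam hardening, phase fringes), straight canals, a single lacuna
shape per volume and convex shells.  Passing tests therefore demonstrate
the correctness of the estimators on their stated geometric models, not
robustness to real scan pathology; segmentation parameters for real data
remain the user's responsibility.  Likewise the genetic simulations assume
no crossover interference, no genotyping-error structure beyond the
symmetric emission model, autosomes only, and Gaussian environmental
noise.

## Known limitations

- Volume I/O is multi-page TIFF (+ CSV tables); no NRRD.
- Classification of pores is by volume only; merged lacunae are not split
  (no watershed), and a lacuna touching a canal would be absorbed into it.
- The X chromosome is out of scope throughout.
- The search space for interactions is pairs of loci already in the model;
  exhaustive two-dimensional scans are used only for penalties.
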