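# Methods

This package re-implements, as a tested pipeline, a comparative analysis
of how the eel (Anguilliformes) locomotory system evolved: body-shape
quantification, lateral-tendon length estimation from fossilised
myoseptal bones, morphospace comparison of extinct and extant eels,
time calibration of a composite phylogeny, phylogenetic-signal
estimation and ancestral-state reconstruction. Museum measurements are
not redistributable, so a synthetic-data generator reproduces the
statistical structure the analyses assume; every stage also accepts
real measurement tables in the documented CSV schemas.

## Vertebrate shape index (morphometrics)

Body shape is summarised by the vertebrate shape index

    VSI = L_axis1 / L_axis2
        + L_head_in_vertebrae * AR_head
        + N_PCV * AR_PCV
        + N_CV  * AR_CV

with `L_axis1` the standard length (mm), `L_axis2` the maximum body
depth (depth rather than width, because fossils are preserved in lateral
view), `L_head_in_vertebrae` the head length in vertebral-centrum units
(fractional values allowed), `N_PCV`/`N_CV` the precaudal/caudal
vertebral counts and `AR_*` length-to-height aspect ratios — for the
vertebral terms, the mean over three selected centra per region. Every
term is dimensionless, so VSI is invariant under uniform rescaling, and
the formula is linear in the counts (one extra caudal centrum adds
exactly `AR_CV`).

Two conventions are deliberate. First, no rule is published for *which*
three centra enter each regional aspect ratio; the default picks the
centra nearest 25%, 50% and 75% of the region's ordinal span, which is
reproducible and overridable by explicit indices. Second, the formula
is evaluated exactly as printed; whether head aspect ratio should be
length/depth or its inverse is left to the input table.

## Lateral-tendon length from ossified myoseptal bones (tendon)

In fossil eels the epineural (ENB) and epipleural (EPB) bones preserve
the myoseptal attachment line on the vertebral column. An element that
attaches on centrum N and crosses k further centra ("N + k") gives an
attachment span of k + 1 vertebrae; the lateral tendon — and hence the
myoseptum — extends one further segment for the anterior cones, a
correction calibrated on extant *Anguilla*, so tendon length is k + 2
vertebral units. Fractional k is carried exactly (the longest fossil
value, 4.5 vertebrae, comes from k = 2.5). When a count is a range
("N + 1/2"), the estimator uses the upper bound — the only choice
consistent with the published per-taxon totals — and reports the
lower-bound length alongside. When only one body side is preserved the
other is mirrored and flagged `inferred`, relying on the
epaxial/hypaxial symmetry of the musculotendinous system. Myorhabdoid
and posterior-oblique tendons locate %TL positions but never enter the
length estimate. Tendon length can also be expressed as a fraction of
total length by summing the spanned centrum lengths (fractional last
centrum pro-rated linearly); %TL positions are measured from the snout.

## Morphospace (regression, PCA, hull overlap)

Standard length is regressed on total vertebral count by OLS
(statsmodels), with a pointwise 95% confidence band from the t
distribution on n − 2 df. The eight VSI component variables are
ordinated by PCA; because they mix millimetres, counts and ratios, the
default is the correlation matrix (covariance mode is retained as an
option). Components are ordered by eigenvalue and each loading column
is oriented so its largest-magnitude entry is positive — a fixed,
reproducible sign convention. Rows with missing variables are excluded
with a logged warning rather than imputed.

Group overlap in a chosen component plane uses convex hulls
(scipy.spatial); a taxon overlaps if it lies inside the *other* group's
hull, boundary inclusive (half-plane test at 1e-9), which is the
conservative direction for claiming separation. Groups need at least
three taxa for a non-degenerate hull.

## Tree calibration (phylocomp)

The composite tree is dated from three kinds of evidence, never
adjusted silently:

1. **Node constraints** on named MRCAs: `fixed` ages are taken as-is
   (error if younger than a descendant fossil), `minimum` ages are
   raised to the oldest descendant first occurrence when the fossil
   record demands it.
2. **Tip occurrences**: each terminal branch extends to the tip's first
   occurrence (0 Ma for extant tips). Ghost lineages need no special
   handling — branch duration is parent age minus child age.
3. **Bracket interpolation**: every remaining internal node takes the
   mean of its nearest dated ancestor and its oldest dated descendant,
   applied root-to-tips so the rule is deterministic on chains of
   undated nodes.

An unconstrained root takes its oldest dated descendant's age — dates
are hard minima, so the tree is as shallow as the evidence allows. A
parent *younger* than its child raises an error listing both ages.
Zero-length branches can arise legitimately (a minimum constraint met
exactly by its oldest fossil); they are kept in reported ages and
handled in covariance inversion by a 1e-6 diagonal jitter only.
Polytomies are preserved throughout — the composite tree's extensive
polytomies are used as-is by the covariance construction and the
parsimony pass.

## Phylogenetic signal

The Brownian covariance is `C[i,j] = root age − age(MRCA(i, j))` in Ma
elapsed from the root, built natively on polytomous trees.

**Blomberg's K** compares the observed ratio of the trait's variance
around the GLS mean to its phylogenetically corrected variance,
MSE0/MSE, with the value that ratio takes under Brownian motion,
`(tr C − n/Σ C⁻¹) / (n − 1)`; K ≈ 1 under BM, < 1 when relatives
resemble each other less than BM predicts. Significance is a tip-label
permutation test (default 999 permutations, seeded, seed recorded in
the result). On a star tree C is diagonal, so K is identically 1.

**Pagel's λ** multiplies the off-diagonal entries of C by λ (diagonal
unchanged) and is estimated by maximum likelihood with the ancestral
mean and Brownian rate profiled analytically at each λ; the bounded
search runs on [0, λ_max], where λ_max keeps C(λ) positive-definite,
capped at 1.2 so estimates near 1 are not truncated by numerics. The
reported estimate is the best of the interior optimum and the
boundary/reference points {0, 1, λ_max}. The p-value is a
likelihood-ratio test against λ = 0 on 1 df. Both statistics are
invariant under affine transformation of the trait.

## Ancestral states (squared-change parsimony)

Ancestral tendon lengths are reconstructed by squared-change parsimony
with all branch lengths set to 1 — divergence times deliberately
ignored, matching the published procedure (a squared-change reading of
the "parsimony method"; linear/Wagner parsimony would be a possible
extension). The minimised objective Σ(parent − child)² is quadratic,
so the subtree cost below each node is a parabola in the node's value;
a postorder pass combines children's parabolas (polytomies sum
naturally) and a preorder pass fixes each node at its conditional
minimiser. This is exact and deterministic; the test suite checks it
against coordinate-wise grid minimisation at step 1e-3.

## Synthetic data

The generator emulates the features the analyses rely on:

* **Specimens**: two groups at the study's scale (8 extinct + 31 extant
  by default). Extant defaults: precaudal counts N(55, 8), caudal
  N(95, 12), centrum aspect ratio N(1.35, 0.15); extinct taxa have
  fewer vertebrae (N(42, 8) + N(70, 12)) with shorter centra
  (AR N(1.05, 0.15)) — the direction the fossil material shows. Counts
  are rounded normals truncated at a 40-vertebra total (anguilliform
  realism); standard length is log-normal (median ≈ 490 mm); per-centrum
  lengths are set so the column fills the postcranial body, heights
  follow from the aspect ratio, and the tabulated `AR_*` values are
  recomputed from the generated centra so records are internally
  consistent. Group offsets are configurable in sign and size
  (`config_with_separation(d)` sets the means d pooled SDs apart;
  d = 0 is an exact null).
* **Trees**: a seeded pure-birth simulator conditioned on n tips, with
  one extra waiting interval after the n-th lineage so the expected
  root age is the closed form Σ_{k=2..n} 1/(k·birth_rate) — which the
  tests verify by Monte Carlo.
* **Traits**: one multivariate-normal draw with covariance
  σ²·C(λ_true), giving exact null (λ = 0) and alternative models for
  the signal estimators.
* **Tendon observations**: one ENB and one EPB per taxon at requested
  traversal counts; in the full fixture the counts derive from a
  Brownian trait on the simulated tree (mapped to half-vertebra steps
  in [0.5, 3]), so the downstream signal stage has real structure to
  find. %TL extents are drawn in a posterior-body window (85–97 %TL by
  default).

One root seed derives fixed-offset substreams per stage, so a stage can
be re-run in isolation and full fixtures are byte-identical per seed.

What the generator does **not** emulate: measurement error and
preservation-driven missingness of real fossils, allometry between
head/body proportions and size beyond the simple proportions used,
taxonomic sampling structure (tips are exchangeable), and any
correlation between tendon length and body shape. Passing tests
therefore demonstrate the pipeline's correctness and statistical
calibration, not the biological conclusions, which require the real
measurement tables.

## Problem sizes and numerical choices

Simulation-based checks use a 64-tip tree with 500 replicates for the
K calibration (mean within [0.9, 1.1]) and a 128-tip tree with 200
replicates for λ recovery at λ_true = 0.7 (mean within ±0.1) — sizes at
which both estimators' sampling error is well inside those bands.
Morphospace recovery uses 100 seeded runs at the study's 39-specimen
scale. Matrix inversions go through Cholesky factorisation where
possible; singular covariances (zero-length branches) get a 1e-6
diagonal jitter for inversion only. Hull membership uses a 1e-9
half-plane tolerance. CSV round-trips preserve lengths to 3 decimals
(mm) and ages to 1 decimal (Ma) — a repository convention, since the
source material does not state a measurement precision.

## Known limitations

* Squared-change parsimony is implemented; linear (Wagner) parsimony is
  not.
* The λ likelihood-ratio test uses the χ²(1) reference even though
  λ̂ = 0 sits on the boundary (conservative by about a factor of two).
* Calibration has no notion of soft maxima or tip-dating uncertainty;
  dates are hard minima by design.
* The regression stage fits a single pooled OLS; no per-clade or
  phylogenetic (PGLS) regression.
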