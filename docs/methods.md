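# Methods

## The analysis chain

The pipeline mirrors how immigration-gradient gut-microbiome experiments
are analysed. Counts are aggregated to bacterial families (unmapped taxa
bucket into `unassigned` by default; a strict mode errors instead), the
table is restricted to the focal families that were experimentally
introduced, and each host's row is relativized. Samples with zero focal
abundance cannot be relativized; they are excluded and logged rather than
silently dropped or zero-padded — at strong dilutions "nothing focal
established" is a real outcome, and the exclusion list is part of the run
report. Downstream operations re-check that relative rows sum to 1 within
1e-9 instead of re-normalizing silently.

α-diversity is reported as Hill numbers: richness (q = 0, a strict
p > 0 presence rule with no pseudo-count floor, since inputs are already
filtered tables) and inverse Simpson (q = 2). Community size is the
per-sample 16S rRNA copy number from qPCR, not the read total — read depth
is an artifact of library preparation; copy number is the abundance proxy.

## β-diversity as multivariate dispersion

Raw pairwise dissimilarities are not independent, so β-diversity is
quantified as dispersion: the mean distance of group members to their
group's center in principal-coordinate space, per immigration × instar
cell. Choices, and why:

* **Square-root transform** (default on): Bray–Curtis is a semimetric and
  its PCoA can have negative eigenvalues; the element-wise square root is
  monotone (pair order preserved) and makes the matrix closer to
  Euclidean-embeddable.
* **PCoA keeps imaginary axes.** Gower-center −½D², eigendecompose, scale
  eigenvectors by √|λ|. Axes with λ below −tol form the imaginary block;
  |λ| ≤ tol with tol = 1e-8 × max|λ| is treated as numerical rank noise and
  dropped. Squared distances are then reconstructed as (real block) −
  (imaginary block), which reproduces the input squared dissimilarities to
  1e-6; this identity is the module's core invariant and is tested on both
  Euclidean and non-Euclidean inputs. Ready-made PCoA implementations
  discard the negative eigenvalues, which would break this contract.
* **Spatial median, not centroid** (centroid available as an option). The
  geometric median is computed per block by damped Weiszfeld iteration
  (damping 0.9, convergence when the iterate moves < 1e-10, max 1000
  iterations). n = 1 returns the point; n = 2 returns the midpoint, the
  symmetric representative of the non-unique minimizer, so output is
  deterministic.
* **Subtractive distance with clamping.** A sample's distance to the
  center is √(max(0, d²_real − d²_imag)); the clamp is applied at distance
  evaluation only, never inside the eigendecomposition.
* **Bias adjustment** (default on): distances are multiplied by
  √(n/(n−1)), counteracting the small-sample downward bias of
  distance-to-center estimates.

Groups with fewer than two members have no defined dispersion; they are
skipped with a warning and listed in the result. The whole configuration
is cross-checked in the tests against vegan's
`betadisper(type = "median", bias.adjust = TRUE, sqrt.dist = TRUE)`
(agreement ~1e-7 on a 10-sample fixture).

## The null model and β-deviation

The null asks: how much β would groups show if each host were assembled by
stochastic sampling from its treatment pool, holding fixed what we know
about the host — its focal richness S and its community size N? Abundances
are integerized (round to nearest; any taxon with positive real abundance
keeps ≥ 1 individual so S is well defined), then each replicate draws, for
every host, S taxa without replacement with probability proportional to
pool proportions, seats one founding individual per selected taxon, and
distributes the remaining N − S individuals multinomially over the
selected taxa (renormalized pool proportions). Both constraints hold
exactly in every draw with no rejection step; a rejection-sampling variant
is available for sensitivity analysis. Equal pool proportions — the
experimental design — make the selection uniform.

Observed and null group β are computed by the *identical* pipeline
(integerize → relativize → Bray–Curtis → sqrt → PCoA → spatial median →
bias adjustment), on the group's own samples, so integerization noise and
every adjustment are symmetric between the two. SES uses the SD of the
null replicate distribution (denominator n_reps − 1), the standard
standardized-effect-size convention; a null SD of zero (e.g. every host at
S = N, forcing the single all-ones community) flags the group degenerate
and reports SES as NaN rather than ±∞. Each group consumes an independent
RNG substream keyed by a CRC-32 of its label, so adding or removing a
group never perturbs another group's draws, and results are
bit-reproducible given (seed, n_reps, inputs).

## The synthetic experiment

The generator reproduces the statistical structure of the design, not its
microbiology. Six treatment pools share five focal families at equal
proportions; densities are base_density × 10^e for e = 0 … −5 with
base_density = 1.69 × 10⁵ CFU/μL (the undiluted mix). Per host, ingested
propagules per taxon are Poisson(colonization_scale × density ×
proportion) — colonization_scale defaults to 2.0, the μL volume of an
inoculum dose — and each propagule establishes with probability 0.1.
Within-host dynamics are discrete growth-then-resample generations
(Wright–Fisher with selection): counts multiply by per-taxon growth
factors, rescale proportionally at the carrying capacity, then a
multinomial resample of min(total, drift_size) individuals injects
demographic drift. One parameter s spans the drift↔selection axis: the
advantaged taxon grows by growth_rate × (1 + s), all others by
growth_rate; s = 0 makes taxa exchangeable and leaves expected composition
a martingale.

Hosts are sampled destructively: stage-3 (3rd instar) samples are
colonization outcomes recorded 24 h post inoculation, stage-5 samples are
*different* hosts of the same treatment carried through
n_generations_between_stages = 10 generations. Host ids link treatments,
not individuals, across stages. As in the real design, instar and elapsed
time are confounded; the simulator makes no attempt to separate them.
qPCR-like totals are the realized within-host total under log-normal
multiplicative noise (σ = 0.1; no error model is published, so a modest
multiplicative noise is assumed). Optional features, off by default:
a molt bottleneck between stages (the gut lining is shed at molts, but its
severity is unquantified) and non-focal background colonists (log-normal
abundances) that exercise the focal-subsetting path.

**Effective community size.** carrying_capacity = drift_size = 2000
effective individuals, far below the census of 16S copies. This is
deliberate: the capacity sets drift strength, and with a two-fold
advantage (s = 1) it leaves non-advantaged families at count scales where
local extinction over an ontogeny is common. That extinction produces
among-host richness variation at the 5th instar, which is precisely what
lets the null model distinguish selection from sampling: observed hosts
converge on the dominant family while null hosts, spread evenly over each
host's surviving families, do not — hence strongly negative β-deviations
at high immigration, weakening toward the dilute treatments. With a much
larger effective size no family ever goes extinct, every host keeps S = 5,
and the convergence signal cannot arise at any selection strength.

**What the generator does not emulate:** real 16S read-count
overdispersion and compositional sequencing artifacts, taxon-specific
colonization ability, host immune feedbacks, strain-level variation, and
ongoing immigration after the single inoculation (the experiment's
controls showed focal dynamics reflect within-host growth, and the
simulator inoculates exactly once). Passing tests therefore demonstrate
the statistical machinery and its expected behavior under the design — not
that any particular biological parameter value is realistic.

## Interpretation note: drift and the sign of SES

"Drift yields SES ≈ 0" holds when assembly is stochastic sampling from the
pool — the situation at colonization. The package's calibration check
(data generated by the null process itself: 20 groups of 8, 500 replicates)
recovers SES centered on 0 with a nominal share of |SES| > 1.96, and
stage-3 simulated groups behave the same. After colonization, however,
*demographic* drift at finite effective size adds compositional variance
beyond pool sampling, so stage-5 groups under s = 0 show positive
β-deviations (divergence) — the documented behavior of abundance-based
null models, and the reason the drift regime is characterized by the
*absence of the declining SES trend* across the immigration gradient
rather than by SES = 0 at every stage.

## Problem sizes and numerics

Default n_reps = 1000 for the null model; the test suite and acceptance
script use 200–500 replicates with 7 replicate hosts per treatment × stage
cell, sizes at which every reported quantity is stable to well within the
tolerances asserted. Closed-form identities (Hill q = 2, Bray–Curtis vs.
half-L1) are exact to 1e-12; ordination reconstruction to 1e-6; dispersion
against direct Euclidean geometry to 1e-6. CSV outputs use '.' decimals,
UTF-8 and LF endings, so identical configurations produce byte-identical
outputs.
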