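# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, in the order the data flow through it.

## Surface processing

**Height maps.** A surface is a regular grid of elevations in µm with
spacings `dx`, `dy` (default geometry mirrors a 146 × 100 µm field at
0.44 µm lateral sampling: 332 × 228 points) and a per-point validity
mask.  Non-measured or masked points are excluded from every fit and sum
with area-weight renormalisation and are never interpolated; interpolation
would manufacture texture at exactly the scales being measured.  Stages
advance strictly `raw → levelled → form_removed → scale_limited` so a
parameter set can always be traced to a fully processed surface.

**Spike masking.** Instead of interactive point deletion, spikes are
flagged where the residual from a 5 × 5 local median exceeds 8 robust
standard deviations (1.4826 × MAD) of all residuals.  The threshold is
deliberately conservative: losing a few per cent of valid points is
harmless (parameters renormalise), while an unmasked +10 µm spike
dominates every moment-based parameter.

**Levelling and form removal.** Levelling subtracts the OLS plane
(arbitrary specimen orientation under the objective).  Gross tooth form
(crown curvature) is removed by a bivariate polynomial of total degree 5,
fitted by iteratively reweighted least squares with Tukey's biweight at
scale 4.4478 × median |residual| — the ISO 16610-71 robust convention —
for ≤ 50 iterations with relative coefficient tolerance 1e−6.
Coordinates are rescaled to [−1, 1] before building the Vandermonde
matrix; without that, a degree-5 fit on coordinates of order 10² µm is
numerically rank-deficient.

**Gaussian regression filter.** Waviness/roughness separation uses a
second-order areal Gaussian regression filter: at every grid point a local
bivariate quadratic is fitted under a Gaussian weight centred there, and
the fitted value is the waviness.  The regression formulation needs no
boundary padding — weights simply renormalise over existing points —
which matters on fields only ~300 samples across, where padding a
convolution filter would distort a noticeable fraction of the area.  The
per-pixel normal equations are assembled from 21 moment images computed
by FFT correlation, so one pass costs a handful of FFTs regardless of
kernel size.

A degree-2 regression filter with the classical Gaussian constant
α = √(ln 2/π) transmits ~84.7% (not 50%) of a sinusoid at the cutoff:
solving the weighted quadratic fit analytically gives a low-pass
amplitude characteristic

    T(λ) = (1 + t)·e^(−t),   t = σ²k²/2,  k = 2π/λ.

The kernel width σ is therefore calibrated so that T(λc) = 1/2 exactly:
σ = λc·√(2t*)/2π with (1 + t*)e^(−t*) = 1/2, t* ≈ 1.67835.  The closed
form above is also the independent oracle the tests check measured
transmissions against (50% at λc, ≥ 99% roughness at λc/10).  Robust
mode re-weights points by Tukey's biweight of the roughness residual and
repeats until the waviness change falls below 1e−6 relative.  Roughness
is defined as input minus waviness, so reconstruction is exact at every
valid point by construction.

**ISO 25178-2 parameters.** Heights are re-centred to a zero-mean plane
first.  Sal/Str scan the masked, zero-padded FFT autocorrelation along
180 directions in half-pixel steps (bilinear interpolation) for the first
crossing below s = 0.2; when the slowest direction never decays inside
the half-field, Str is computed against the half-field extent and
flagged.  Std is the lay direction (angular power-spectrum maximum,
rotated 90° from the spectral direction; ridges along x give Std = 0°).
Sdr uses triangulated facet area (two triangles per cell, cells with all
four corners valid); Sdq uses central differences, one-sided at borders.
Material-ratio quantities use the ISO default thresholds: Smc at 10%,
Smr at 1 µm below the mean plane, Sxp between 2.5% and 50%, Vmp at 10%,
Vmc 10–80%, Vvc 10–80%, Vvv at 80%, integrating the quantile function on
a 2001-point grid.  Degenerate inputs flag rather than raise where a
value is conventionally reported (constant surface: Sa = Sq = 0 with
Ssk/Sku undefined).

## Guild framework and screen

Dietary compositions are volumetric proportions over six prey categories
(tetrapods, fish, harder/softer/softest invertebrates, plants).  Guild
assignment is deterministic: omnivore when plants ≥ 10% accompany animal
prey, otherwise the dominant prey category (≥ 50% of identified volume)
names the guild; ties and all-zero compositions raise for manual
resolution, because silently picking a guild would propagate into every
downstream statistic.

Texture tables are log10-transformed (the DMTA literature convention;
the base is a parameter) with Ssk dropped.  The screen runs per
parameter: median-centred Levene at α = 0.05 selects classical versus
Welch ANOVA; raw P values across all testable parameters form a single
Benjamini–Hochberg family at FDR 0.05; significant parameters get Tukey
HSD (Tukey–Kramer under unequal n) pairwise comparisons with no further
correction, since the studentized-range test already controls its own
family.  Parameters constant within every guild are reported untestable
and excluded from the B–H family rather than contributing P = NaN.

## Ordination

The texture-dietary space is an eigendecomposition of the correlation
matrix of the selected log-parameters over framework specimens only
(individual specimens, not species means).  Correlation rather than
covariance because ISO parameters span orders of magnitude; covariance
mode stays available via `scale=False`.  Eigenvector sign is arbitrary,
so each axis is oriented to make its largest-|loading| entry positive —
scores are then bit-reproducible across runs and platforms.  Projection
of unknowns applies the stored centring/scaling/loadings; the model is
immutable, so fossils cannot restructure the space they are being read
against.  Spearman correlations use average ranks with exact permutation
P for n ≤ 9 and the t approximation otherwise; group separation uses the
pooled two-sample t (df = nA + nB − 2); the ontogeny regression reports
Spearman r_s plus an OLS line with pointwise 95% confidence band.

## Phylogenetic machinery

**Time calibration ("equal" rule).** Node ages start at the maximum
first-appearance date (FAD) of their descendants; the root is pushed back
by a configurable extension (default 2 Myr — required, since the basal
node otherwise sits exactly at the oldest FAD).  Tips are dated at FAD.
Each remaining zero-length branch takes a share of the nearest ancestral
positive branch: node ages along the chain from the top of that branch to
the zero branch's child are re-spaced equally.  Moved nodes only get
older, so no new zeros appear and the procedure terminates with all
branches positive and every root-to-tip path preserved.

**Covariance.** All comparative methods run on the Brownian-motion
variance–covariance matrix (root-to-MRCA shared path lengths, Myr),
assembled in one postorder pass; polytomies are genuine multifurcations.
Nodes are labelled by their sorted descendant tip sets ("A|B|C"), immune
to the index drift of numbering schemes across prunings.

**Blomberg's K** uses the MSE0/MSE ratio about the phylogenetic GLS mean,
normalised by its Brownian expectation (tr C − n/(1'C⁻¹1))/(n − 1);
P values come from seeded tip permutations ((1 + #{≥ observed})/(n+1)),
default 999, with the seed recorded.  **Pagel's λ** is maximised by
bounded scalar search (tolerance 1e−6) on [0, λ_max] with λ_max =
max(C)/max(off-diagonal); the profile likelihood concentrates out the
mean and rate through a Cholesky solve; P is a χ²(1) likelihood-ratio
test against λ = 0.  Both match the standard R reference implementation
(phytools) to ~1e−8 on a fixed test tree, and those reference values are
frozen in the test suite.

**Ancestral states** are the GLS/ML Brownian estimates
x̂_k = μ̂ + c_k'C⁻¹(x − μ̂1) with variance
σ̂²·(d_k − c_k'C⁻¹c_k + (1 − 1'C⁻¹c_k)²/(1'C⁻¹1)) and 95% CI =
estimate ± 1.96σ.  The Brownian rate uses the bias-corrected GLS
estimator (x − μ̂1)'C⁻¹(x − μ̂1)/(n − 1) — one degree of freedom is
absorbed by the phylogenetic mean, and this is the convention of the
standard comparative-methods tools, so CIs line up with theirs.
Phylomorphospace node coordinates are exactly these per-axis estimates.

## Synthetic data

Surfaces are self-affine fractals by spectral synthesis (power spectrum
∝ f^−2(H+1), default Hurst H = 0.8, RMS σ = 0.15 µm), with carved
oriented scratches (Gaussian cross-section grooves), spherical-cap pits
and optional spike outliers; spectral synthesis rather than midpoint
displacement because it is stationary and exactly seedable.  Guild
structure is an ordered hardness axis: the invertebrate guilds follow
softest < softer < harder in their multipliers on σ and scratch/pit
density (0.6, 0.85, 1.25), with vertebrate consumers off-axis (piscivore
0.7, carnivore 0.95).  Fast mode draws log-normal parameter vectors whose
log10 means shift by log10 of the multiplier for the hardness-affected
parameters (within-guild SD 0.12 log10 units, n = 10 per guild by
default); surface mode generates actual scans from guild-multiplied
recipes.  Dietary templates are jittered slightly and always re-checked
against the guild-assignment rule, so generated labels are self-consistent
by construction.

Trees are Yule (pure-birth) via the standard simulator, with pendant
edges extended by one extra exponential waiting time because the
generator stops exactly at a speciation event (which would leave two
zero-length tips and a singular covariance).  Traits evolve by Brownian
recursion along branches (true node states retained as ground truth) or,
for λ < 1, by a draw from the λ-transformed multivariate normal.
Stratigraphic ranges place each tip's FAD between its true age and its
parent-node age, within a sampling span of the parent (default 2 Myr),
which guarantees the equal method a feasible calibration; with span 0 the
FAD equals the true tip age.

**What passing tests do and do not show.** The generators reproduce the
statistical *structure* the analyses assume — guild-ordered roughness,
Brownian trait evolution, minimum-age-consistent ranges — not the
physics of enamel wear, instrument noise spectra, inter-observer
treatment effects, or any real taxon's measured textures.  Green tests
demonstrate that the machinery recovers known structure under its own
model assumptions and matches independent references; they say nothing
about whether a particular fossil's diet is correctly inferred.

## Monte-Carlo calibration results and problem sizes

The acceptance checks run at these sizes, chosen to pin each rate down
without excessive replication: screen null calibration at 500 replicates
(5 guilds × 5, 14 parameters; flagged fraction ≲ 0.4%, far under the 5%
FDR bound); PC1 hardness-order recovery over 100 end-to-end replicates
(100% observed); Blomberg K averaged over 500 Brownian simulations on a
fixed 20-tip tree (within 1.0 ± 0.1); λ rates over 500 replicates on
30-tip trees; root-CI coverage over 500 replicates (~92–93%, inside the
90–99% band).  Filter and parameter checks run on 256² and 220² grids.

**Known limitation — λ near the null.**  On 30-tip trees the ML λ̂ under
tree-independent traits exceeds 0.1 in roughly 13–15% of datasets; this
is a property of the estimator's null sampling distribution at that tree
size (our estimates match the reference implementation to four decimals),
and it shrinks with more tips (≤ 0.1 in ~93% of datasets at 50–80 tips).
A small-tree λ̂ appreciably above zero is therefore weak evidence by
itself; the likelihood-ratio P value, which the package also reports, is
the better-calibrated quantity.  Similarly, minimum-age ("equal")
calibration compresses deep branches whenever old nodes subtend only
young tips — an inherent property of FAD-based dating, visible in the
demo as reduced K on the calibrated tree relative to the generating tree.
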