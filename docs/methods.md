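# Methods

This note documents the models and procedures implemented in `moviemap`,
the synthetic data they are verified against, the numerical choices made
where the design was open, and the known limits of what the verification
shows.

## The synthetic cortex and what it emulates

All analyses are validated on a synthetic cortical sheet rather than
imaging data. The sheet is a rectangular grid per hemisphere (default
24 × 32 units) instead of a triangulated surface: every analysis consumes
sets of cortical units (areas, traced lines), not geodesic geometry, so a
grid keeps the whole pipeline testable at desk scale. One grid axis carries
eccentricity (0 foveal → 1 peripheral), the other carries area identity:
dorsal areas (V1d, V2d, V3d, V3A-B) stacked above V1, ventral areas (V1v,
V2v, V3v, hV4) below, each a contiguous band of rows, mirrored exactly
across hemispheres. A broader 12-area scheme (adding VO1/PHC1/LO1/hMT)
is available for stream-clustering analyses. Hierarchy levels are V1 = 1,
V2 = 2, V3 = 3, {hV4, V3A-B} = 4; "adjacent" means hierarchy distance 1
within a stream, "distal" distance ≥ 2.

Ground-truth maps are analytic: the spatial-frequency map is a strictly
decreasing function of eccentricity (high spatial frequency at the fovea);
the meridian map is sin(2·polar angle) with an eccentricity-decaying
envelope, constructed so its sign is constant within each area and flips at
exactly every area boundary a perpendicular line crosses. A small Gaussian
kernel (σ = 0.5 units) smooths both maps without breaking either invariant.

**Recordings.** Every participant watching a movie shares a latent time
course S (k = 10 × T per movie): an AR(2) process low-passed at 0.3 ×
Nyquist, approximating the hemodynamic passband at TR = 2 s. The cutoff
matters: heavier smoothing leaves so few temporal degrees of freedom that a
*time-reversed* recording aligns with the forward latents by chance,
contaminating the flipped-baseline null. Each participant mixes S through a
loading matrix whose columns are

* eight area-anchored patterns whose weight decays with hierarchy distance
  (ratio 0.5 per level) and drops across streams (× 0.3) — this plants the
  homotopic same > adjacent > distal correlation structure;
* the two ground-truth maps, scaled so they carry the fraction
  `map_coupling` of loading variance (default 0.5). The spatial-frequency
  column is demeaned within area first: its area means are a constant that
  would only add a uniform shared signal across areas. The meridian column
  keeps its alternating area means, which are part of its sign structure;
* participant-specific smooth random patterns at scale 0.2 (functional
  idiosyncrasy).

Gaussian noise, spatially smoothed (σ = 1.5 units), is added at
`snr` = signal SD / noise SD (default 1), plus a motion confound: a
per-participant rectified AR(1) motion time course times one global spatial
pattern with a positive offset, so motion transients drive consistent
activity across areas — exactly the confound the partial-correlation
control must remove. The hemodynamic delay is an integer-TR shift with
cropping (default 2 TR = 4 s); each unit's time course is z-scored within
movie. All randomness fans out from a single master seed through
tuple-addressed `SeedSequence` children, so identical configurations give
bit-identical cohorts and every stage is independently reproducible.

All smooth random fields use periodic (wrap-around) boundary conditions.
This is deliberate: the rolled-component null (below) permutes maps by
circular grid shifts, and with periodic fields a shift is an exact symmetry
of the noise distribution — original and rolled noise components are
statistically exchangeable, which is what a specificity null requires.

Two special generator modes: `map_jitter_scale` warps each participant's
maps by a seeded smooth displacement field (RMS amplitude in grid units),
emulating residual anatomical misalignment after template registration;
`structured=False` replaces all loading columns with anatomy-free patterns
(phase-random periodic oscillations along the area axis, like banding
artifacts, plus large-scale smooth fields) for "pure noise" cohorts whose
spatial organization bears no relation to the area layout.

**What the generator does not emulate.** No hemodynamic convolution beyond
the integer shift, no eye movements or attention fluctuations, no
biological hemisphere asymmetry, no surface geometry, no between-area
latency differences. Passing tests show the *analyses* recover planted
structure under realistic noise; they do not show that infant data contain
that structure.

## Homotopy analysis

Per participant, unit time courses (all movies concatenated) are averaged
within each (hemisphere, area); every left-hemisphere area is Pearson
correlated with every right-hemisphere area, giving a left × right matrix
that is deliberately not symmetric. Cells are grouped by metadata — same
area/same stream, same area/cross stream, adjacent within stream, distal
within stream — with both asymmetric cells of each heterotopic pair
included. Group means are taken on Fisher-Z values within participant
(reported back as correlations for display), and group differences are
tested across participants by bootstrap: resample participants with
replacement (default 10,000 pseudosamples), two-tailed p = 2 × fraction of
pseudosample means with sign opposite the observed mean, capped at 1, with
a 2.5/97.5 percentile interval and no bias correction. A p of zero is
reported as "< 2/n_boot". Missing areas are simply excluded from every
group they would enter. A motion regressor can be partialled out of every
cell (ordinary least squares residualization with intercept).

**Calibration of the bootstrap.** The sign-flip percentile bootstrap is
slightly anti-conservative at n = 15: the pseudosample mean distribution
provides a z-type rather than t-type reference, and the bootstrap variance
carries the 1/n (not 1/(n−1)) factor. Measured type-I error at α = 0.05 is
≈ 0.08 (analytically, P(|t₁₄| > 1.96/√(15/14)) ≈ 0.079). This is a property
of the procedure itself, which is implemented exactly as specified (no
studentization or bias correction); users testing small cohorts should
treat p-values near 0.05 with caution. The calibration experiment in the
acceptance suite reports the empirical rate and its binomial band honestly;
at these sample sizes the rate sits at the upper edge of the band.

**MDS.** The participant-average matrix's rows are treated as feature
vectors; pairwise Euclidean distances are embedded by metric SMACOF
(8 seeded restarts plus a classical-scaling start, 300 iterations,
convergence 10⁻⁹, best configuration kept) and goodness of fit is Kruskal
stress-1, √(Σ(δ−d)²/Σδ²), conventionally acceptable below 0.2. Stream
separation is summarized by the silhouette of dorsal/ventral labels on the
2-D embedding.

## Spatial ICA map discovery

Spatial ICA treats units as samples and timepoints as features, so sources
are spatial maps: PCA whitening to the requested rank, then fixed-point ICA
(logcosh contrast, symmetric decorrelation, 500 iterations, tol 10⁻⁶,
seeded; non-convergence returns the best iterate with a flag). The
automatic rank is the smallest retaining 90% of variance, bounded to
[20, 170]. The reference experiments use a fixed rank of 20 — at the
standard SNR the variance rule retains many noise dimensions, which
fragments the planted maps across components; 20 is the scale at which a
single component can carry a whole map.

Candidate selection replaces a human coder with four blinded criteria, all
computed without the ground truth:

* occipital energy fraction ≥ 0.5 (trivially 1 on the synthetic sheet,
  meaningful for real-data masks);
* mirror symmetry ≥ 0.2, computed as the correlation between left- and
  right-hemisphere gradient profiles (profile averaging suppresses
  unit-level noise, mimicking inspection of a smoothed map);
* spatial-frequency candidates: Spearman |ρ| ≥ 0.85 of the mean parallel
  (fovea→periphery) profile against position;
* meridian candidates: per perpendicular line group (one per hemisphere ×
  stream span — the dorsal and ventral spans alternate with opposite phase
  and must not be pooled), ≥ 3 sign changes at area-boundary gaps with at
  most 1 elsewhere, in at least 3 of 4 groups.

Thresholds are configuration; the defaults were set so that spatially
smooth noise maps pass at a low rate (< 10%, empirically ≈ 1–4%) while
planted maps survive at realistic SNR.

Selected components are validated by correlating gradient profiles with
the ground-truth map — profiles grouped into equal-phase sets, per-group
correlations averaged, absolute value taken because ICA signs are
arbitrary — then ranked among all components and converted to a percentile
(100 = best, chance = 50; ties share mean ranks; multiple selections are
averaged).

**Rolled-component null.** Each component map is spatially permuted while
preserving smoothness, an equal number of rolled and original maps are
pooled under hashed identities and shuffled, selection runs blind, and the
fraction of selected maps that are original is tested against 50% with an
exact two-tailed binomial test (doubling rule, rational arithmetic). The
default permutation rolls each hemisphere's grid by half the width and by
half the height *plus one row*: the meridian layout is periodic with a
two-area period, so an exact half-height roll would be a symmetry of the
meridian map and the null would be vacuous; the extra row is the minimal
offset that breaks boundary alignment. A hemisphere-swap mode (swap plus
exact half-extent rolls, an involution) is also provided, but on these
exactly mirror-symmetric sheets swapping hemispheres is nearly an identity,
so it is not the default null — on real, asymmetric cortical surfaces the
swap is the natural choice.

## Shared response modeling

The SRM minimizes Σᵢ‖Xᵢ − WᵢS‖²_F over orthonormal Wᵢ (units × k) and
shared S (k × T). Both alternating updates are exact minimizers — Wᵢ by
orthogonal Procrustes (UVᵀ of XᵢSᵀ), S by averaging WᵢᵀXᵢ — so the
objective is non-increasing by construction and this is asserted on every
fit. Initialization is QR of a seeded Gaussian per participant; defaults
k = 10, 50 iterations, relative tolerance 10⁻⁹. The deterministic
formulation (not the probabilistic EM variant) was chosen because it is
exactly testable: noiseless construct-and-recover must reach relative
residual < 10⁻⁶ and principal angles < 10⁻⁴ rad at matched k.

Map transfer holds one participant out per movie: the SRM is fit on the
rest, their ground-truth maps are projected into the shared space (Wᵢᵀmᵢ)
and averaged into a template v̄, the held-out basis W_test is learned
against the *frozen* S with a single Procrustes solve, and the prediction
is W_test·v̄ (the orthonormal basis makes the pseudoinverse of the analysis
map exact). Predictions are scored by *signed* gradient correlation —
unlike ICA, alignment fixes the sign, and negative transfer is
informative. Baselines: (i) flipped — the held-out movie data reversed in
time per movie, so no stimulus-locked mapping is learnable; its
correlations scatter around zero with appreciable variance per fold (the
chance alignment of a k = 10 basis over ~90 TR of smooth latents), so only
seed-averaged means are meaningful; (ii) anatomical — the element-wise
average of the other participants' maps on the common grid, which plays
the role of surface-template averaging and is scored identically.
Per-participant results are averaged across movies within participant
before any bootstrap comparison. With perfectly aligned maps the anatomical
average is the better predictor; map jitter degrades it monotonically while
functional alignment is unaffected, and the ordering flips for the sharper
meridian map by jitter ≈ 2 grid units.

The shared dimensionality k = 10 is the default; `select_k_crossval`
implements the supporting selection procedure (participant-wise holdout
crossed with time halves: fit on training participants' first halves,
learn the held-out basis on their first half, reconstruct their second half
from the training second-half shared response, score by correlation).

## Problem sizes and determinism

Reference experiments run on one CPU in minutes: the standard cohort is 15
participants × two 90-TR movies on a 24 × 32-per-hemisphere grid; planted
ICA recovery uses 25 single-participant cohorts; the rolled null 25 planted
plus 25 anatomy-free cohorts; map transfer 10 cohorts with one held-out
participant each; the jitter sweep 8-participant cohorts at jitter
{0, 1, 2, 4}. Every stochastic step is seeded; the full pipeline report is
byte-identical across reruns of the same configuration.

## Limitations

* The synthetic sheets are exactly mirror symmetric and share a common
  coordinate frame; anatomical-average baselines are therefore optimistic
  (correlation 1.0 at zero jitter) relative to real template alignment.
* The selection criteria are sharper than a human coder (they know where
  boundaries are); rolled-null fractions on real data would be less
  favorable.
* The bootstrap's mild anti-conservativeness at small n is inherited from
  the procedure, not a bug; it is quantified above.
* ICA map recovery degrades when the decomposition rank greatly exceeds
  the latent rank; the automatic variance-based rank is provided for
  fidelity but a rank near the expected signal complexity performs better
  on synthetic cohorts.
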