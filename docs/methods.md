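# Methods

This note documents the models, procedures and numerical choices behind
`constancy`, in the order the pipeline runs them: scene synthesis, the
observer-side scaling, the model-side matching, the reflectance network,
and the alignment metrics. It also states which features of real
experiments the synthetic data does and does not emulate.

## Scene model

Image formation is the diagonal (von Kries) model in linear RGB:
`rgb = reflectance ⊙ g`, with `g` a per-channel illuminant gain and values
clipped to [0, 1]. There is no global illumination, shadowing or
inter-reflection; every surface is flat-shaded. Scenes are 64×64 by
default: a blocky background drawn from a palette (the `outdoor` palette
carries a deliberate green bias, mimicking vegetation-dominated scene
statistics), up to five candidate target locations on a jittered grid, an
optional leaf disk under each location, a small bright achromatic patch,
and one labeled target disk per capture. A seed fully determines layout.

**Illuminants.** Five lights: neutral (`g = 0.6` per channel) plus two
symmetric pairs. The yellow and red gains are obtained by inverting the
rendering so that a mid-gray surface (reflectance 0.35) is displaced by
exactly Δ CIELAB units along +b\* and +a\* respectively; blue and green are
the channel-wise gain mirrors (`g_blue = 2 g_n − g_yellow`), so the
neutral gain is exactly the centroid of the four chromatic gains. The
default Δ = 18 was chosen once so that every competitor surface stays
inside the physical reflectance range [0, 1] under every illuminant
(Δ = 20 pushes the tristimulus match under the green illuminant to a
reflectance above 1); it is configurable. A consequence of exact
gain-space symmetry is that the *Lab* displacements of the mirrored
illuminants are only approximately opposite, and the T–R spans differ by
illuminant (about 13 Lab units under blue up to about 31 under green) —
the CCI normalizes by each span, so the index is comparable across
illuminants.

**Competitor sets.** The competitor color space is anchored in the
*reflectance frame*: a competitor's coordinate is the CIELAB value of its
surface reflectance rendered under the neutral illuminant. R is the
achromatic target reflectance itself; T is the surface whose light under
the test illuminant equals the target's light under neutral
(`ρ_T = ρ_t ⊙ g_n / g_i`, the exact diagonal inversion). S1 and S2 are
placed by linear interpolation *in Lab* at 1/3 and 2/3 of the T→R
segment and O one S-step beyond R, then inverted back to reflectances;
interpolating in Lab rather than in linear reflectance makes collinearity
and equal spacing exact rather than approximate. Under the neutral
illuminant R and T coincide; the set is flagged degenerate and the CCI is
undefined there. This frame has two exactness consequences used as
anchors everywhere: an agent that reads ground-truth reflectance
reproduces the competitor originals exactly (CCI = 100), and an agent
that reads the raw image maps the T competitor onto R's coordinate
exactly (CCI = 0).

**Cue silencing.** `local_surround` re-renders leaf pixels under the
neutral gain (their rendered color becomes illuminant-independent);
`maximum_flux` does the same for the bright achromatic patch;
`spatial_mean_add` inserts filler disks whose reflectance is the squared
chromatic mirror of the illuminant (`ρ ∝ (g_n/g_i)^2`), pulling the scene
mean toward the opponent direction; `spatial_mean_change` rescales all
background reflectances by `(g_n/g_i)^2`, which lands the rendered
scene-mean chromaticity on the *opposite* side of neutral from the
illuminant. The exponent 2 implements "shift the mean in the opposite
direction": exponent 1 would merely neutralize the mean. Each mechanism
touches only its designated pixels; the reflectance map is updated
consistently for the two spatial-mean variants (they are real surface
changes), while the two clamping mechanisms override rendered color only.

**Surround colors.** The four leaf reflectances (khaki, rose, purple,
teal) sit on the diagonals between the illuminant axes in a\*b\* at chroma
20: rose on the red/yellow diagonal, khaki green/yellow, teal green/blue,
purple blue/red, constructed as exactly opposite pairs so khaki/purple
and rose/teal average to the neutral chromaticity. `classify_direction`
labels an illuminant Neighboring if its hue is within 90° of the
surround's hue, Opposing otherwise; purple therefore neighbors blue and
red and opposes green and yellow.

## Observer-side scaling (adapted MLDS)

Each selection trial shows the five competitors; the simulated observer
perturbs every competitor's 1-D perceptual position with independent
Gaussian noise (SD 0.1) and picks the one closest to its internal match.
Choices are reduced to a paired-comparison matrix (a choice is a win over
each of the four others; a pair's comparisons are the trials on which
either member was chosen, so complementary proportions sum to 1 exactly).

The fit maximizes the *selection* likelihood — the probability that the
chosen competitor's noisy position is nearest the match, computed by
48-node Gauss–Hermite quadrature with closed-form normal tails for the
other four — over four competitor gaps and the match position, with T
fixed at 0, gaps bounded below by 0.025, fixed noise SD 0.1, and the
match constrained non-negative (the ordering constraint rules out sub-T
solutions). Optimization is multistart L-BFGS-B (10 restarts by default,
best likelihood kept, seeded). The selection likelihood is the exact
model of how the synthetic data are generated; a pairwise Thurstonian
composite likelihood was measurably less accurate at recovering the
index from 150-trial runs.

**Identifiability.** Five selection frequencies carry four degrees of
freedom, against five free parameters: the likelihood has a ridge, and
absolute gap sizes are only weakly identified from a single condition's
matrix. What the constraints pin down is the match's position relative to
its flanking competitors — exactly what the Lab interpolation consumes.
Recovery is therefore validated on the index, not on raw positions:
across 20 seeded synthetic observers spanning true CCI 0–130% at 150
trials each, the median |recovered − true| CCI error is about 3
percentage points (the acceptance suite asserts < 5).

The fitted match is mapped to CIELAB by transferring its relative
position between flanking competitors to the same competitors' Lab
coordinates (nearest-segment ratio when extrapolating), and scored as
`CCI = 100·|T − Match| / |T − R|`; values above 100 mark
overcompensation.

## Model-side matching

Predictions are pooled per competitor by an unweighted pixel mean over
the masked target across all its appearances (appearances with more
pixels weigh more). Each pooled color is orthogonally projected onto the
line through R and T; the two competitors whose projections land closest
to R (ties broken by the fixed order R, S2, S1, T, O) select the
interpolation segment, and the Match is the inverse-distance-weighted
combination of those two competitors' *original* coordinates
(`w_near = d_far / (d_near + d_far)`). Both tied-at-zero distances return
the nearer competitor's coordinate. Classical estimators are scored
through the identical pipeline: estimate, von Kries correction (with mean
luminance preserved so the correction is purely chromatic), re-render
under the neutral gain into the competitor frame, then masked averaging
and interpolation.

## Classical estimators

Gray world (channel mean), white patch (channel max), shades of gray
(Minkowski p-norm mean, default p = 6), gray edge (Minkowski mean of
Gaussian-derivative magnitudes, default first order, σ = 1, p = 1) and
weighted gray edge (gradient contributions scaled by a monotone power of
edge strength, default exponent 2). Defaults follow the conventions of
the methods' literature and are all configurable. Estimates are
normalized to unit L2; pixels at the clip ceiling are excluded from the
statistics (clipping corrupts both mean and max estimators); a spatially
constant image yields a flagged degenerate estimate from the edge
methods, never a silent fallback. For p ≤ 16 the p-norm mean is computed
directly (so p = 1 equals gray world to machine precision); above that a
max-rescaled form guards against overflow.

## Reflectance network

A compact convolutional encoder–decoder written directly on numpy with
hand-derived backpropagation (verified against central differences to
~1e-9 relative): two stride-1 conv+ReLU stages with 2× average-pool
downsampling, a bridge whose globally averaged features are broadcast and
re-mixed (giving the decoder scene-level statistics, the information an
illuminant estimate would need), two nearest-upsample stages with encoder
skips, and a linear 1×1 head scaled to Lab range. The output is
*residual*: the net predicts a correction added to the raw image's Lab
(the zero-constancy reading), so the untrained model starts at the
tristimulus baseline and learning moves it toward constancy. Default
width 16 (~47k parameters); inputs need spatial dimensions divisible
by 4.

**Loss.** `PBCLoss = λ1·mean(ΔE00) + λ2·mean(ω·((Δa)² + (Δb)²)) +
λ3·mean(ΔL²)` with `ω = 1 + β(C_gt/128)^γ` and defaults
(λ1, λ2, λ3, β, γ) = (1, 0.5, 0.2, 2, 2); the over-bar means are taken
over all pixels of the mini-batch, each term averaged independently. The
chroma weighting counters the near-achromatic skew of natural pixel
statistics that lets plain MSE favor desaturated output. The squared
terms are differentiated analytically; the ΔE00 term by central finite
differences per Lab channel (step 1e-3 — the formula is piecewise smooth
and behaves like an L1 penalty near zero, which also means the last
fraction of a percent of training loss decays only with the learning
rate).

**Training protocol.** Stage 1 trains all parameters on baseline scenes
(15 layouts × 5 illuminants, one varied competitor surface each, 30
epochs, Adam, lr 3e-3, batch 8); stage 2 freezes the encoder
(bit-identical, asserted by checksum) and fine-tunes the decoder on
baseline scenes with the achromatic reference (6 layouts, 8 epochs,
lr 1e-3). Optimizer and schedule are package choices; at this scale the
whole protocol takes a couple of CPU minutes. Evaluation layouts use
disjoint seeds from training layouts.

## Alignment metrics

Accuracy is the Pearson correlation between an agent's condition vector
(one entry per scene × mechanism × illuminant cell) and the mean human
vector; bias the mean signed difference; normalized error the RMSE over
the SD of the human mean. Lin's CCC uses population (1/n) moments — the
convention of the concordance literature — while the normalized error's
SD uses 1/(n−1); both are configurable. LOO is the mean over participants
of the CCC between each participant and the mean of the others, and
ncCCC = CCC/LOO, so the human mean itself scores exactly 1/LOO and values
above 1 mean the agent tracks the mean human better than individuals
agree with each other. Indoor and outdoor participant groups are disjoint
by design; for pooled ("all") metrics the i-th participants of each group
are concatenated into one pseudo-participant.

## Synthetic observers as study conditions

Synthetic humans are generated from condition-level true CCI values —
baseline 85% (indoor) / 78% (outdoor), mechanism decrements matching the
published human pattern (indoor −23.8 local surround, −8.0 maximum flux,
−23.3 spatial-mean-add, −75.7 spatial-mean-change; outdoor −14.4, −1.4,
−13.6, −72.9; surround silencing −2/−15 Neighboring/Opposing indoor,
−8/−25 outdoor), individual offsets (SD 8) and per-condition jitter
(SD 6), clipped at 0 — and then pushed through the *full* trial →
choice-matrix → MLDS → interpolation pipeline with 150 trials per
condition, so their scores inherit the scaling method's estimation noise
exactly as real data would. These values parameterize the simulation; they
are inputs, not results.

## What passing tests do and do not show

The generator reproduces the study's *design* — illuminant geometry,
competitor construction, cue-specific silencing, the selection task — but
not the photometric complexity of rendered VR scenes: no shadows, no
inter-reflections, no spatially varying illumination, no sensor noise,
flat surfaces only. Results on it validate the machinery (the scaling
recovers planted constancy levels; the matching pipeline is exact at its
anchors; the trained net's degradations order the mechanisms as the
design intends) and say nothing about performance on photographs or
rendered scenes. The network is desk-scale and trained on the same
distribution it is evaluated on (different layouts); its absolute CCI
values are not comparable to a large pre-trained model's.

## Numerical choices and degenerate inputs

All color math is double precision; XYZ↔Lab round-trips to < 1e-9 and the
CIEDE2000 implementation matches an independent reference to < 1e-12 on
the canonical verification pairs. Rendered values are clipped to [0, 1]
with a logged warning if clipping touches a labeled region (the default
gains and reflectances are chosen so it does not). Degenerate cases are
flagged, not silently patched: neutral-illuminant competitor sets
(CCI undefined), all-zero or constant images (degenerate estimates),
near-uniform choice matrices (low-confidence fits), zero-variance metric
inputs (errors). Problem sizes in the analysis scripts (64×64 scenes,
5 locations, 6–10 synthetic participants, 150 trials per condition) are
the package's defaults for a desk-scale run and are configurable.
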