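# Methods

`angiotrack` extracts the centerline tree, per-point diameters and local
structure (terminations, bifurcations, crossings) of bright tubular
structures in 2-D grayscale images — the geometry of contrast-filled
coronary arteries in an X-ray angiogram.  This note describes the model
each stage implements, the tunable parameters and their defaults, the
numerical choices made where the design was genuinely open, what the
phantom generator does and does not emulate, and the known limitations.

## Vessel feature and direction maps

The image `I` (floats in [0, 1], vessels bright) is convolved with
scale-normalized second-derivative-of-Gaussian kernels at scales
`σ_f`.  The eigenvalues of the scaled Hessian `σ_f² ∇²(G_{σ_f} * I)`,
ordered `|λ1| ≥ |λ2|`, characterize local tubularity: a bright ridge of
Gaussian half-width `s` gives `λ1 = −σ² s/(σ²+s²)^{3/2}` across the vessel
and `λ2 ≈ 0` along it.  Per scale, pixels with `λ1` below a negative gate
`r_λ = −(2/π)/σ_f` receive the log response

    Z(x; σ_f) = ln|λ1(x; σ_f)| + c,     c = −ln|r_λ|,

clamped at zero, so that `Z = 0` exactly at the gate.  The vessel feature
map `Ẑ` is the per-pixel maximum over all scales, min–max normalized to
[0, 1]; the scale of the maximum is recorded per pixel.  The vessel
direction `v2` is the unit vector orthogonal to the eigenvector of the
dominant eigenvalue (sign-ambiguous; pixels with `|λ2|/|λ1| > 0.98` are
flagged invalid and inherit the tracking direction).  Binarizing `Ẑ` at
0.05 and thinning gives the vessel mask and skeleton; the automatic seed
is the skeleton pixel of maximal `Ẑ` (row-major first on ties), which on a
tree lands on the widest, highest-contrast trunk.

*Scale set.* 14 log-spaced scales from 0.9 to 8.0 px.  The top scale
reaches the ridge-response optimum of the widest blurred tubes handled
(≈ `√2 ×` the effective cross-section std of a 15 px tube under 3–4 px
focal blur).  Large scales trade off against the separation of closely
parallel vessels (see Limitations).

*Gate sign conventions.*  With vessels bright, ridge eigenvalues are
negative and the gate magnitude `2/(πσ_f)` shrinks with scale, admitting
faint large vessels.  Images with dark vessels are negated on input
(`invert`).

## Probabilistic tracking operator (PTO)

An artery element carries position `x_t`, vesselness `Ẑ(x_t)`, direction
`φ_t` and diameter `d_t`.  Candidates for the next element are the mask
pixels in the annulus between the look-ahead `s_t = round(d_t/2)` (clipped
to [1, 7] px) and the disk radius `r_S = d_t`; when the annulus is empty
the full disk is used, then the disk expands to the detector radius
`r_D = d_t`, which is what lets the operator walk across contrast gaps
narrower than `r_D` while wider gaps terminate the branch.  Three
continuity measures are computed per candidate and normalized by the
per-step maxima over the candidate set:

    Q_Z = |1 − Ẑ/Ẑ_max|,
    Q_θ = min(θ mod π, π − (θ mod π)) / π    (reversal-invariant),
    Q_d = |d_i − d_t| / d_max,

with `θ` the deflection between the step vector and `φ_t`.  Each measure
feeds a Gaussian likelihood whose standard deviation is the population
std of that measure over the current candidate set (floored at 1e−3 for
homogeneous sets), and the next element is the candidate maximizing the
product of the three likelihoods — a maximum a posteriori choice under a
uniform prior.  The adaptive variances are what keep the ranking
informative through stenoses, aneurysms and gaps, where all candidates
score poorly in absolute terms.

Numerical details: the annulus lower bound gets 0.5 px slack so the exact
on-axis pixel is never cut out by a fractional radius; candidate
directions come from the direction map, oriented along the travel step;
invalid-direction pixels inherit the incoming direction.  Candidates are
restricted to the forward half-plane of the (oriented) travel direction —
a kink beyond 90° at half-diameter spacing is never vessel continuation,
only blur fringe.

## Diameter estimation

The local diameter is measured on a 1-D profile of the raw intensity
sampled perpendicular to the local direction (81 samples, 1 px apart,
cubic interpolation).  The profile is convolved with `σ²`-normalized
second-derivative-of-Gaussian kernels over 25 geometric scales (σ from
0.8 to 12 px); the scale `σ̂` with the largest response magnitude at the
profile centre is selected, with the centre itself refined to subpixel
precision (parabola on the matched kernel's response) and the winning
scale interpolated quadratically in log-scale.  For wide tubes `σ̂ ≈ w/2`;
for thin ones it saturates near `√2 ×` the blur, so the mapping
`σ̂ → diameter` is calibrated once per acquisition point-spread
(`psf_sigma`, default 3.2 px) on noise-free straight-bar phantoms of known
width (3–19 px in 0.5 px steps) and stored as a monotone PCHIP table.  A
single least-squares constant (`k_cal`) is also available but markedly
less accurate because of the thin-tube saturation.

All candidates on one transversal line share one diameter; the tracker
caches measurements per pixel.  After a branch is finished its diameters
are re-measured densely (1 px) along the final polyline, cleaned against a
rolling median (junction blobs produce impulsive outliers), extended by
constants across end margins (the node→limb chord plus half a diameter at
a spawning junction, half a diameter at a tip, where the transversal
profile is contaminated), masked and interpolated across registered node
and crossing zones, and finally corrected for the blur's along-axis
averaging: an isotropic PSF turns a width profile `w(s)` into
approximately `w + (σ_psf²/2) w''`, so the estimated curvature term
(Savitzky–Golay second derivative over a 15 px window) is subtracted.
Constant-width stretches are unaffected; the residual error concentrates
in the steepest taper regions of a stenosis or aneurysm, where higher-order
terms of the 2-D blur are not a 1-D convolution of the width profile and
cannot be deconvolved stably (Tikhonov and Van Cittert variants were
evaluated and amplify the model mismatch).

Measuring on the vesselness map instead (`diameter_source="feature_map"`)
is supported for completeness but poorly conditioned: the log-compressed,
multiscale-smoothed map has `d(width)/d(σ̂) ≈ 6` for wide tubes and mixes
widths along the vessel, an order of magnitude worse in practice.

## Structure pattern detector (SPD)

At each new element a circular template samples 150 vesselness values
(bilinear) on the circle of radius `α·d_t/2 + 3·σ_psf` (α = 1.25).  The
PSF margin is essential: the limbs of a junction only separate into
distinct profile peaks once the circle clears the blur-merged core.
Profile peaks are positive-to-negative sign transitions of the circular
first-derivative-of-Gaussian-smoothed profile (dead zone 1e−9 against
floating-point ripple), refined by a local quadratic fit and discarded
below the binarization threshold.

Each peak receives a "co-vessel" measure `γ ∈ (0, 1)`: the largest
absolute response of real-component Gabor masks (wavelength = mask size,
envelope σ = size/2, zero-mean, L2-normalized; sizes 0.6–1.4 × the local
diameter clipped to 3–15 px; orientation along the centre→peak azimuth
± π/8) evaluated at the peak on the raw image, normalized by the same
bank's response at the element's own position along its own direction.
Peaks with `γ < 0.15` are treated as noise or a neighbouring structure's
flank and do not count as limbs.

The fuzzy inferring function assigns each pattern `i ∈ {1 termination,
2 segment, 3 bifurcation, 4 crossing}` the membership

    μ_i = min( min_m μ_{m,Ẑ}, min_m μ_{m,γ}, μ_{M}^i ),

with Gaussian peak memberships `μ_{m,Ẑ} = exp(−(Ẑ_max−Ẑ_m)²/2σ_Z²)`,
`μ_{m,γ} = exp(−(γ_max−γ_m)²/2σ_γ²)` and the peak-count membership
`μ_M^i = exp(−(M−i)²/2σ_M²)` for `M ≥ i`, else 0.  Zero peaks infer a
termination outright.  The inferred pattern maximizes membership, ties
resolving to the simpler pattern.  Widths `σ_Z = σ_γ = 0.5`, `σ_M = 1.0`
were calibrated on the phantoms: with the min-composition, class
distinction rests on the peak-count term, so the peak-feature memberships
must not saturate the minimum at realistic junction heterogeneity.

## Tracking orchestration

A LIFO source-list starts with the seed in both orientations; each branch
is tracked until a stop rule fires: (1) a bifurcation is detected — the
branch is truncated at the refined node and every outgoing limb becomes a
source; (2) the next vesselness falls below 0.05, or more than 2.2
endpoint-decrements (below) under the branch's running level; (3) the path
overlaps a previously tracked vessel — a raster of all finished branches
dilated to the local half-width plus the PSF fringe (capped at 1.4
diameters), with the branch's own earlier path included — except inside
the exemption zone of a registered crossing; (4) the source-list empties;
(5) the path leaves the image.  A grace zone around each spawn point
exempts the parent's raster until the child first leaves it.

Node handling works on detection *clusters*: consecutive node-class SPD
results collect until a segment result, a span of 4 diameters, or 12
detections.  Because the flanks of a crossing always present three limbs,
a cluster counts as a crossing whenever its four-limb detections reach
70 % of its best three-limb membership; otherwise the maximal-membership
detection dates the bifurcation.  While a cluster is open, and throughout
a registered crossing's zone, candidates are confined to a corridor
(lateral tolerance ≈ half a diameter, capped at 4 px) along the axis
locked at cluster entry, so the path can neither turn onto the other
vessel of a crossing nor drift on the junction blob.  Node positions are
estimated from the limb geometry (least-squares intersection of limb
lines through grouped template peaks), then re-estimated after tracking
completes by intersecting fits of every incident polyline's ring just
outside the node region — quadratic fits along arclength evaluated at the
near end where enough points exist (≥ 14), straight fits otherwise —
which removes the downstream bias of detection-time estimates; incident
branch endpoints move with the node.

Terminations are finalized in two steps calibrated on the straight-bar
family: trailing elements whose vesselness sits more than
`(0.657 − 0.0258·d)/raw_range` below the branch level are blur fringe and
are pruned (the raw log-response drop at the geometric end of a tube of
diameter `d`, blur-independent over 3.2–4.0 px; `raw_range` is the
pre-normalization response range), and the endpoint is then advanced at
1 px resolution along the tail direction (PCA of the last 22 px of
polyline) up to the same threshold crossing.  This places tracked ends
within ~1–3 px of the geometric tube end.

## Stenosis quantification

On a tracked branch, `%-LENGTH = (1 − L_r/L_m) × 100` with `L_r` the
minimal diameter inside a lesion and `L_m` the mean diameter of the
nonstenotic part.  `L_m` is found iteratively (start from the overall
mean, re-average outside the candidate lesions until stable); a lesion's
extent is a maximal run where the running grade exceeds 25 %, the lowest
visual grade of the standard classification.  Branches with fewer than
10 samples are skipped.

## Phantom generator

Segment phantoms are ideal tubes of analytic centerline and width profile
— straight, stenotic and aneurysmal (cosine-tapered dip/bulge between the
nominal and extreme widths over the central 40 % of the length), parallel
pairs (two tubes at an edge-to-edge gap `d_P`), gapped tubes (a stretch of
missing contrast of width `w_G`) and curved tubes (sine centerline).  The
simulated arterial tree has a curving trunk (width 14 px), two generations
of bifurcating branches (widths 6–9 px, departure angles 40–52°) and a
descending branch whose tube overlaps another branch in projection — one
true crossing; total skeleton length 705 px in a 320×320 image.
Rasterization is 4× supersampled and box-downsampled so ground-truth
diameters are meaningful at subpixel scales; the binary tube is then
Gaussian-blurred (σ_B, default 3.2 px, the X-ray focal blur) and white
Gaussian noise of std σ_w is added without clipping (clipping would bias
the noise statistics; integer clipping happens only when files are
written).  Ground truth — centerlines at 0.5 px spacing, per-point
diameters, typed nodes, the ideal mask — is exact by construction and
independent of blur, noise and seed.

What the phantoms do not emulate: background anatomy and soft-tissue
clutter, vessel foreshortening and densitometric projection effects,
spatially varying contrast, motion blur, and correlated imaging noise.
Passing on phantoms therefore demonstrates the geometric correctness of
the operators under known blur and noise, not clinical performance.

## Evaluation

Tracked polylines and ground truth are resampled at 0.25 px.  EVL% is the
fraction of truth length within τ = 2 px of the tracked polylines; IR% the
fraction of tracked length within τ of truth; DAS% the fraction of truth
segments with at least half their length covered.  `e0` is the mean
perpendicular distance of tracked elements to the truth centerline
(perpendicular to the local truth tangent, so overshoot past an endpoint
is not charged as lateral error), `e0(nodes)` the same restricted to
elements within one local diameter of a truth node.  `ed` compares each
element's diameter with the nearest point of the best-matching truth
segment among those passing within the tolerance — at a junction the
element is shared by all incident limbs and is judged against the limb it
matches best; elsewhere exactly one segment qualifies and this reduces to
plain nearest-point comparison.

## Problem sizes

The default study conditions are 120 px lesion segments in 120×176 images
and the 705 px five-branch tree in 320×320; a full tree run (preprocessing,
calibration, tracking, refinement) takes ~20 s single-threaded, a segment
run 2–5 s.

## Known limitations

* **Diameter accuracy in steep tapers.**  Mean diameter error on the
  lesion phantoms is ~0.09 px, dominated by the steepest parts of the
  cosine tapers where the 2-D blur is not exactly a 1-D convolution of
  the width profile; uniform stretches are exact to < 0.02 px.
* **Closely parallel vessels.**  At the geometric admissibility limit
  `d_P = (r1+r2)/2` under 3.2 px blur the two tubes are photometrically
  merged (the inter-tube intensity dip is a few percent), so the mask,
  the skeleton — hence the automatic seed — and any profile-based width
  estimate see a single structure; tracking then follows the merged
  ridge.  From an edge gap of ~8 px (≈ 2.5 σ_B) the tubes resolve and the
  tracked path stays within 1 px of its own axis.
* **Junction neighbourhoods.**  Tracked geometry within roughly one
  template radius of a node comes from the node refinement and the
  node→limb chords rather than free tracking; axis error there averages
  ~0.7 px versus ~0 on straight stretches.
* **Tracking completeness.**  On the noise-free tree the pipeline covers
  99.0 % of the truth length with 98.2 % of the tracked length correct;
  the residuals sit in the junction gaps above.
* Loops (a vessel crossing itself) and images whose vessels leave and
  re-enter the field are not handled specially.
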