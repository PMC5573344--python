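# Methods

## The simulated study

One simulated "study" mirrors a two-phase field protocol. A 5 × 4 grid of
cameras at 750 m spacing operates for 13 daily occasions; afterwards 10
corral traps, placed one per stratum of an overlay grid inside the camera
array (jittered uniformly within each stratum by the seed), operate for 14
nights with all traps active every night (140 trap-nights). Coordinates are
planar kilometres, origin at the grid corner; occasions are 0-based with
the camera phase first.

The landscape is the detector bounding box buffered by
`landscape_margin_km` (default 4.8 km — the trap truncation radius at the
largest design σ of 1.2 km — so that every animal that could ever reach a
detector exists in the population). Home-range centroids are stationary and
clustered: parent points fall uniformly, each receives
Poisson(`cluster_mean_size`=4) offspring displaced uniformly within
`cluster_radius_km`=0.3, and the realized count is thinned or augmented to
exactly `round(density × area)`, so true density is exact by construction.
The cluster defaults are a deliberately mild grouping (family-group-sized
clusters a few hundred metres across); the clustering exists to stress the
estimators' independence assumptions, not to model any particular
population.

### Availability and detection

Daily availability at centroid–detector distance d is a truncated Gaussian

    p_avail(d) = min(1, exp(-d²/2σ²) / √(2πσ²)),  d ≤ R;  0 otherwise.

The Gaussian *density* form means the kernel exceeds 1 near d = 0 once
σ < 1/√(2π) ≈ 0.399; availability is a probability, so it is clamped at 1
there rather than renormalized. Clamping preserves the intended reading —
small-σ animals are effectively always available very close to their
centroid — where renormalizing would instead rescale the whole curve.
Truncation radii are multiples of σ: 3σ for cameras, 4σ for traps
(baited traps draw animals from farther); both are configurable and were
fixed before any estimator was run.

Detection multiplies availability by a baseline: g₀ at cameras,
`trap_g0_ratio` × g₀ = 0.25 g₀ at corral traps (the 75%-lower trap
baseline). Per night, an animal is detected with probability
1 − Π_k (1 − p_k) over in-range detectors. For cameras, a detected animal's
number of distinct cameras that night is drawn from
`visit_probs = (0.82, 0.15, 0.03)` over {1, 2, 3}; the cameras themselves
are sampled without replacement with weights proportional to the
per-camera detection probabilities, so nearer cameras are favoured (the
visit count is specified by the design; *which* cameras are visited is a
modelling choice). Trap-happiness multiplies g₀ by `behavior_mult` = 2
(capped at 1) at cameras where that animal was detected on an *earlier*
night — a site-specific learned response of moderate size; its magnitude
is configurable. At traps an animal is captured at most once ever: the
capturing trap is drawn proportionally to per-trap detection
probabilities and the animal is removed from the population.

All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning (per-phase and, in the grid, per
(cell index, replicate) counters), so any cell or phase is reproducible in
isolation and results are independent of execution order.

## Estimators

**Chapman LPE.** n₁ = photo-identified individuals (ground-truth identity:
the simulator has no misidentification), n₂ = trapped individuals, m =
both. N̂ = (n₁+1)(n₂+1)/(m+1) − 1 with the usual Chapman variance; the CI is
a normal approximation on N̂ (log-normal available), floored at the number
of distinct observed individuals. The construction of the CI is a package
choice; nothing in the estimator depends on it.

**SECR.** Full (unconditional) likelihood for binary proximity detectors:
activity centers are a homogeneous Poisson process of intensity D, the
number of observed individuals is Poisson(D·a(θ)) with a(θ) the integral
of the overall detection probability p·(s) over a discrete habitat mask,
and each observed history is integrated over the mask. Detection is
half-normal, p(s,k) = g₀ exp(−d²/2σ²), with optional effects on logit(g₀):
a site-specific behavioral response (naive vs experienced at detector k,
reconstructed from the history) and a camera-vs-trap type effect. The
model set {null, bk, type, bk+type} replaces a larger a-priori set; σ is
always shared across types. Two deliberate mismatches with the generator
remain — the multinomial visit cap and the availability clamp/truncation
are *not* in the fitted model — because estimator robustness to exactly
this mismatch is part of what the experiment measures.

Removal at traps is handled by truncating an individual's occasions after
its capture (no removal term in the likelihood). The thinning term a(θ)
still uses full effort, which is exact here: only detected animals are ever
removed, so a never-detected animal is at risk for the whole study. This
pooled treatment is a known approximation for the *detected* animals'
contribution and is the pragmatic standard for such pooled histories.

Numerics: parameters are estimated on link scales (log D, logit g₀, log σ)
by BFGS; the first start is data-driven (pooled within-individual spread of
detection locations for σ, detection-probability moment match for D), with
up to two additional jittered starts used only when a search fails.
Likelihood evaluations collapse each history to per-(individual, detector)
hit/miss counts split at the first detection, so one evaluation is a few
(mask × detector) matrix products. The default mask buffer is 4 × the
σ-guess (bounded to [1, 6] km) and spacing σ-guess/3 (bounded to
[0.1, 0.5] km); likelihood changes from halving the spacing are below 0.1
in data-rich regimes (tested). SEs come from a central-difference Hessian;
the density CI is Wald on the log scale. A fit is flagged non-converged —
never raised — when no individual is detected at two distinct detectors
(σ unidentifiable), the optimizer fails from every start, or the Hessian
is not positive definite; flagged cells stay visible in the grid output.

**Bayesian removal.** Nₜ = N₀ − Σ_{s<t} y_s, yₜ ~ Binomial(Nₜ, pₜ),
pₜ = 1 − (1−θ)^{Eₜ} (per-trap-night odds compounding; an exponential
hazard link pₜ = 1 − e^{−θEₜ} is available). Priors: N₀ ~
discrete-uniform[Σy, N_max] with N_max = 20 × Σy by default, θ ~ Beta(1,1).
Metropolis-within-Gibbs: integer random walk on N₀ (step ≈ 2% of the prior
range) and a Gaussian random walk on logit θ (step 0.4, acceptance ratio
carrying the θ(1−θ) Jacobian). Defaults 50,000 iterations / 10,000 burn-in,
no thinning; the N₀ update is O(1) via the telescoping binomial-coefficient
identity, so chains cost ~1 s. Diagnostics on every fit: acceptance rates,
initial-positive-sequence effective sample sizes, and the posterior mass in
the top decile of the N₀ support — a nonzero value means the N_max prior
bound is binding and should be raised; `nmax_sensitivity` runs an explicit
doubled-N_max refit on demand. The boundary-mass diagnostic was chosen as
the always-on sensitivity report because it is free, whereas a second chain
per fit would double the cost of every grid cell. Zero total catch is
flagged non-estimable (N₀ and θ are confounded at zero catch).

**Buffers.** MMDM is the mean, over individuals detected at ≥ 2 distinct
locations (camera and trap records pooled), of each individual's maximum
pairwise distance between detection locations. HMMDM applies MMDM/2 as the
buffer width. The naive buffer is the radius of a circle with a
user-supplied home-range area (placeholder default 2 km²). Effective area
is the detector convex hull dilated by the buffer, computed by the exact
Minkowski closed form A + P·w + πw² (degenerate hulls included); density is
N̂/A with delta-method variance var(N̂)/A², the area treated as fixed —
buffer uncertainty is deliberately not propagated, matching standard
practice for ad-hoc buffers.

## The factorial experiment

Axes (defaults): σ ∈ {0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2} km, D ∈ {0.25,
0.5, 0.75, 1.25, 2, 2.5, 3.75, 5, 6.25, 7.5, 10, 15} per km², g₀ ∈ {0.1,
0.2, 0.3, 0.5, 0.7, 0.8, 0.9}: 588 cells, 5 replicates each. Per replicate
the four estimators run on the same dataset; the non-spatial estimators are
converted to density with the MMDM buffer (falling back to a failure status
when MMDM is undefined). Scaled bias is (D̂ − D)/D; CV is SE/D̂, reported
raw and display-capped at 2.0. Aggregation over replicates is the mean
(median also exported) over converged fits only, with failure counts kept
alongside so no replicate is silently lost. The paper-scale design is an
overnight run; tests and the acceptance script use reduced designs
(single cells or 2–3-value axes, 10–20 replicates, removal chains of
8–20 k iterations) sized so the whole suite runs in minutes — chain length
and replicate counts are algorithm/measurement settings, not study
conditions, and the chain-length reductions were checked against ESS.

## What the generator does and does not emulate

It emulates: clustered stationary centroids, distance-driven daily
availability, detector-type-specific baselines, nightly multi-camera visit
caps, site-specific trap-happiness, removal on first trap capture, and
per-night trap effort. It does not emulate: explicit movement trajectories
(no correlated random walks or Brownian bridges — movement is collapsed
into σ by design), habitat covariates or inhomogeneous landscapes,
misidentification of photos, births/deaths/immigration during the study
(closure), or trap saturation (a trap can catch several animals in one
night). Passing tests therefore speak to estimator behaviour under
distance-driven heterogeneity and removal dynamics, not to photo-ID error
or open-population effects in real data.

## Known limitations

- The SECR likelihood assumes binary proximity detectors throughout; true
  multi-catch trap likelihoods are not implemented.
- The behavioral-state reconstruction assumes the recorded history is
  complete (true for simulated data; real data with missed occasions would
  bias the bk effect).
- MMDM from detector locations understates movement when detections are
  sparse, which propagates into LPE/removal densities exactly as it does in
  the field — this is a property being studied, not corrected.
- The removal estimator inherits the buffer problem: it estimates the
  trappable population, and its density depends almost entirely on the
  buffer choice when movement scales are large.
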