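# densim

Simulation-based evaluation of wildlife population-density estimators for
camera-trap and removal-trap study designs.

Wildlife managers estimating the density of a species like the wild pig
(*Sus scrofa*) choose between several families of estimators — two-sample
capture-recapture, spatially explicit capture-recapture (SECR), and removal
(depletion) models — whose accuracy depends strongly on the animals' scale
of movement, the true density, and baseline detectability. `densim`
simulates the whole observation chain (a camera grid, then corral trapping
with lethal removal) under an explicit movement/detection model and scores
each estimator family by scaled bias and coefficient of variation across a
factorial grid of those three drivers, so you can see *when* each estimator
can be trusted before committing to a field design.

## Models

**Generative (observation) model.** Each animal has a stationary home-range
centroid; centroids are clustered (a partial Poisson cluster process, to
mimic social grouping). On a daily time scale, the probability an animal is
*available* at a detector at distance *d* from its centroid is a truncated
Gaussian kernel

&nbsp;&nbsp;&nbsp;&nbsp;p(avail) = min{1, (2πσ²)^(−1/2) exp(−d²/2σ²)},&nbsp;&nbsp;
zero beyond a truncation radius,

where σ (km) is the scale of movement. Detection given availability is a
flat baseline g₀, so p(detect) is a scaled truncated Gaussian. A detected
animal visits 1, 2 or 3 distinct cameras that night with probabilities
(0.82, 0.15, 0.03); a trap-happiness effect multiplies g₀ at cameras where
the animal was previously detected. Corral traps follow the 13-day camera
phase for 14 nights with g₀ reduced by 75%; an animal is removed at its
first (and only) trap capture. The default layout is the field design: a
5 × 4 camera grid at 750 m spacing with 10 stratified-random corral traps
inside it (140 trap-nights).

**Estimators.**

- `ChapmanEstimator` — Lincoln–Petersen with the Chapman correction,
  N̂ = (n₁+1)(n₂+1)/(m+1) − 1, camera photo-IDs as marks and trapping as the
  recapture sample.
- `SECREstimator` — maximum-likelihood SECR for binary proximity detectors:
  homogeneous Poisson activity centers, half-normal detection
  p(s,k) = g₀ exp(−‖s−xₖ‖²/2σ²), optional behavioral ("bk") and
  detector-type effects on g₀ (logit scale), AICc model comparison.
  Camera-only ("camera SECR") or camera + trap occasions ("trap SECR").
- `RemovalEstimator` — Bayesian hierarchical depletion model: yₜ ~
  Binomial(Nₜ, 1 − (1−θ)^{Eₜ}) with effort Eₜ trap-nights, flat priors,
  Metropolis-within-Gibbs sampling of (N₀, θ).
- `densim.buffers` — abundance → density via the effective sampled area:
  the detector convex hull dilated by MMDM (mean maximum distance moved),
  HMMDM, or a naive literature buffer, with delta-method variances.

Estimators follow scikit-learn conventions: constructor parameters,
`fit(...)`, trailing-underscore fitted attributes, `get_params`/`set_params`.

## Worked example

```python
import densim as d

cfg = d.SimulationConfig(sigma=0.6, density=2.5, g0_camera=0.5, seed=42)
ds = d.simulate_dataset(cfg)

chap = d.ChapmanEstimator().fit(ds.camera_history, ds.trap_history)
dens = d.density_from_abundance(chap.estimate_, ds.detectors,
                                d.BufferSpec("MMDM"), ds.history)
secr = d.SECREstimator(detectors_used="all", seed=0).fit(ds.history,
                                                         ds.detectors)
```

With this seed the simulated landscape holds 373 animals (2.5/km² over
149 km²); 62 are photo-identified at cameras and 24 removed at traps. Every
trapped animal was already camera-marked (n₁=62, n₂=m=24), so the Chapman
estimate collapses to N̂ = 62 with zero sampling variance — a real LPE
behaviour in data-rich regimes. MMDM is 1.420 km, giving an effective area
of 28.00 km² and an LPE density of 2.21/km² against a truth of 2.50. The
trap-SECR fit estimates D = 2.58/km² (SE 0.34), σ = 0.529 km, g₀ = 0.403 —
SECR needs no ad-hoc buffer because the effective area is part of the
likelihood. The removal model sees the nightly catches
[7, 3, 4, 3, 1, 0, 2, 0, 1, 2, 1, 0, 0, 0] and estimates N₀ = 24 [24, 29]:
it can only speak for the trappable population, which is why its buffer
choice matters so much.

The same machinery runs from the shell:

```bash
densim simulate --seed 1 --sigma 0.6 --density 2.5 --g0 0.5 --out dataset/
densim fit --encounters dataset/encounters.csv --detectors dataset/detectors.csv \
           --effort dataset/effort.csv --estimator chapman --estimator trap_secr
densim grid --sigma 0.2 --sigma 1.2 --density 2.5 --g0 0.5 --replicates 5 \
            --estimator camera_lpe --seed 1 --out results.csv
densim summarize --results results.csv
```

The full factorial design (`GridSpec()` defaults) is 7 movement scales ×
12 densities × 7 detection probabilities = 588 combinations with 5
replicate datasets each; `run_grid` records every fit (including failures,
which stay visible as status rows) and `summarize` aggregates scaled bias
((D̂ − D)/D) and CV (SE/D̂, display-capped at 2.0) per cell.

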