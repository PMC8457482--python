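# Methods

## Model and estimation

The core quantity is a resource-selection probability function: the absolute
probability `w(x) ∈ (0,1)` that a landscape unit with covariates `x`
experiences a reported human–bear conflict, logistic in the linear predictor.
Data follow a use–availability design: the "used" sample is the set of
reported conflict locations (after cleaning and spatial thinning), the
"available" sample is drawn uniformly from the study region outside exclusion
buffers around the used points, at a fixed available:used ratio (default 5).
Available points are *not* absences; the likelihood accounts for this by
contrasting each used point's `w` against the availability-sample mean of
`w`:

    ℓ(β) = Σ_used [ log w(x_i; β) − log( mean_avail w(x_j; β) ) ]

Two consequences shape the numerics:

* `ℓ` is invariant to duplicating the availability sample, and identically
  zero whenever `w` is constant (so an intercept-only model always has
  `ℓ = 0`, AIC = 2).
* Under a logistic link the intercept — the absolute probability scale — is
  only weakly identified, and the likelihood is *unbounded* along any
  direction whose halfspace contains every used point while excluding part of
  the availability mass (the use–availability analogue of quasi-complete
  separation). The supremum on that ridge is approached only at infinite
  coefficients; the scientifically meaningful estimate is the interior
  stationary point.

Estimation therefore works on internally standardised coefficients (exact
affine reparameterisation; reported coefficients are mapped back to raw
covariate scales) with L-BFGS-B inside a box: slopes within ±60 and the
intercept within ±100 standardised units. The box does not bind for any
identified fit; it is a deterministic stop on the pathological ridge. A fit
whose standardised slope magnitude reaches 15 (an odds ratio above `e^15` per
covariate SD — never estimable signal) is declared *separated*: during model
search this is an error that excludes the subset (logged); during validation
refits the boundary fit is kept and flagged (`boundary_columns`), since only
the ranking of its scores matters there. An intercept pinned at the box edge
sets `intercept_weak`. Convergence requires the gradient infinity-norm below
1e-6 or a relative likelihood change below 1e-10, within 500 iterations.

The warm start is an ordinary used-vs-available logistic regression, clipped
to ±10 standardised units so a separated warm start cannot pin the
quasi-Newton run to the boundary from step one.

### Bootstrap

Standard errors are the SD of the estimate over `B` nonparametric bootstrap
refits (default 1000; heavy simulation tests use 200) that resample the used
and available strata independently with replacement, preserving stratum sizes
(unmatched design, `m = 0`; matched designs are out of scope). Refits
warm-start at the MLE clipped to ±10 standardised units — starting exactly at
a ridge estimate would pin every resample to the same edge and fabricate tiny
SEs. Non-converged refits are dropped and counted, with an error if more than
5% drop. p-values are two-sided normal Wald statistics on the bootstrap SE;
a bootstrap-percentile alternative would be straightforward but the Wald form
is what the reported tables imply.

## Point preparation

* **Thinning** enforces a minimum pairwise distance (default 5 km, the scale
  of a ~25 km² bear home range) by randomised greedy elimination: repeatedly
  delete a uniformly chosen point among those with the most neighbours closer
  than the minimum, rerun over `n_repetitions` (default 100) independent RNG
  substreams, and keep the run retaining the most points (ties: lowest run
  index). Against exhaustive maximum-independent-set enumeration on 12-point
  instances the greedy optimum matches ≥ 90% of the time.
* **Background** points are proposed uniformly over the region mask (uniform
  cell, uniform offset within it) and accepted iff at least `buffer_radius`
  (default 5 km) from every used point — an exact per-point disc test, never
  a rasterised buffer, so the 50 m grid introduces no edge artefacts. The
  ratio is exactly 5 available per used. A proposal cap (10^6) turns
  buffer-saturated landscapes into an informative error.

## Covariate engineering

Grids are planar, metres, row-major from the upper-left origin; cell
membership is half-open so boundary coordinates resolve deterministically to
the lower index. Distance layers are centre-to-centre Euclidean distance
transforms. The two heavy-tailed layers (distance to forest, population
density) are log-transformed with a configurable offset, default +1, because
both supports include zero. Nearest-neighbour resampling is used for
alignment; categorical codes are never interpolated. Collinearity screening
computes `VIF_j = 1/(1−R²_j)` and removes the worst offender until all are
below 10, then drops the lower-priority member of any pair with squared
Pearson correlation above 0.7 — the priority ordering is a required input
because "more relevant to bears" is a judgment, not a statistic. Aspect, if
supplied, is treated as plain continuous (its circularity is ignored, a known
simplification).

## Model selection

All `2^n` subsets of the screened covariates are fitted (land cover is one
atomic term: all dummies in or out; the reference class is the most frequent
class in the availability sample and is recorded in the fit metadata because
coefficients are contrasts against it). The bootstrap is disabled during the
search — AIC needs only the MLE — and applied once to the selected model.
Selection follows the conventional parsimony rule: among candidates within
ΔAIC ≤ 2 of the best, the fewest terms win; ties break by lower AIC, then
lexicographic term order.

A calibration fact worth knowing: with `q` irrelevant candidate covariates
the true submodel survives this rule only when the summed spurious AIC
improvements `Σ(χ²₁ − 2)⁺` stay below 2, which for `q = 5` happens with
probability ≈ 0.76 even in the nominal asymptotic regime. Exhaustive AIC
search *overselects by design*; the parsimony window mitigates but does not
eliminate it. The selection-consistency test in the suite documents this
honestly rather than hiding it.

## Validation

AUC uses the rank (Mann–Whitney) formulation with mid-rank ties. The decision
threshold is the equal-sensitivity/specificity cut: candidates are all
distinct scores plus midpoints between consecutive distinct scores, the
lowest minimiser of |sens − spec| wins. The convention is fixed everywhere:
"conflict" means score ≥ threshold, so conflict omission is the used fraction
strictly below the threshold and non-conflict omission the available fraction
at or above it. "Overall omission" is reported under both common definitions
— pooled misclassified fraction and unweighted mean of the two class rates —
because they differ on imbalanced samples and published tables are ambiguous
about which was used. Thresholds are always derived on training data and
applied to test data. Two designs: spatial holdout (train outside a focal
subregion, test inside) and stratified k-fold (default 5; each fold tests
once). A configurable robustness gate (AUC > 0.7, overall omission < 0.3)
marks reports pass/fail.

## Risk projection

The fitted `w` is evaluated cell-wise over the raster stack with exactly the
design encoding used at fit time; nodata in any required layer propagates.
Projection streams in row blocks (default 256 rows) so statewide 50 m grids
fit in bounded memory; the block size provably does not change the output
(asserted in tests). Hotspot classes use half-open bins — a value exactly at
a break goes to the class above.

## Synthetic landscapes

Continuous covariates are smoothed Gaussian white noise: a uniform
moving-average kernel of the stated range (cells), rescaled to the requested
mean and SD; range 1 is white noise, larger ranges raise lag-1 Moran's I.
Land cover is an independent latent field sliced at quantile breaks (default
equal shares over 8 classes), which keeps classes spatially coherent. Used
points are drawn by rejection sampling — propose uniform over the region
mask, accept with probability `w(x)` — so `w` acts as an absolute
probability, exactly the RSPF semantics; the empirical acceptance rate
converges to the spatial mean of `w`. The focal subregion grows by
breadth-first search from the region's central cell to a target fraction of
cells, guaranteeing contiguity.

Default study conditions place conflicts at a strongly selected urban–
wildland interface (true `w` spanning most of the unit interval; in the
rare-hotspot regime for validation demonstrations). Sample sizes follow the
motivating design: ~700 used points at a 5:1 availability ratio for recovery
experiments, 1000 for selection experiments; heavier Monte Carlo suites run
at those sizes with B = 200.

What the generator does *not* emulate: real terrain or land-cover
proportions, complaint-reporting effort and its demographic drivers, temporal
structure (seasonality, repeat complaints), and coordinate error. Passing
tests therefore demonstrate the *estimator and pipeline* are correct under
the model's own assumptions, not that the model is an adequate description of
any particular landscape's conflict process.

## Known limitations

* The logistic-RSPF intercept is weakly identified unless `w` approaches 1
  somewhere in the data; intercept estimates should be read with the
  `intercept_weak` flag in hand.
* With weak signal or small samples the likelihood's separating ridge can
  attract the optimiser; such fits are flagged or excluded as described, but
  their AIC values (a plateau supremum) remain approximate.
* AIC subset search overselects with known probability (above); effect
  estimates after selection carry the usual post-selection optimism.
* Validation AUC has a structural ceiling when used and available points
  share the landscape: for a symmetric `w` field it cannot exceed ~0.75; high
  AUC requires the rare-hotspot regime.
* No spatially blocked cross-validation beyond the single focal-region
  holdout; no matched designs; no model averaging.
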