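# Methods

This note documents the models, the defaults and their rationale, the
numerical choices, and what the synthetic-data validation does and does not
establish.

## Signal model of the synthetic movies

Raw fluorescence is generated multiplicatively,

    F(t, x, y) = F0(x, y) · (1 + R + S + H) · B(t) + ε,

so that ΔF/F = F/F₀ − 1 recovers the injected components exactly in the
noise-free limit and blank subtraction cancels the multiplicative artifacts
to first order.  Components:

- **Evoked response `R`.**  At distance `d` (μm) from the wavefront center
  the local time is `tl = t − t_onset − d/v` with propagation speed `v`.
  The response is `A · g(tl) · exp(−d/λ(tl))` where `g` is a rise/decay
  double exponential normalized to peak 1 (analytic peak time
  `t* = ln(τ_d/τ_r)·τ_rτ_d/(τ_d−τ_r)`), and `λ(tl) = λ₀ + λ'·tl` is an
  exponential distance-damping length growing slowly with local time.
  The exponential (rather than Gaussian) distance profile is a deliberate
  choice: its cusp keeps the early response confined to a single barrel
  column while its heavy tail still reaches the outer rings at later
  times, and — because the envelope is nearly static — ring latencies are
  set by the propagation delay `d/v`.  A Gaussian envelope whose width
  grows with time cannot do all three at once: any growth rate large
  enough to reach the outer rings makes the envelope growth, not the
  delay, determine ring peak times (pushing them to 100–200 ms), while a
  growth small enough for sane latencies never reaches the outer rings.
- **Spontaneous activity `S`.**  Spatiotemporal white noise convolved with
  an isotropic Gaussian of sd `spont_corr_length` (wrap-around boundary, so
  the field is stationary), normalized to unit variance, passed through a
  per-frame AR(1) with coefficient 0.8, and scaled to `spont_amplitude`.
- **Heartbeat `H`.**  A spatially uniform 9 Hz sinusoid with a fresh
  uniform phase every trial.  Its amplitude models the *residual* artifact
  after standard normalization.  Being spatially uniform, it survives
  spatial shuffling; an amplitude much above ~1×10⁻⁴ would therefore put a
  visible floor under the shuffle null, which is not what blank-corrected
  recordings show.
- **Bleaching `B`.**  One shared exponential, time constant 5×10⁴ ms
  (≈0.5%/250 ms) — deterministic, hence removed exactly by blank
  subtraction (and by residualization, since it is trial-invariant).
- **Vessels and resting light.**  `F0` carries a smooth 2% multiplicative
  staining/illumination texture (correlation length 3 px) — static per
  animal, removed exactly by ΔF/F, but essential for vessel detection to
  have a physical background scale.  Vessels are seeded random walks
  (width 1–2 px, ≤15% coverage) that depress `F0` by 20%.  Cohort
  generation keeps an 8 px disc at the field center vessel-free, as an
  experimenter centering the camera on a clean barrel would.
- **Shot noise `ε`.**  White, sd `noise_sd · F0` per pixel and frame.

### Default parameters

| parameter | Ctrl-like | Tg-like | units | why |
|---|---|---|---|---|
| evoked_amplitude | 4.3×10⁻³ | 7.3×10⁻³ | ΔF/F | group peak amplitudes at the reported scale (ratio ≈ 1.7) |
| spread_sigma0 (λ₀) | 650 | 650 | μm | early 20 ms area ≈ one barrel (ROI ~15 px at the 77.5% threshold); identical across groups so early maps match |
| spread_growth (λ') | 0.5 | 1.5 | μm/ms | late broadening; larger in Tg-like so the late activated area is wider |
| propagation_speed | 40 | 40 | μm/ms | ring-to-ring latency steps of ~5 ms (200 μm rings) |
| rise_tau / decay_tau | 15 / 160 | 22 / 160 | ms | center time-to-peak ≈ 42 ms (Ctrl) vs ≈ 53 ms (Tg, ~10 ms later, smaller max derivative); half-peak decay ≈ 150 ms |
| spont_corr_length | 100 | 60 | μm | spontaneous spatial coherence; shorter in Tg-like, giving neighborhood synchrony ≈ 0.18 vs ≈ 0.10 |
| spont_amplitude / noise_sd | 5×10⁻⁴ / 5×10⁻⁴ | same | ΔF/F | clean-staining regime: 20-trial averages recover the wavefront center to ±1 px ≥95% of the time and give barrel-scale ROIs |
| heartbeat 9 Hz, amp 1×10⁻⁴; bleach 5×10⁴ ms; AR 0.8 | both | | | see above |

Between-animal variability: multiplicative log-normal jitter (sd 10%,
median-preserving) on amplitude, kinetics and spread parameters.

## Analysis pipeline

Order is fixed and enforced: ΔF/F → blank subtraction → vessel exclusion →
analysis; the σ = 1.5 px display smoothing is terminal-only.

- **ΔF/F** uses the mean of the 3 frames (30 ms) before stimulus onset
  (first 3 frames for unstimulated trials).  `F/F₀ − 1` and `(F−F₀)/F₀`
  are algebraically identical.
- **Vessel detection**: |high-pass residual| > 3 × (1.4826 × MAD), σ = 2 px.
  The threshold rule is this package's choice (robust to the vessels' own
  outliers); a tiny absolute floor keeps float dust on constant frames
  unflagged.  Detected masks dilate the true vessel by ~1–2 px (the
  high-pass spreads a line into its neighborhood); this is accepted and
  reported, not corrected.
- **Barrel ROI**: argmax pixel of the 20 ms frame (ties → smallest row,
  then column), thresholded at 77.5% of the center value, restricted to
  the center's 8-connected component so disjoint noise pixels cannot join
  (4-connectivity available).  Note a *relative* threshold is invariant to
  positive scaling of the frame but not to arbitrary monotone transforms.
- **Temporal metrics**: forward first differences on the raw 100 Hz grid,
  no smoothing (values are per 10 ms frame; ×0.1 for per ms); derivative
  maximum over the rising extent, minimum over the post-peak extent;
  half-peak time by linear interpolation of the first post-peak crossing,
  with a reported error (never silent clipping) if the trace does not get
  there.  Peak times use the earliest-tie rule; ring latencies use a
  three-point parabolic refinement because the ~5 ms ring-to-ring steps
  are below the 10 ms frame.
- **Rings**: half-open annuli `(i−1)·w < d ≤ i·w` in Euclidean pixel
  distance, w = 200 μm = 4 px, 4 rings; the center pixel belongs to no
  ring; clipped or vessel-masked pixels are counted and warned about past
  20%.  Profiles are normalized to the inner-ring value at 20 ms; sample
  times default to 20/50/80 ms.
- **Synchrony**: residuals = single trials minus the trial average
  (2500 ms window for spontaneous, 150 ms post-stimulus for evoked);
  windowed Pearson r over 9 frames (center ± 4, honoring the ±40 ms
  reading of an 80 ms window); per-window r values combined by plain
  (count-weighted) averaging over trials, window positions and seeds —
  not Fisher-z, matching the field's convention of averaging correlation
  values.  Zero-variance windows are missing, never zero.  The seed cell
  (r = 1 by definition) is excluded from maps and scalars.  Neighborhood
  radius: floor(200 μm / 50 μm) = 4 px, Euclidean.  The shuffle null
  freshly permutes non-vessel pixel positions within every frame of every
  trial (the stricter per-frame reading) and reruns the whole aligned
  pipeline per iterate; since the scalar only reads cells within the
  neighborhood radius, null iterates use a radius-sized patch — cell-for-
  cell identical to the wide-patch computation restricted to those cells.
- **Statistics**: two-sided throughout; the animal (never the trial) is
  the unit; exact rank-sum for combined n ≤ 20 without ties, exact
  signed-rank for ≤ 25 nonzero, tie-free pairs, else tie-corrected normal
  approximation (the choice is recorded).  The asymptotic branch uses no
  continuity correction so exchangeable samples give p = 1 exactly.  Zero
  paired differences are dropped and counted.  No multiple-testing
  correction is applied, and reports flag this.

## Validation: what it shows and what it does not

The suite checks the pipeline three ways: algebraic identities (constant
movies, scale invariance, exact cancellation), independent oracles
(nested-loop Pearson maps to 1e−10, enumeration of rank-test distributions,
lattice enumeration of ring geometry, closed-form response peak times), and
parameter recovery on synthetic cohorts (amplitude ratio, synchrony
ordering in the spontaneous correlation length, shuffle-null calibration,
rank-test size and power).

The generator reproduces the *statistical structure* the pipeline assumes —
not biophysics.  It omits dye kinetics, cortical lamination, hemodynamic
contamination, motion, plaque geometry, and any nonstationarity of
spontaneous activity; its noise is Gaussian rather than photon-limited.
Passing tests therefore establish that the implementation measures what it
claims on data of the assumed form, not that the assumptions hold for any
particular recording.  Two quantitative caveats surfaced during
development and are documented deliberately:

- On small grids a spatially correlated field has a per-frame spatial mean
  that survives shuffling, so the shuffle null is only near zero when the
  field is much larger than the correlation area; the ±0.02 null check is
  run at the full 100 × 100 grid.
- The observed synchrony of *white* input is a draw from the shuffle null
  only under per-frame exchangeability, which the heartbeat (a common
  temporal component) and the AR(1) continuity both break; the
  corresponding check switches them off.

## Problem sizes

Simulation studies in the tests and the acceptance script run at reduced
sizes chosen to keep the statistical content intact: 60 × 60 px fields
(same 50 μm pitch), 12–40 frames per evoked trial, 6 spontaneous trials of
the full 2500 ms window, 3–10 blanks, single-precision movies for the
500-cohort power study.  Animal counts (8 vs 6), evoked trial counts (20),
the 100-shuffle null, all window lengths and all thresholds are kept at
their full study values.

One further limitation: in the real experiment, stimulus-driven
synchronization equalized the groups' evoked-state synchrony even though
their spontaneous synchrony differed.  The generator has no mechanism for
that — evoked-trial residual correlations inherit each group's spontaneous
correlation length — so synthetic evoked synchrony differs between groups
whenever spontaneous synchrony does.
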