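# Methods

This note documents the models, estimators and numerical choices behind
`smstoich`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Photobleaching model and trajectory simulation

A focus carrying `k` fluorophores is modeled as a sum of independent
emitters. Each emitter draws a constant emission level once from
`N(step_mu, step_sigma²)` truncated at 0 (a fluorophore with non-positive
intensity is unobservable) and keeps it until it bleaches; bleach times
are geometric per frame with probability `1 − exp(−bleach_rate)`, the
frame-discretized exponential — frames are the observable unit at 5 Hz
(200 ms). Additive Gaussian noise models the EMCCD read-out. Blinking is
off by default, matching acquisition under an oxygen-scavenger system;
when enabled it is a two-state on/off Markov chain per fluorophore.
Emission is constant between steps — no slow drift — which is exactly the
piecewise-constant model the step detector assumes.

Channel defaults reproduce the reported single-step intensity
distributions: client/AF647 170.5 ± 99 a.u., chaperone/AF488
166 ± 119 a.u.

## Change-point step detection

`detect_steps` minimizes the within-segment sum of squares plus a
per-change-point penalty `beta = penalty · σ̂² · log n` over all
segmentations with segments of at least `min_dwell` frames, by exact
O(n²) dynamic programming (optimal partitioning). `σ̂` is the robust
noise sd from the median absolute successive difference
(`MAD(diff)·1.4826/√2`), which is insensitive to the sparse true steps.
Adjacent plateaus closer than `min_step` (default `0.5 σ̂`) are merged,
smallest gap first. Defaults: `penalty = 2.5` (BIC-like; chosen so that
noise-driven false steps are rare at step SNR 5 while true steps down to
~2.5 σ̂ with a few frames of dwell are kept), `min_dwell = 3` frames for
general use.

Numerical floors keep the penalty and `min_step` above the float-rounding
noise of the prefix-sum costs (relative to `mean(x²)`), so noise-free
piecewise-constant traces are segmented exactly — zero residual, a
property the test suite asserts for 1–8 steps.

## Single-step calibration: censoring and coincidence

The single-fluorophore intensity `I_s-mean` is estimated from pooled
detected downward steps. Two sampling artifacts of any change-point
detector must be modeled, or the estimate is biased by +10–25% under
realistic conditions:

1. **Completeness (left-censoring).** A step with adjacent dwells
   `d1, d2` is detected only if it reduces the squared error by more than
   `beta`, i.e. only if its height exceeds `c = sqrt(beta/w)` with
   `w = d1·d2/(d1+d2)`. Small steps are therefore missing from the pool,
   and the missingness threshold is *known per observation*. The fit
   treats each pooled step as left-censored at its own `c`, with
   measurement sd `σ̂·sqrt(1/d1 + 1/d2)`.
2. **Coincidence.** Two fluorophores bleaching within the dwell
   resolution appear as one step of summed height. The model is a
   mixture whose m-th component is the m-fold sum of the truncated
   single-step distribution (Gaussian approximation via the truncated
   moments), with weights constrained to decrease in m — physically
   guaranteed, since an m-fold coincidence requires m−1 independent
   near-simultaneous bleach times, and necessary for identifiability:
   with a broad single-step distribution (CV ≈ 0.6) an unconstrained
   mixture can collapse onto a spurious low mean.

The likelihood is maximized by Nelder–Mead over
`(μ, log σ, weight ratios)`. With no censoring information and one
component this reduces to zero-truncated Gaussian ML, and further to the
plain sample mean/sd when the data are far from the truncation bound.
`calibrate_single_step` runs detection at `min_dwell = 1` (the finest
resolution, minimizing coincidences) and reports the single-step `μ` as
`I_s-mean`. Under the validation conditions (1000 trajectories of 2–8
fluorophores, 200 frames, mean bleach 30 frames, noise sd 25) the
generative means are recovered to ~1–4%; the naive pooled mean is ~14%
high under the same conditions.

The calibration replaces the manual curation of "distinct" bleaching
steps that a human analyst performs: the quality rules (`AcceptRules`)
are explicit — all steps downward (upward steps indicate blinking or
arrival of a second molecule), and by default a final plateau at
background. The pipeline relaxes the final-plateau rule when movies end
before every fluorophore has bleached, since detected downward steps
from partially bleached traces are equally valid single-bleach events.

## Subunit counting (FPP)

`I_0` is the arithmetic mean of a focus's first 20 frames — deliberately
not a change-point plateau, since segmentation becomes unreliable for
large complexes. `FPP = I_0 / I_s-mean`; the subunit count is FPP rounded
half-up and clamped to a minimum of 1 (a detected focus implies at least
one fluorophore). Counts above 20 are flagged excluded — fluorophore
self-quenching at high local density makes larger counts unreliable —
and retained with the flag; summaries report the excluded fraction
rather than dropping records. The rounding rule and the minimum of 1 are
this package's choices, exposed in the API.

Because `I_0` and `I_s-mean` are measured through the same aperture, the
PSF-truncation factor of the aperture cancels in FPP. What does not
cancel is bleaching inside the 20-frame `I_0` window: `I_0` underestimates
the true initial intensity by the mean alive-fraction over those frames
(≈ `exp(−10·bleach_rate)`), so accurate counting requires bleaching slow
relative to 4 s — the regime the imaging conditions target.

## Image pipeline

Camera model: `I = offset + flatfield · signal + N(0, read_noise²)`;
`correct_stack` inverts it as `(I − offset)/flatfield`, exactly in the
noise-free case. The corrected stack is clipped at 0 by default (for
display and detection); trajectory extraction uses the unclipped
correction, because rectifying zero-mean noise raises the post-bleach
baseline and compresses step heights by several percent.

Foci are local maxima of the mean of the first 10 frames (before
bleaching erodes signal) above a robust background threshold
(median + k·MAD-sd, default k = 5), separated by at least 3 px, refined
to sub-pixel positions by background-subtracted centroid. Coordinates
are 0-based (row, col) with pixel centers at integers. Trajectories are
aperture sums (radius 3 px) minus the annulus median (5–7 px) times the
aperture area; the median is robust to a neighboring focus intruding
into the annulus, and any spatially uniform background cancels exactly.

Colocalization uses greedy mutual-nearest matching: candidate cross-
channel pairs within the radius (default 2 px, near the diffraction
limit; the radius is a config parameter, not a value taken from the
source study) are accepted in order of increasing distance, each focus
used at most once. The matching is deterministic, order-independent
(ties broken by row then column), and maximal. Channel registration is
assumed identity; an affine hook can be applied upstream if needed.

## Two-step binding simulation

The population simulator is an exact event-driven (Gillespie) simulation
with three event types over a well-mixed, depletable free-chaperone
subunit pool of initial size `molar_ratio · n_clients`:

* **capture** — a binding-competent free client is bound by a free sHsp
  seed species (size drawn from `shsp_seed_dist`, mass on 1–3mers) at
  rate `k_bind` per client;
* **accretion** — a bound complex gains one subunit at rate
  `k_accrete · (free pool fraction)`;
* **dissociation** — a complex with more than one chaperone subunit
  loses one at rate `k_off`.

The equilibrium bound-client fraction is modeled by making each client
binding-competent with probability `plateau_bound_fraction`: the
expected bound fraction is then exactly
`plateau · (1 − e^(−k_bind·t))` — the one-phase association form used to
fit colocalization kinetics. Defaults (`k_bind = 1/h`,
`k_accrete = 0.3/h`, `k_off = 0.05/h`, ratio 2:1, plateau 0.5) emulate
kinetics that rise steeply in the first hour and plateau at ~50% by 4 h
while complexes keep accreting subunits. Tests validate the simulator
against a closed-form/ODE mean-field oracle in a linear-rate regime
(instant capture, no dissociation) where the mean-field solution is
exact.

The initial client oligomer size distribution is not constrained by any
reported measurement at the subunit level; it is a configuration
parameter (default concentrated on 1–5mers).

## Movie rendering

Each focus is a pixel-integrated 2-D Gaussian PSF (error-function
differences over each pixel's unit square, on a patch of ±(4σ+1) px)
scaled by its instantaneous trajectory value; channels are rendered
independently, labeled subunit counts are binomial thinnings of the true
counts, then offset, flat-field and read noise are applied. Positions
are sampled uniformly with a minimum separation of 4·psf_sigma by
default (overlap can be allowed). Foci are immobilized — no diffusion —
matching a surface-tethered assay, and the camera is Gaussian-noise
only (no photon-level EM gain register model).

## Aggregation curves

Light-scatter (A340) curves are logistic sigmoids with a lag phase.
Chaperone suppression `s` scales the aggregation *extent* (amplitude)
with a shared time course, so the endpoint statistic
`percent inhibition = ((ΔIc − ΔIs)/ΔIc)·100` equals `100·s` exactly on
noise-free curves at any assay horizon; a rate reduction would make the
statistic horizon-dependent without changing what it estimates. ΔI is
defined initial-to-final (optionally window-averaged endpoints, which
reduces variance on noisy plate-reader data); negative inhibition
(aggregation enhancement) is reported, not clipped.

## Statistics

Kruskal–Wallis (tie-corrected, via scipy) is the omnibus test for
subunit-size distributions across groups; pairwise Dunn z-tests on the
pooled ranks use the standard tie-corrected variance and Bonferroni
adjustment by default (the common convention for "Dunn's procedure";
Holm and unadjusted are available). The asymptotic omnibus p-value is
cross-checked against a permutation oracle in the tests. Violin
summaries report median, quartiles and a Gaussian KDE (Silverman
bandwidth) with kernel reflection at 1, since counts are bounded below;
the reflected density integrates to 1 on [1, ∞).

One-phase association fits use bounded nonlinear least squares
(`k ≥ 0`), initialized from the data span; flat data return
`plateau = y0`, `k = 0` with a warning rather than an error.

## Validation scales and what they show

Desk-scale problem sizes keep the full suite fast: 300–1000 simulated
trajectories for calibration recovery; 50 replicates × 500 molecules for
kinetics; one 50-complex, 2000-frame, 160×160 two-channel movie for the
end-to-end test (counts 1–8, per-fluorophore CV 6%, extracted-trace step
SNR ≈ 6, mean bleach 1200 frames), which recovers exact per-focus counts
for ≥ 90% of foci and the joint stoichiometry histogram within
total-variation distance 0.1.

Passing these tests shows the estimators are consistent and the pipeline
is unbiased *under the generative model*: constant emission, Gaussian
noise, isolated immobilized foci, known camera. Real data add
photophysics the generator deliberately omits — partial quenching,
FRET between labels, non-Gaussian EMCCD noise, drift, overlapping foci —
so quantitative accuracy there depends on how well those assumptions
hold, not on these tests. The per-fluorophore intensity CV of the
end-to-end fixture (6%) is far narrower than the reported single-step
distributions (CV ≈ 0.6); with realistic CV, exact integer recovery of
large counts is information-theoretically impossible for any estimator,
and FPP counts should be read as distributions, not exact integers —
which is how the heatmap and violin summaries treat them.

## Known limitations

* FRET traces are leakage-corrected proximity ratios only — no gamma
  correction or distance calibration.
* The change-point engine is exact for the L2 cost but O(n²); for
  10⁵-frame traces a pruned variant would be preferable.
* `I_0` frame-averaging undercounts when bleaching is fast relative to
  the 20-frame window; the bias factor is `≈ exp(−10·bleach_rate)`.
* The Gillespie simulator treats the free sHsp pool as well mixed and
  ignores client aggregation after capture.
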