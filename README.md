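# smstoich

Subunit stoichiometries of chaperone–client complexes from two-color
single-molecule photobleaching data.

## The problem

Small heat shock proteins (sHsps) such as alphaB-crystallin (αBc) are
ATP-independent chaperones that trap misfolded client proteins and prevent
their aggregation. Because both the chaperone oligomers and the complexes
they form with clients are dynamic and polydisperse, bulk methods cannot
resolve how many chaperone and client subunits a given complex contains.
Two-color TIRF microscopy of surface-immobilized complexes can: each
diffraction-limited focus is imaged until every fluorophore has
photobleached, and the discrete intensity drops count the labeled subunits.

`smstoich` implements that analysis as a tested, reusable pipeline, for
single-molecule microscopists and method developers:

* **change-point step detection** on per-focus intensity trajectories —
  exact penalized least-squares segmentation (piecewise-constant model,
  BIC-style penalty) with dwell and step-size constraints;
* **single-step calibration** — the pooled single-bleach intensities
  `I_s` are fit with a truncated-Gaussian maximum-likelihood model that
  corrects for the detector's completeness limit (steps below the local
  detection threshold are censored) and for coincident bleach events
  (components at integer multiples of the single-step intensity), giving
  the single-fluorophore intensity `I_s-mean`;
* **subunit counting** — `FPP = I_0 / I_s-mean`, where `I_0` is the mean
  of a focus's first 20 frames; FPP is rounded to a subunit count, and
  counts above 20 are flagged (fluorophore self-quenching makes them
  unreliable) but never silently dropped;
* **two-channel colocalization** (greedy mutual-nearest matching) and
  pairing of per-channel counts into complex stoichiometries, with
  abundance heatmaps, one-phase association fits of colocalization
  kinetics `y(t) = y0 + (plateau − y0)(1 − e^(−kt))`, violin-style
  size-distribution summaries, and Kruskal–Wallis/Dunn group comparisons;
* **bulk aggregation assay statistics** — the endpoint light-scatter
  percent-inhibition, `((ΔIc − ΔIs)/ΔIc) × 100`;
* a **synthetic-data generator** embodying a two-step binding mechanism
  (small free sHsp species first capture misfolded clients; bound
  complexes then accrete further sHsp subunits from a depletable pool),
  plus photobleaching-trajectory simulation, binomial labeling thinning,
  and a two-channel movie renderer (pixel-integrated Gaussian PSFs,
  EMCCD-like offset/flat-field/read-noise camera) — so every stage of the
  pipeline is verifiable by parameter recovery against known ground truth.

## Worked example

Calibrate the single-fluorophore intensity from simulated multi-step
photobleaching trajectories (`examples/01_step_calibration.py`):

```python
import numpy as np
from smstoich import (FluorophorePhotophysics, calibrate_single_step,
                      simulate_trajectory)

rng = np.random.default_rng(1)
pp = FluorophorePhotophysics(step_mu=170.5, step_sigma=99.0, bleach_rate=1/30)
trajs = []
for _ in range(500):
    traj, _ = simulate_trajectory(int(rng.integers(2, 9)), pp,
                                  n_frames=200, noise_sd=25.0, seed=rng)
    trajs.append(traj)
dist = calibrate_single_step(trajs, label="client")
```

This prints:

```
pooled steps:        n = 2126
fitted I_s-mean:     164.0 a.u.  (generative 170.5)
fitted I_s-sigma:    103.3 a.u.  (generative 99)
single/coincident:   0.95 / 0.05
```

The fitted `I_s-mean` recovers the generative single-step intensity to a
few percent even though each trajectory mixes 2–8 overlapping bleach
events in noise; ~5% of detected steps are attributed to coincident
double bleaches. Dividing a focus's initial intensity by `I_s-mean`
yields its subunit count.

The other examples walk through binding kinetics and the one-phase
plateau fit (`02`), the full movie→stoichiometry pipeline with a
recovered joint abundance heatmap (`03`), percent inhibition by molar
ratio (`04`), and size-distribution comparisons (`05`). Each prints the
numbers it computes and a line on what they mean.

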