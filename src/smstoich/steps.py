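"""Photobleaching step analysis and subunit counting.

A surface-immobilized complex carrying ``k`` fluorophores emits at a roughly
constant level until, one by one, the fluorophores irreversibly photobleach,
producing a step-wise decreasing intensity trajectory.  This module turns such
trajectories into subunit counts:

1. :func:`detect_steps` fits a piecewise-constant model to a trajectory by
   penalized least-squares change-point segmentation and reports the plateau
   levels and the per-event intensity drops (``I_s``).
2. :func:`pool_single_steps` applies programmatic quality rules to collect
   clean single-bleach intensities across many trajectories.
3. :func:`fit_single_step_distribution` fits a (zero-truncated) Gaussian to
   the pooled ``I_s`` values; its location is the single-fluorophore intensity
   ``I_s-mean``.
4. :func:`compute_fpp` divides a focus's initial intensity ``I_0`` (mean of
   its first 20 frames, :func:`initial_intensity`) by ``I_s-mean`` to obtain
   the number of fluorescently labeled proteins per point (FPP), rounded to an
   integer subunit count; counts above 20 are flagged as excluded because
   self-quenching makes them unreliable.

:func:`fret_trace` computes leakage-corrected proximity-ratio (FRET
efficiency) traces from donor/acceptor trajectory pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Trajectory",
    "StepFit",
    "AcceptRules",
    "SingleStepDistribution",
    "FPPResult",
    "FretTrace",
    "initial_intensity",
    "detect_steps",
    "pool_single_steps",
    "fit_single_step_distribution",
    "calibrate_single_step",
    "compute_fpp",
    "fret_trace",
]

#: Number of leading frames averaged to estimate the initial intensity I_0.
I0_FRAMES = 20


@dataclass
class Trajectory:
    """Per-focus fluorescence intensity versus frame for one channel.

    Parameters
    ----------
    intensities : array
        Background-subtracted intensity per frame (a.u.).
    frame_interval : float
        Seconds per frame (default 0.2 s, i.e. 5 Hz acquisition).
    focus_id : str or int, optional
        Identifier linking the trajectory to a detected focus.
    channel : str, optional
        Channel label (e.g. ``"client"`` / ``"chaperone"``).
    """

    intensities: np.ndarray
    frame_interval: float = 0.2
    focus_id: object = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 1:
            raise ValueError("intensities must be a non-empty 1-D array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.size

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class StepFit:
    """Piecewise-constant fit of one trajectory.

    ``change_points`` are the frame indices at which a new plateau starts
    (strictly increasing, excluding frame 0).  ``levels`` holds one plateau
    mean per segment; ``step_heights`` are the successive level differences,
    positive for downward (bleaching) steps.  ``dwells`` are segment lengths
    in frames.
    """

    change_points: np.ndarray
    levels: np.ndarray
    step_heights: np.ndarray
    dwells: np.ndarray
    noise_sd: float
    penalty_beta: float = 0.0
    focus_id: object = None
    channel: str = ""

    @property
    def n_steps(self) -> int:
        return self.step_heights.size

    def fitted(self, n_frames: int | None = None) -> np.ndarray:
        """Return the piecewise-constant fitted trace."""
        if n_frames is None:
            n_frames = int(self.dwells.sum())
        return np.repeat(self.levels, self.dwells)[:n_frames]


def initial_intensity(traj: Trajectory) -> float:
    """Initial intensity ``I_0``: arithmetic mean of the first 20 frames.

    Raises
    ------
    ValueError
        If the trajectory is shorter than 20 frames.
    """
    if traj.n_frames < I0_FRAMES:
        raise ValueError(
            f"I_0 requires at least {I0_FRAMES} frames; trajectory has "
            f"{traj.n_frames}"
        )
    return float(traj.intensities[:I0_FRAMES].mean())


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise scale from the median absolute successive difference.

    For a piecewise-constant signal plus white noise the first differences
    are noise except at the (sparse) change points, so
    ``MAD(diff) * 1.4826 / sqrt(2)`` estimates the per-frame noise sd
    robustly.
    """
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(stats.median_abs_deviation(d, scale="normal") / np.sqrt(2.0))


def _segment_means(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.array(
        [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )


def _optimal_partition(
    x: np.ndarray, beta: float, min_dwell: int
) -> np.ndarray:
    """Exact penalized least-squares segmentation.

    Minimizes sum of within-segment squared deviations plus ``beta`` per
    change point, over all segmentations whose segments are at least
    ``min_dwell`` frames long, by O(n^2) dynamic programming.  Returns the
    segment boundaries including 0 and n.
    """
    n = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    big = np.inf
    F = np.full(n + 1, big)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    for j in range(min_dwell, n + 1):
        # candidate previous boundaries: 0, or any i with both sides >= min_dwell
        i = np.arange(0, j - min_dwell + 1)
        i = i[(i == 0) | (i >= min_dwell)]
        seg_n = j - i
        seg_sum = s1[j] - s1[i]
        cost = (s2[j] - s2[i]) - seg_sum * seg_sum / seg_n
        tot = F[i] + beta + cost
        k = int(np.argmin(tot))
        F[j] = tot[k]
        last[j] = i[k]
    if not np.isfinite(F[n]):  # trace shorter than min_dwell: one segment
        return np.array([0, n])
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(last[bounds[-1]]))
    return np.array(bounds[::-1])


def _merge_small_steps(
    x: np.ndarray, bounds: np.ndarray, min_step: float
) -> np.ndarray:
    """Iteratively merge adjacent segments whose level difference is below
    ``min_step``, smallest difference first."""
    bounds = list(bounds)
    while len(bounds) > 2:
        levels = _segment_means(x, np.array(bounds))
        gaps = np.abs(np.diff(levels))
        k = int(np.argmin(gaps))
        if gaps[k] >= min_step:
            break
        del bounds[k + 1]
    return np.array(bounds)


def detect_steps(
    traj: Trajectory,
    penalty: float = 2.5,
    min_step: float | None = None,
    min_dwell: int = 3,
) -> StepFit:
    """Detect photobleaching steps by penalized change-point segmentation.

    The trace is fit with a piecewise-constant model by exact penalized
    least-squares (optimal partitioning); the per-change-point penalty is
    ``penalty * sigma_hat**2 * log(n)`` with ``sigma_hat`` the robust noise
    sd from first differences — a BIC-style criterion.  Segments shorter than
    ``min_dwell`` are disallowed, and adjacent plateaus closer than
    ``min_step`` (default ``0.5 * sigma_hat``) are merged.

    A constant trace yields zero change points; on noise-free step traces the
    segmentation is exact (zero residual).
    """
    x = traj.intensities
    n = x.size
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    if n < 2 * min_dwell:
        raise ValueError(
            f"trajectory has {n} frames; need at least 2*min_dwell = "
            f"{2 * min_dwell} for segmentation"
        )
    sigma = _robust_noise_sd(x)
    # floors keep the penalty above float-rounding noise in the prefix-sum
    # costs so noise-free traces segment exactly (no zero-height splits)
    scale2 = max(float(np.mean(x * x)), 1.0)
    if min_step is None:
        min_step = max(0.5 * sigma, 1e-7 * np.sqrt(scale2))
    beta = max(penalty * sigma * sigma * np.log(n), 1e-9 * scale2)
    bounds = _optimal_partition(x, beta, min_dwell)
    bounds = _merge_small_steps(x, bounds, min_step)
    levels = _segment_means(x, bounds)
    return StepFit(
        change_points=bounds[1:-1],
        levels=levels,
        step_heights=levels[:-1] - levels[1:],
        dwells=np.diff(bounds),
        noise_sd=sigma,
        penalty_beta=beta,
        focus_id=traj.focus_id,
        channel=traj.channel,
    )


@dataclass
class AcceptRules:
    """Programmatic trace-quality rules replacing manual curation.

    A trajectory's steps enter the single-step pool only if

    * it shows at least ``min_steps`` detected steps,
    * every step is downward (an upward step beyond the detection resolution
      indicates blinking or a second molecule arriving),
    * the final plateau is at background, i.e. within
      ``final_level_sigma`` noise sds of zero (all fluorophores bleached).
    """

    min_steps: int = 1
    require_all_downward: bool = True
    final_level_sigma: float = 4.0
    final_level_abs: float = 1e-6

    def accept(self, fit: StepFit) -> bool:
        if fit.n_steps < self.min_steps:
            return False
        if self.require_all_downward and np.any(fit.step_heights <= 0):
            return False
        if np.isfinite(self.final_level_sigma):
            tol = max(self.final_level_sigma * fit.noise_sd,
                      self.final_level_abs)
            if abs(fit.levels[-1]) > tol:
                return False
        return True


def pool_single_steps(
    stepfits: Sequence[StepFit], rules: AcceptRules | None = None
) -> np.ndarray:
    """Pool downward step heights from trajectories passing quality rules."""
    if rules is None:
        rules = AcceptRules()
    pooled: list[float] = []
    for fit in stepfits:
        if rules.accept(fit):
            pooled.extend(fit.step_heights[fit.step_heights > 0])
    return np.asarray(pooled, dtype=float)


@dataclass
class SingleStepDistribution:
    """Gaussian fit of pooled single-photobleaching-step intensities.

    ``mean`` (``I_s-mean``) and ``sigma`` are the location and scale of the
    single-step component; ``weights`` gives the fitted mixture weights when
    coincident-bleach components were included (see
    :func:`fit_single_step_distribution`).
    """

    values: np.ndarray
    mean: float
    sigma: float
    n: int
    label: str = ""
    weights: tuple = (1.0,)
    lower_bound: float = 0.0


def _trunc_moments(mu: float, sig: float) -> tuple[float, float]:
    """Mean and sd of N(mu, sig^2) truncated below at 0."""
    if sig <= 0:
        return mu, 0.0
    a = -mu / sig
    mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig,
                                      moments="mv")
    return float(mean), float(np.sqrt(var))


def _weights_from_params(params: np.ndarray, n_comp: int) -> np.ndarray:
    """Monotone-decreasing mixture weights via cumulative-product ratios.

    ``w_m = w_{m-1} * sigmoid(gamma_m)`` enforces that coincident
    double/triple bleach events are rarer than single events, which is true
    by construction (an m-fold event needs m-1 independent near-coincident
    bleach times).
    """
    if n_comp == 1:
        return np.ones(1)
    gammas = special.expit(params)
    w = np.concatenate(([1.0], np.cumprod(gammas)))
    return w / w.sum()


def _step_mixture_nll(
    params: np.ndarray,
    x: np.ndarray,
    n_comp: int,
    lb: float,
    thresholds: np.ndarray,
    meas_sd: np.ndarray,
) -> float:
    """Negative log-likelihood of the censored truncated-Gaussian mixture.

    Component 1 is the single-step distribution N(mu, sig^2) truncated below
    at ``lb``; component m >= 2 approximates the m-fold coincident-bleach
    sum as a Gaussian with the truncated distribution's moments scaled by m.
    Observation i is further left-censored at its detection threshold
    ``thresholds[i]`` and blurred by measurement noise ``meas_sd[i]``.
    """
    mu = params[0]
    sig = np.exp(params[1])
    w = _weights_from_params(params[2:], n_comp)
    lo = np.maximum(thresholds, lb) if np.isfinite(lb) else thresholds
    ll_comp = np.empty((x.size, n_comp))
    mu_t, sig_t = _trunc_moments(mu, sig) if n_comp > 1 else (mu, sig)
    for m in range(1, n_comp + 1):
        if m == 1:
            loc = mu
            var = sig * sig + meas_sd * meas_sd
        else:
            loc = m * mu_t
            var = m * sig_t * sig_t + meas_sd * meas_sd
        sd = np.sqrt(var)
        z = (x - loc) / sd
        logpdf = -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi)
        lognorm = stats.norm.logsf(lo, loc=loc, scale=sd)
        ll_comp[:, m - 1] = logpdf - lognorm + np.log(w[m - 1])
    hi = ll_comp.max(axis=1)
    ll = hi + np.log(np.exp(ll_comp - hi[:, None]).sum(axis=1))
    return -float(ll.sum())


def censoring_info(
    stepfits: Sequence[StepFit], rules: AcceptRules | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool accepted step heights with per-step detection-limit metadata.

    The penalized segmentation accepts a change point only when it reduces
    the squared error by more than the penalty ``beta``; for a step with
    adjacent dwells ``d1, d2`` the reduction is ``w * h^2`` with
    ``w = d1*d2/(d1+d2)``, so steps below ``c = sqrt(beta/w)`` are
    undetectable and the observed pool is left-censored at a per-step
    threshold.  The measurement sd of a detected height is
    ``noise_sd * sqrt(1/d1 + 1/d2)``.  Returns ``(heights, thresholds,
    measurement_sds)`` for use by :func:`fit_single_step_distribution`.
    """
    if rules is None:
        rules = AcceptRules()
    heights, thresholds, meas = [], [], []
    for fit in stepfits:
        if not rules.accept(fit):
            continue
        d = fit.dwells.astype(float)
        for j, h in enumerate(fit.step_heights):
            if h <= 0:
                continue
            d1, d2 = d[j], d[j + 1]
            w = d1 * d2 / (d1 + d2)
            heights.append(float(h))
            thresholds.append(float(np.sqrt(fit.penalty_beta / w)))
            meas.append(float(fit.noise_sd * np.sqrt(1 / d1 + 1 / d2)))
    return (
        np.asarray(heights),
        np.asarray(thresholds),
        np.asarray(meas),
    )


def fit_single_step_distribution(
    values: Sequence[float],
    min_n: int = 50,
    lower_bound: float = 0.0,
    max_multimer: int = 1,
    thresholds: np.ndarray | None = None,
    meas_sd: np.ndarray | None = None,
    label: str = "",
) -> SingleStepDistribution:
    """Maximum-likelihood Gaussian fit of pooled step intensities.

    By default a single Gaussian, truncated below at ``lower_bound`` (0 a.u.:
    negative step intensities are unobservable), is fit to the pooled
    values; the truncation-aware ML recovers the underlying location
    ``I_s-mean`` even when the distribution has appreciable mass clipped at
    zero, and reduces to the plain sample mean/sd when truncation is
    negligible.

    Two optional refinements model how a change-point detector actually
    samples the step population:

    * ``thresholds``/``meas_sd`` (per observation, as computed by
      :func:`censoring_info`): steps below the detector's local
      detectability limit are never observed, so each observation is
      treated as left-censored at its own threshold — a completeness
      correction.
    * ``max_multimer > 1``: bleach events coincident within the dwell
      resolution are detected as one step of summed height; components
      ``m = 2..max_multimer`` (Gaussian approximations of the m-fold sum,
      with monotone-decreasing weights) absorb such events instead of
      letting them inflate the single-step mean.

    Raises ``ValueError`` when fewer than ``min_n`` values are supplied.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        raise ValueError(
            f"single-step pool has {x.size} values; at least {min_n} required"
        )
    if np.ptp(x) == 0.0:  # degenerate: all values identical
        return SingleStepDistribution(
            x, float(x[0]), 0.0, x.size, label, (1.0,), lower_bound
        )
    thresholds = (
        np.zeros(x.size) if thresholds is None
        else np.broadcast_to(np.asarray(thresholds, float), x.shape).copy()
    )
    meas_sd = (
        np.zeros(x.size) if meas_sd is None
        else np.broadcast_to(np.asarray(meas_sd, float), x.shape).copy()
    )
    mu0 = float(np.median(x))
    sig0 = float(stats.median_abs_deviation(x, scale="normal"))
    sig0 = max(sig0, 1e-6 * abs(mu0), 1e-12)
    p0 = np.concatenate(([mu0, np.log(sig0)], np.full(max_multimer - 1, -2.0)))
    res = optimize.minimize(
        _step_mixture_nll,
        p0,
        args=(x, max_multimer, lower_bound, thresholds, meas_sd),
        method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-8, "fatol": 1e-10},
    )
    mu = float(res.x[0])
    sig = float(np.exp(res.x[1]))
    w = _weights_from_params(res.x[2:], max_multimer)
    return SingleStepDistribution(
        x, mu, sig, x.size, label, tuple(float(v) for v in w), lower_bound
    )


def calibrate_single_step(
    trajectories: Sequence[Trajectory],
    rules: AcceptRules | None = None,
    min_n: int = 50,
    max_multimer: int = 2,
    label: str = "",
    min_dwell: int = 1,
    **detect_kwargs,
) -> SingleStepDistribution:
    """Full single-step calibration: detect -> pool -> fit ``I_s-mean``.

    Runs :func:`detect_steps` on every trajectory (at the finest dwell
    resolution, ``min_dwell=1`` by default, to minimize coincident-bleach
    merging), pools accepted downward steps with their detection-limit
    metadata, and fits the censoring-corrected truncated-Gaussian model
    with a coincident-bleach component.  The returned distribution's
    ``mean`` is the single-fluorophore intensity calibration for the
    channel; its ``weights`` report the fitted share of single versus
    coincident events.
    """
    fits = [detect_steps(t, min_dwell=min_dwell, **detect_kwargs)
            for t in trajectories]
    heights, thresholds, meas = censoring_info(fits, rules)
    return fit_single_step_distribution(
        heights,
        min_n=min_n,
        max_multimer=max_multimer,
        thresholds=thresholds,
        meas_sd=meas,
        label=label,
    )


@dataclass
class FPPResult:
    """Fluorescently labeled proteins per point for one focus.

    ``fpp = I_0 / I_s_mean``; ``subunit_count`` is FPP rounded half-up and
    clamped to a minimum of 1 (a detected focus implies at least one
    fluorophore).  Counts above ``max_subunits`` (20) are retained but
    flagged ``excluded``.
    """

    i0: float
    fpp: float
    subunit_count: int
    excluded: bool
    focus_id: object = None
    channel: str = ""


def compute_fpp(
    i0: float,
    dist: SingleStepDistribution,
    max_subunits: int = 20,
    focus_id: object = None,
    channel: str = "",
) -> FPPResult:
    """Convert an initial intensity into a subunit count via ``I_s-mean``."""
    if dist.mean <= 0:
        raise ValueError("I_s_mean must be positive to compute FPP")
    fpp = i0 / dist.mean
    count = max(1, int(np.floor(fpp + 0.5)))
    return FPPResult(
        i0=float(i0),
        fpp=float(fpp),
        subunit_count=count,
        excluded=count > max_subunits,
        focus_id=focus_id,
        channel=channel,
    )


@dataclass
class FretTrace:
    """Leakage-corrected proximity-ratio trace.

    ``efficiency`` is ``E = A' / (A' + D)`` with ``A' = A - alpha*D`` the
    donor-leakage-corrected acceptor signal, clipped to [0, 1]; frames where
    the total corrected signal is non-positive are marked invalid.  E is a
    proximity ratio, not a distance-calibrated FRET efficiency.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    alpha: float
    efficiency: np.ndarray = field(default=None)
    valid: np.ndarray = field(default=None)


def fret_trace(
    donor: Trajectory, acceptor: Trajectory, alpha: float = 0.0
) -> FretTrace:
    """Compute the proximity-ratio (FRET efficiency) trace.

    Parameters
    ----------
    donor, acceptor : Trajectory
        Donor- and acceptor-channel trajectories of equal length.
    alpha : float
        Fraction of donor signal leaking into the acceptor channel,
        ``0 <= alpha < 1``.
    """
    d = donor.intensities
    a = acceptor.intensities
    if d.size != a.size:
        raise ValueError(
            f"donor ({d.size} frames) and acceptor ({a.size} frames) "
            "trajectories must have equal length"
        )
    if not 0 <= alpha < 1:
        raise ValueError("leakage alpha must be in [0, 1)")
    a_corr = a - alpha * d
    total = a_corr + d
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, a_corr / np.where(valid, total, 1.0), np.nan)
    e = np.clip(e, 0.0, 1.0)
    return FretTrace(donor=d, acceptor=a, alpha=alpha, efficiency=e, valid=valid)
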