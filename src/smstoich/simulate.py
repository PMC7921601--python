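"""Synthetic single-molecule data with known ground truth.

Every stage of the stoichiometry pipeline can be validated by parameter
recovery against data generated here:

* :func:`simulate_trajectory` — step-wise photobleaching trajectories with
  per-fluorophore constant emission, geometric (frame-discretized
  exponential) bleach times, optional two-state blinking, and additive
  Gaussian noise.
* :func:`simulate_complex_population` — an exact event-driven (Gillespie)
  simulation of the two-step chaperone-client binding mechanism: small free
  chaperone species first capture binding-competent clients, then bound
  complexes accrete further chaperone subunits from a well-mixed, depletable
  free pool (and may lose them), so complex stoichiometries grow over time
  while the bound-client fraction rises toward its equilibrium plateau with
  one-phase association kinetics.
* :func:`render_two_color_movie` — two-channel image stacks with
  pixel-integrated Gaussian point-spread functions, electronic offset,
  flat-field gain and Gaussian read noise, writable as multi-page TIFF.
* :func:`thin_by_labeling` — binomial thinning for sub-stoichiometric
  fluorescent labeling.
* :func:`simulate_aggregation` — sigmoidal light-scatter (A340) aggregation
  curves with ratio-dependent chaperone suppression.

Default photophysics for the two channels reproduce the reported
single-step intensity distributions of the dye-labeled client (AF647,
170.5 +/- 99 a.u.) and chaperone (AF488, 166 +/- 119 a.u.).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .aggregation import AggregationCurve
from .imaging import ImageStack
from .steps import Trajectory
from .stoich import ComplexStoichiometry

__all__ = [
    "FluorophorePhotophysics",
    "BindingKineticsConfig",
    "CameraModel",
    "TrajectoryTruth",
    "PopulationSnapshot",
    "MovieGroundTruth",
    "client_photophysics",
    "chaperone_photophysics",
    "simulate_trajectory",
    "simulate_complex_population",
    "thin_by_labeling",
    "render_two_color_movie",
    "simulate_aggregation",
    "write_movie",
    "write_ground_truth",
    "write_population",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FluorophorePhotophysics:
    """Emission and bleaching parameters of one fluorophore species.

    Parameters
    ----------
    step_mu, step_sigma : float
        Mean and sd of the per-fluorophore emission intensity (a.u.); each
        fluorophore's intensity is drawn once from ``N(step_mu,
        step_sigma^2)`` truncated at 0 and held constant until bleaching.
    bleach_rate : float
        Per-frame bleaching rate (1/frame); bleach times are geometric with
        per-frame probability ``1 - exp(-bleach_rate)``.
    blink_on, blink_off : float
        Optional two-state blinking rates (1/frame): ``blink_off`` is the
        rate of leaving the emitting state, ``blink_on`` of re-entering it.
        Both default to 0 (blinking disabled, as under an oxygen-scavenger
        system).
    """

    step_mu: float
    step_sigma: float
    bleach_rate: float
    blink_on: float = 0.0
    blink_off: float = 0.0

    def __post_init__(self) -> None:
        if self.step_mu <= 0:
            raise ValueError("step_mu must be positive")
        if self.step_sigma < 0:
            raise ValueError("step_sigma must be non-negative")
        p = self.bleach_prob
        if not 0 < p < 1:
            raise ValueError("bleach_rate must give per-frame probability in (0, 1)")
        if self.blink_on < 0 or self.blink_off < 0:
            raise ValueError("blinking rates must be non-negative")

    @property
    def bleach_prob(self) -> float:
        """Per-frame bleaching probability."""
        return 1.0 - np.exp(-self.bleach_rate)


def client_photophysics(bleach_rate: float = 1 / 30) -> FluorophorePhotophysics:
    """Client-channel (AF647) defaults: single-step intensity 170.5 +/- 99 a.u."""
    return FluorophorePhotophysics(170.5, 99.0, bleach_rate)


def chaperone_photophysics(bleach_rate: float = 1 / 30) -> FluorophorePhotophysics:
    """Chaperone-channel (AF488) defaults: single-step intensity 166 +/- 119 a.u."""
    return FluorophorePhotophysics(166.0, 119.0, bleach_rate)


@dataclass
class TrajectoryTruth:
    """Ground truth for one simulated trajectory."""

    n_fluors: int
    intensities: np.ndarray  # per-fluorophore emission levels
    bleach_frames: np.ndarray  # first dark frame of each fluorophore


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, size: int
) -> np.ndarray:
    """Draw N(mu, sigma^2) truncated below at 0 by rejection."""
    if sigma == 0:
        return np.full(size, mu)
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mu, sigma, need.size)
        ok = draw > 0
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def simulate_trajectory(
    n_fluors: int,
    photophysics: FluorophorePhotophysics,
    n_frames: int,
    noise_sd: float = 0.0,
    seed=None,
    frame_interval: float = 0.2,
    focus_id=None,
    channel: str = "",
) -> tuple[Trajectory, TrajectoryTruth]:
    """Simulate one photobleaching trajectory.

    Each of ``n_fluors`` fluorophores draws a constant emission level from
    the truncated normal of ``photophysics`` and a geometric bleach frame
    (support 1, 2, ...; the fluorophore emits on frames ``t < bleach``).
    The trace is the sum of active emissions plus additive Gaussian noise.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_fluors < 0:
        raise ValueError("n_fluors must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    levels = _truncated_normal(rng, photophysics.step_mu,
                               photophysics.step_sigma, n_fluors)
    bleach = rng.geometric(photophysics.bleach_prob, n_fluors) if n_fluors else (
        np.empty(0, dtype=int))
    frames = np.arange(n_frames)
    active = frames[None, :] < bleach[:, None] if n_fluors else np.zeros(
        (0, n_frames), dtype=bool)
    if photophysics.blink_off > 0:
        active = active & _blink_mask(rng, photophysics, n_fluors, n_frames)
    trace = (levels[:, None] * active).sum(axis=0) if n_fluors else np.zeros(n_frames)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n_frames)
    traj = Trajectory(trace, frame_interval=frame_interval,
                      focus_id=focus_id, channel=channel)
    return traj, TrajectoryTruth(n_fluors, levels, bleach)


def _blink_mask(
    rng: np.random.Generator,
    pp: FluorophorePhotophysics,
    n_fluors: int,
    n_frames: int,
) -> np.ndarray:
    """Two-state on/off Markov-chain emission mask (on at frame 0)."""
    p_off = 1.0 - np.exp(-pp.blink_off)
    p_on = 1.0 - np.exp(-pp.blink_on) if pp.blink_on > 0 else 0.0
    mask = np.ones((n_fluors, n_frames), dtype=bool)
    state = np.ones(n_fluors, dtype=bool)
    for t in range(1, n_frames):
        u = rng.random(n_fluors)
        state = np.where(state, u >= p_off, u < p_on)
        mask[:, t] = state
    return mask


def thin_by_labeling(true_count: int, p_label: float, seed=None) -> int:
    """Binomial thinning for sub-stoichiometric labeling efficiency."""
    if not 0 <= p_label <= 1:
        raise ValueError("p_label must be in [0, 1]")
    if true_count < 0:
        raise ValueError("true_count must be >= 0")
    return int(_rng(seed).binomial(true_count, p_label))


# ---------------------------------------------------------------------------
# Two-step binding-mechanism population simulation
# ---------------------------------------------------------------------------


@dataclass
class BindingKineticsConfig:
    """Parameters of the two-step chaperone-client binding mechanism.

    Step 1 (capture): small free chaperone species — sizes drawn from
    ``shsp_seed_dist`` (mass on 1-3mers) — stably bind free, misfolded,
    binding-competent clients at rate ``k_bind`` per client.  Step 2
    (accretion): bound complexes gain chaperone subunits at rate
    ``k_accrete`` scaled by the remaining free-subunit fraction, and lose
    them at ``k_off``.  ``plateau_bound_fraction`` is the equilibrium
    fraction of clients in complex: each client is binding-competent with
    this probability, so the expected bound fraction follows
    ``plateau * (1 - exp(-k_bind * t))`` — the one-phase association form.

    Rates are per hour.  ``molar_ratio`` sets the size of the free chaperone
    subunit pool relative to the number of clients (2:1 in the kinetics
    experiments the defaults emulate).
    """

    client_oligomer_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    shsp_seed_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    k_bind: float = 1.0
    k_accrete: float = 0.3
    k_off: float = 0.05
    molar_ratio: float = 2.0
    plateau_bound_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_accrete", "k_off", "molar_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.plateau_bound_fraction <= 1:
            raise ValueError("plateau_bound_fraction must be in [0, 1]")
        for dist_name in ("client_oligomer_dist", "shsp_seed_dist"):
            d = dict(getattr(self, dist_name))
            total = sum(d.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{dist_name} probabilities must sum to 1")
            if any(k < 1 for k in d):
                raise ValueError(f"{dist_name} sizes must be >= 1")
            setattr(self, dist_name, d)


@dataclass
class PopulationSnapshot:
    """State of the simulated population at one timepoint."""

    time: float
    complexes: list  # list[ComplexStoichiometry]
    free_client_sizes: np.ndarray
    free_shsp_subunits: int

    @property
    def n_clients(self) -> int:
        return len(self.complexes) + self.free_client_sizes.size

    @property
    def bound_fraction(self) -> float:
        return len(self.complexes) / self.n_clients


def _sample_dist(rng, dist: Mapping[int, float], size: int) -> np.ndarray:
    sizes = np.array(sorted(dist))
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=size, p=probs)


def simulate_complex_population(
    cfg: BindingKineticsConfig,
    timepoints: Sequence[float],
    n_clients: int = 500,
    seed=None,
) -> list[PopulationSnapshot]:
    """Exact stochastic simulation of the two-step binding mechanism.

    Event-driven (Gillespie) continuous-time simulation with three event
    types — capture, accretion, dissociation — over a well-mixed, depletable
    free chaperone subunit pool of initial size
    ``round(molar_ratio * n_clients)``.  Snapshots of the population are
    recorded at each requested timepoint (hours, sorted, non-negative).
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("at least one timepoint required")
    if any(t < 0 for t in timepoints):
        raise ValueError("timepoints must be non-negative")
    if sorted(timepoints) != timepoints:
        raise ValueError("timepoints must be sorted ascending")
    rng = _rng(seed)

    client_sizes = _sample_dist(rng, cfg.client_oligomer_dist, n_clients)
    bindable = rng.random(n_clients) < cfg.plateau_bound_fraction
    free = list(zip(client_sizes.tolist(), bindable.tolist()))
    pool0 = max(int(round(cfg.molar_ratio * n_clients)), 1)
    pool = pool0
    complexes: list[list[int]] = []  # [n_client, n_chaperone]

    def snapshot(t: float) -> PopulationSnapshot:
        recs = [
            ComplexStoichiometry(n_client=c, n_chaperone=s, condition=t)
            for c, s in complexes
        ]
        return PopulationSnapshot(
            time=t,
            complexes=recs,
            free_client_sizes=np.array([s for s, _ in free], dtype=int),
            free_shsp_subunits=pool,
        )

    out: list[PopulationSnapshot] = []
    t = 0.0
    tp_iter = iter(timepoints)
    next_tp = next(tp_iter)
    done = False
    while not done:
        n_free_bindable = sum(1 for _, b in free if b)
        r_bind = cfg.k_bind * n_free_bindable if pool >= 1 else 0.0
        r_acc = cfg.k_accrete * (pool / pool0) * len(complexes)
        n_losable = sum(1 for _, s in complexes if s > 1)
        r_off = cfg.k_off * n_losable
        total = r_bind + r_acc + r_off
        t_next = t + rng.exponential(1.0 / total) if total > 0 else np.inf
        while next_tp is not None and next_tp < t_next:
            out.append(snapshot(next_tp))
            next_tp = next(tp_iter, None)
        if next_tp is None:
            done = True
            break
        t = t_next
        u = rng.random() * total
        if u < r_bind:
            candidates = [i for i, (_, b) in enumerate(free) if b]
            idx = candidates[rng.integers(len(candidates))]
            size, _ = free.pop(idx)
            s = int(_sample_dist(rng, cfg.shsp_seed_dist, 1)[0])
            s = min(s, pool)
            pool -= s
            complexes.append([int(size), s])
        elif u < r_bind + r_acc:
            c = complexes[rng.integers(len(complexes))]
            c[1] += 1
            pool -= 1
        else:
            candidates = [c for c in complexes if c[1] > 1]
            c = candidates[rng.integers(len(candidates))]
            c[1] -= 1
            pool += 1
    return out


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """EMCCD-like camera: offset, flat-field gain and Gaussian read noise.

    A pixel records ``offset + flatfield * signal + N(0, read_noise_sd^2)``,
    so ``(I - offset) / flatfield`` inverts the model exactly in the
    noise-free case.
    """

    offset: float = 100.0
    read_noise_sd: float = 10.0
    psf_sigma: float = 1.2
    shape: tuple[int, int] = (128, 128)
    flatfield: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.flatfield is None:
            self.flatfield = np.ones(self.shape)
        else:
            self.flatfield = np.asarray(self.flatfield, dtype=float)
            if self.flatfield.shape != tuple(self.shape):
                raise ValueError("flatfield shape must match image shape")
            if np.any(self.flatfield <= 0):
                raise ValueError("flatfield must be strictly positive")


@dataclass
class MovieGroundTruth:
    """Ground truth for a rendered two-channel movie."""

    positions: np.ndarray  # (n, 2) 0-based (row, col), pixel centers at ints
    stoichiometries: list  # true ComplexStoichiometry per focus
    labeled_counts: dict  # channel -> (n,) labeled fluorophore counts
    truths: dict  # channel -> list[TrajectoryTruth]
    trajectories: dict  # channel -> list[Trajectory] (noise-free signal)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (r, c) in enumerate(self.positions):
            for ch in self.labeled_counts:
                rows.append(
                    {
                        "focus": i,
                        "channel": ch,
                        "row": r,
                        "col": c,
                        "labeled_count": int(self.labeled_counts[ch][i]),
                        "bleach_frames": ";".join(
                            str(b) for b in self.truths[ch][i].bleach_frames
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _psf_weights(
    pos: tuple[float, float], sigma: float, shape: tuple[int, int], half: int
) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated 2-D Gaussian weights on a local patch.

    Each pixel weight is the product of error-function differences over the
    pixel's unit square, so the weights sum to ~1 up to truncation at the
    patch edge.
    """
    r0, c0 = pos
    rc, cc = int(round(r0)), int(round(c0))
    rlo, rhi = max(rc - half, 0), min(rc + half + 1, shape[0])
    clo, chi = max(cc - half, 0), min(cc + half + 1, shape[1])
    rows = np.arange(rlo, rhi)
    cols = np.arange(clo, chi)
    s = sigma * np.sqrt(2.0)
    wr = 0.5 * (
        special.erf((rows + 0.5 - r0) / s) - special.erf((rows - 0.5 - r0) / s)
    )
    wc = 0.5 * (
        special.erf((cols + 0.5 - c0) / s) - special.erf((cols - 0.5 - c0) / s)
    )
    return slice(rlo, rhi), slice(clo, chi), np.outer(wr, wc)


def sample_positions(
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    rng,
    margin: float = 8.0,
    max_tries: int = 100_000,
) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (rejection)."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries > max_tries:
            raise RuntimeError(
                "could not place foci with the requested separation; "
                "reduce n or min_separation"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - p) ** 2 + (c - q) ** 2 >= min_separation**2 for p, q in pts):
            pts.append((r, c))
    return np.array(pts)


def render_two_color_movie(
    complexes: Sequence[ComplexStoichiometry],
    photophysics_a: FluorophorePhotophysics,
    photophysics_b: FluorophorePhotophysics,
    camera: CameraModel,
    n_frames: int,
    seed=None,
    positions: np.ndarray | None = None,
    p_label_a: float = 1.0,
    p_label_b: float = 1.0,
    min_separation: float | None = None,
    allow_overlap: bool = False,
    frame_interval: float = 0.2,
) -> tuple[ImageStack, ImageStack, MovieGroundTruth]:
    """Render a population of complexes as a two-channel movie.

    Channel A carries the client subunits (``n_client`` fluorophores after
    binomial labeling thinning), channel B the chaperone subunits.  Each
    focus is a pixel-integrated Gaussian PSF scaled by its instantaneous
    photobleaching-trajectory value; the camera model then applies offset,
    flat-field gain and read noise independently per channel and frame.
    Complexes with ``n_chaperone == 0`` (free clients) render in channel A
    only.

    Positions default to uniform sampling with minimum separation
    ``4 * psf_sigma`` (``allow_overlap=True`` disables the separation
    constraint).
    """
    rng = _rng(seed)
    complexes = list(complexes)
    n = len(complexes)
    shape = tuple(camera.shape)
    if positions is None:
        if min_separation is None:
            min_separation = 0.0 if allow_overlap else 4.0 * camera.psf_sigma
        positions = sample_positions(n, shape, min_separation, rng)
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n, 2):
            raise ValueError("positions must have shape (n_complexes, 2)")
        if (
            np.any(positions < 0)
            or np.any(positions[:, 0] > shape[0] - 1)
            or np.any(positions[:, 1] > shape[1] - 1)
        ):
            raise ValueError("positions must lie inside the pixel grid")

    half = int(np.ceil(4 * camera.psf_sigma)) + 1
    stacks = {}
    labeled = {}
    truths: dict[str, list[TrajectoryTruth]] = {}
    trajs: dict[str, list[Trajectory]] = {}
    for ch, pp, p_label, attr in (
        ("A", photophysics_a, p_label_a, "n_client"),
        ("B", photophysics_b, p_label_b, "n_chaperone"),
    ):
        signal = np.zeros((n_frames,) + shape)
        counts = np.empty(n, dtype=int)
        ch_truths = []
        ch_trajs = []
        for i, cplx in enumerate(complexes):
            k = thin_by_labeling(getattr(cplx, attr), p_label, rng)
            counts[i] = k
            traj, truth = simulate_trajectory(
                k, pp, n_frames, noise_sd=0.0, seed=rng,
                frame_interval=frame_interval, focus_id=i, channel=ch,
            )
            ch_truths.append(truth)
            ch_trajs.append(traj)
            if k == 0:
                continue
            rs, cs, w = _psf_weights(tuple(positions[i]), camera.psf_sigma,
                                     shape, half)
            signal[:, rs, cs] += traj.intensities[:, None, None] * w
        frames = camera.offset + camera.flatfield * signal
        if camera.read_noise_sd > 0:
            frames = frames + rng.normal(0.0, camera.read_noise_sd, frames.shape)
        stacks[ch] = ImageStack(frames, frame_interval=frame_interval, channel=ch)
        labeled[ch] = counts
        truths[ch] = ch_truths
        trajs[ch] = ch_trajs
    gt = MovieGroundTruth(
        positions=positions,
        stoichiometries=complexes,
        labeled_counts=labeled,
        truths=truths,
        trajectories=trajs,
    )
    return stacks["A"], stacks["B"], gt


# ---------------------------------------------------------------------------
# Bulk aggregation curves
# ---------------------------------------------------------------------------


def simulate_aggregation(
    client_conc: float = 30.0,
    chaperone_ratio: float = 0.5,
    growth_rate: float = 1.0,
    suppression: Callable[[float], float] | float = 0.5,
    n_timepoints: int = 120,
    t_total: float = 20.0,
    noise_sd: float = 0.0,
    seed=None,
) -> tuple[AggregationCurve, AggregationCurve]:
    """Simulate a light-scatter (A340) aggregation assay curve pair.

    The control curve is a monotone sigmoid (logistic with a lag phase,
    time constant ``1/growth_rate`` hours, amplitude proportional to client
    concentration).  The chaperone curve shares the time course with its
    amplitude — the extent of aggregation — scaled by ``1 - s``, where the
    suppression ``s`` in [0, 1] is either given directly or computed from
    ``suppression(chaperone_ratio)``.  On noise-free output the endpoint
    percent-inhibition statistic then equals ``100 * s`` exactly.
    """
    if client_conc <= 0 or growth_rate <= 0:
        raise ValueError("client_conc and growth_rate must be positive")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    s = suppression(chaperone_ratio) if callable(suppression) else float(suppression)
    if not 0 <= s <= 1:
        raise ValueError("suppression must be in [0, 1]")
    rng = _rng(seed)
    t = np.linspace(0.0, t_total, n_timepoints)
    tau = 1.0 / growth_rate
    t0 = 3.0 * tau
    f = 1.0 / (1.0 + np.exp(-(t - t0) / tau))
    f0 = 1.0 / (1.0 + np.exp(t0 / tau))
    shape = (f - f0) / (1.0 - f0)
    amplitude = client_conc / 30.0  # a.u.; 30 uM client gives ~1 a.u. rise
    control = amplitude * shape
    treated = (1.0 - s) * amplitude * shape
    if noise_sd > 0:
        control = control + rng.normal(0, noise_sd, t.size)
        treated = treated + rng.normal(0, noise_sd, t.size)
    return (
        AggregationCurve(t, control, condition="control"),
        AggregationCurve(t, treated, condition=f"ratio {chaperone_ratio}:1"),
    )


# ---------------------------------------------------------------------------
# Writers (text-friendly TIFF/CSV/JSON)
# ---------------------------------------------------------------------------


def write_movie(stack: ImageStack, path) -> None:
    """Write an image stack as 16-bit multi-page TIFF."""
    import tifffile

    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def write_ground_truth(gt: MovieGroundTruth, path) -> None:
    """Write per-focus ground truth (position, counts, bleach frames) as CSV."""
    gt.to_frame().to_csv(path, index=False)


def write_population(snapshots: Sequence[PopulationSnapshot], path) -> None:
    """Write population stoichiometries per timepoint as JSON."""
    payload = [
        {
            "time": snap.time,
            "bound_fraction": snap.bound_fraction,
            "free_shsp_subunits": int(snap.free_shsp_subunits),
            "free_client_sizes": snap.free_client_sizes.tolist(),
            "complexes": [
                {"n_client": r.n_client, "n_chaperone": r.n_chaperone}
                for r in snap.complexes
            ],
        }
        for snap in snapshots
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
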