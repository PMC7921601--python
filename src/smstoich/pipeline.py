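"""End-to-end analysis: two-channel movie -> complex stoichiometries.

Chains the pipeline stages with their standard settings: camera
correction, focus detection on the clipped stack, trajectory extraction
from the unclipped stack, single-step calibration per channel, FPP subunit
counting, colocalization and stoichiometry pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import (
    ColocalizedPair,
    Focus,
    ImageStack,
    colocalize,
    correct_stack,
    detect_foci,
    extract_trajectory,
)
from .steps import (
    FPPResult,
    SingleStepDistribution,
    Trajectory,
    calibrate_single_step,
    compute_fpp,
    initial_intensity,
)
from .stoich import ComplexStoichiometry, pair_stoichiometries

__all__ = ["ChannelAnalysis", "MovieAnalysis", "analyze_channel",
           "analyze_two_color_movie"]


@dataclass
class ChannelAnalysis:
    """Per-channel results: foci, trajectories, calibration and counts."""

    foci: list[Focus]
    trajectories: list[Trajectory]
    distribution: SingleStepDistribution
    fpp: dict  # focus_id -> FPPResult


@dataclass
class MovieAnalysis:
    """Two-channel results with colocalized pairs and stoichiometries."""

    channel_a: ChannelAnalysis
    channel_b: ChannelAnalysis
    pairs: list[ColocalizedPair]
    colocalized_fraction: float
    records: list[ComplexStoichiometry]


def analyze_channel(
    stack: ImageStack,
    offset: float,
    flatfield: np.ndarray | None = None,
    detect_window: int = 10,
    threshold_k: float = 5.0,
    min_separation: int = 3,
    aperture_radius: float = 3.0,
    bg_annulus: tuple[float, float] = (5.0, 7.0),
    min_calibration_steps: int = 50,
    require_full_bleaching: bool = False,
) -> ChannelAnalysis:
    """Detect foci, extract trajectories, calibrate I_s and count subunits.

    By default the single-step calibration pools steps from all traces with
    exclusively downward steps, whether or not the trace has fully bleached
    by the end of the movie: each detected downward step is a valid
    single-bleach event, and requiring full bleaching would discard most
    multi-fluorophore traces when the movie ends before every fluorophore
    has bleached.  Set ``require_full_bleaching=True`` to restore the
    stricter final-plateau-at-background rule.
    """
    from .steps import AcceptRules

    clipped = correct_stack(stack, offset, flatfield, clip=True)
    linear = correct_stack(stack, offset, flatfield, clip=False)
    foci = detect_foci(clipped, detect_window, threshold_k, min_separation)
    trajs = [
        extract_trajectory(linear, f, aperture_radius, bg_annulus) for f in foci
    ]
    rules = (
        AcceptRules()
        if require_full_bleaching
        else AcceptRules(final_level_sigma=np.inf)
    )
    dist = calibrate_single_step(
        trajs, rules=rules, min_n=min_calibration_steps, label=stack.channel
    )
    fpp = {
        f.focus_id: compute_fpp(
            initial_intensity(t), dist, focus_id=f.focus_id, channel=f.channel
        )
        for f, t in zip(foci, trajs)
    }
    return ChannelAnalysis(foci, trajs, dist, fpp)


def analyze_two_color_movie(
    stack_a: ImageStack,
    stack_b: ImageStack,
    offset: float,
    flatfield: np.ndarray | None = None,
    radius: float = 2.0,
    condition=None,
    **channel_kwargs,
) -> MovieAnalysis:
    """Full two-color analysis to paired complex stoichiometries.

    Channel A is the client channel, channel B the chaperone channel; the
    colocalized fraction reported is the fraction of A foci with a B focus
    within ``radius`` pixels.
    """
    ca = analyze_channel(stack_a, offset, flatfield, **channel_kwargs)
    cb = analyze_channel(stack_b, offset, flatfield, **channel_kwargs)
    pairs, fraction = colocalize(ca.foci, cb.foci, radius)
    records = pair_stoichiometries(pairs, ca.fpp, cb.fpp, condition=condition)
    return MovieAnalysis(ca, cb, pairs, fraction, records)
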