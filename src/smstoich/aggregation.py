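"""Bulk light-scatter aggregation-assay analysis.

Chaperone activity in vitro is quantified by incubating the client protein
with and without chaperone and following aggregation as light scatter
(absorbance at 340 nm) over time.  The summary statistic is

    % inhibition = ((dIc - dIs) / dIc) * 100

where ``dIc`` and ``dIs`` are the endpoint changes in absorbance in the
absence (control) and presence of chaperone, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AggregationCurve",
    "InhibitionResult",
    "curve_delta",
    "percent_inhibition",
    "inhibition_by_ratio",
    "read_plate_csv",
]


@dataclass
class AggregationCurve:
    """One light-scatter time course.

    ``times`` in hours (strictly increasing); ``intensities`` is the A340
    light-scatter signal (a.u.); ``condition`` labels the molar ratio or
    control status.
    """

    times: np.ndarray
    intensities: np.ndarray
    condition: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities must have equal length")
        if self.times.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class InhibitionResult:
    """Percent inhibition with the endpoint deltas it derives from."""

    delta_ic: float
    delta_is: float
    percent: float


def curve_delta(curve: AggregationCurve, endpoint_window: int = 1) -> float:
    """Endpoint change in absorbance, dI = end minus start.

    With ``endpoint_window > 1`` the first/last ``endpoint_window`` values
    are averaged, which reduces variance on noisy plate-reader curves;
    ``endpoint_window=1`` reproduces the single-endpoint difference.
    """
    if endpoint_window < 1:
        raise ValueError("endpoint_window must be >= 1")
    y = curve.intensities
    if endpoint_window > y.size:
        raise ValueError("endpoint_window exceeds curve length")
    return float(y[-endpoint_window:].mean() - y[:endpoint_window].mean())


def percent_inhibition(delta_ic: float, delta_is: float) -> InhibitionResult:
    """Percent inhibition from control/chaperone endpoint deltas.

    Negative values (aggregation enhancement) are reported, not clipped.
    A non-positive control delta means the control did not aggregate and
    the statistic is undefined.
    """
    if delta_ic <= 0:
        raise ValueError(
            "control delta must be positive (control did not aggregate)"
        )
    pct = 100.0 * (delta_ic - delta_is) / delta_ic
    return InhibitionResult(
        delta_ic=float(delta_ic), delta_is=float(delta_is), percent=float(pct)
    )


def inhibition_by_ratio(
    control_curves: Sequence[AggregationCurve],
    treated_by_ratio: Mapping[object, Sequence[AggregationCurve]],
    endpoint_window: int = 1,
) -> pd.DataFrame:
    """Percent inhibition (mean +/- sd over replicates) per molar ratio.

    Control replicates are paired with treated replicates by index; with a
    single control its delta is reused for every replicate.  The returned
    frame is sorted by ratio and carries a ``monotone`` flag indicating
    whether mean inhibition is non-decreasing with ratio.
    """
    if not control_curves:
        raise ValueError("at least one control curve required")
    control_deltas = [curve_delta(c, endpoint_window) for c in control_curves]
    rows = []
    for ratio, curves in treated_by_ratio.items():
        if not curves:
            raise ValueError(f"no replicates for ratio {ratio!r}")
        pcts = []
        for i, c in enumerate(curves):
            dic = control_deltas[i % len(control_deltas)]
            pcts.append(percent_inhibition(dic, curve_delta(c, endpoint_window)).percent)
        pcts = np.asarray(pcts)
        rows.append(
            {
                "ratio": ratio,
                "mean_percent_inhibition": pcts.mean(),
                "sd_percent_inhibition": pcts.std(ddof=1) if pcts.size > 1 else 0.0,
                "n": pcts.size,
            }
        )
    df = pd.DataFrame(rows).sort_values("ratio").reset_index(drop=True)
    df["monotone"] = bool(
        np.all(np.diff(df["mean_percent_inhibition"].to_numpy()) >= 0)
    )
    return df


def read_plate_csv(path) -> dict:
    """Read long-format plate-reader CSV (time, well, condition, A340).

    Returns ``{condition: [AggregationCurve per well]}``.
    """
    df = pd.read_csv(path)
    required = {"time", "well", "condition", "A340"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)}")
    out: dict = {}
    for (cond, _well), sub in df.groupby(["condition", "well"], sort=False):
        sub = sub.sort_values("time")
        out.setdefault(cond, []).append(
            AggregationCurve(sub["time"].to_numpy(), sub["A340"].to_numpy(), cond)
        )
    return out
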