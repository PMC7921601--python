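"""Complex stoichiometries and their summaries.

Pairs per-channel subunit counts of colocalized foci into
client/chaperone complex stoichiometries and reproduces the standard
summaries of such data: relative-abundance heatmaps over the
(client, chaperone) subunit grid, one-phase association fits of
colocalization kinetics, rank-based multi-group comparisons
(Kruskal-Wallis with Dunn's post hoc procedure), and violin-style
size-distribution summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .steps import FPPResult

__all__ = [
    "ComplexStoichiometry",
    "AbundanceHeatmap",
    "OnePhaseFit",
    "SizeDistributionComparison",
    "pair_stoichiometries",
    "abundance_heatmap",
    "one_phase_association",
    "colocalized_fraction_kinetics",
    "compare_size_distributions",
    "size_violin_summary",
]

MAX_SUBUNITS = 20


@dataclass
class ComplexStoichiometry:
    """Paired subunit counts for one colocalized focus.

    ``n_chaperone = 0`` denotes a free client (no colocalized chaperone
    focus).  Records whose count exceeds 20 in either channel carry
    ``excluded=True``; they are retained and reported as a fraction, never
    silently dropped.
    """

    n_client: int
    n_chaperone: int
    condition: object = None
    excluded: bool = False


def pair_stoichiometries(
    pairs: Sequence,
    fpp_client: Mapping[object, FPPResult],
    fpp_chaperone: Mapping[object, FPPResult],
    condition: object = None,
) -> list[ComplexStoichiometry]:
    """Pair colocalized foci into complex stoichiometries.

    Parameters
    ----------
    pairs : sequence
        Colocalized pairs; each must expose ``focus_a``/``focus_b`` (as from
        :func:`smstoich.imaging.colocalize`) or be a ``(id_a, id_b)`` tuple.
    fpp_client, fpp_chaperone : mapping
        Focus id -> :class:`~smstoich.steps.FPPResult` for the client (A)
        and chaperone (B) channel respectively.

    Raises
    ------
    ValueError
        If any paired focus lacks an FPP result, listing the focus ids.
    """
    records = []
    missing = []
    for p in pairs:
        if hasattr(p, "focus_a"):
            id_a = p.focus_a.focus_id
            id_b = p.focus_b.focus_id
        else:
            id_a, id_b = p
        if id_a not in fpp_client:
            missing.append(("client", id_a))
            continue
        if id_b not in fpp_chaperone:
            missing.append(("chaperone", id_b))
            continue
        ra = fpp_client[id_a]
        rb = fpp_chaperone[id_b]
        records.append(
            ComplexStoichiometry(
                n_client=ra.subunit_count,
                n_chaperone=rb.subunit_count,
                condition=condition,
                excluded=ra.excluded or rb.excluded,
            )
        )
    if missing:
        raise ValueError(
            "missing FPP results for paired foci: "
            + ", ".join(f"{ch}:{fid}" for ch, fid in missing)
        )
    return records


@dataclass
class AbundanceHeatmap:
    """Relative abundance of complexes over the subunit grid.

    ``matrix[i, j]`` is the fraction of included complexes with ``i + 1``
    client and ``j + 1`` chaperone subunits; included entries sum to 1.
    ``excluded_fraction`` reports the share of records flagged excluded
    (> 20 subunits in either channel).
    """

    matrix: np.ndarray
    condition: object = None
    n: int = 0
    excluded_fraction: float = 0.0

    @property
    def client_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def chaperone_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        counts = np.arange(1, self.matrix.shape[0] + 1)
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(counts, name="n_client"),
            columns=pd.Index(counts, name="n_chaperone"),
        )


def abundance_heatmap(
    records: Sequence[ComplexStoichiometry],
    condition: object = None,
    max_count: int = MAX_SUBUNITS,
) -> AbundanceHeatmap:
    """Normalized joint (client, chaperone) histogram over complexes.

    Only non-excluded records with at least one chaperone subunit (true
    complexes) enter the histogram; free clients and excluded records are
    counted toward ``n``/``excluded_fraction`` bookkeeping only.
    """
    records = list(records)
    included = [
        r
        for r in records
        if not r.excluded and r.n_chaperone >= 1 and 1 <= r.n_client <= max_count
        and r.n_chaperone <= max_count
    ]
    if not included:
        raise ValueError("no included (non-excluded) complex records")
    mat = np.zeros((max_count, max_count))
    for r in included:
        mat[r.n_client - 1, r.n_chaperone - 1] += 1
    mat /= mat.sum()
    n_excl = sum(r.excluded for r in records)
    return AbundanceHeatmap(
        matrix=mat,
        condition=condition,
        n=len(included),
        excluded_fraction=n_excl / len(records),
    )


@dataclass
class OnePhaseFit:
    """One-phase association fit ``y(t) = y0 + (plateau - y0)(1 - e^(-k t))``."""

    y0: float
    plateau: float
    k: float
    residual_sd: float


def one_phase_association(
    t: np.ndarray, y0: float, plateau: float, k: float
) -> np.ndarray:
    """The one-phase association model."""
    t = np.asarray(t, dtype=float)
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def colocalized_fraction_kinetics(
    timepoints: Sequence[float], fractions: Sequence[float]
) -> OnePhaseFit:
    """Fit the one-phase association model to colocalization kinetics.

    Used for the colocalized-client fraction versus incubation time; the
    fitted ``plateau`` is the equilibrium bound-client fraction.  The fit is
    invariant to the ordering of the timepoints.  Degenerate flat data
    yields ``plateau = y0`` and ``k = 0`` with a warning.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size != y.size:
        raise ValueError("timepoints and fractions must have equal length")
    if t.size < 3:
        raise ValueError("at least 3 timepoints required")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.ptp(y) == 0.0:
        warnings.warn("flat kinetics data; reporting k = 0", stacklevel=2)
        return OnePhaseFit(y0=float(y[0]), plateau=float(y[0]), k=0.0,
                           residual_sd=0.0)
    span = max(t.max() - t.min(), 1e-12)
    p0 = (float(y[0]), float(y[-1]), 2.0 / span)
    popt, _ = optimize.curve_fit(
        one_phase_association,
        t,
        y,
        p0=p0,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - one_phase_association(t, *popt)
    dof = max(t.size - 3, 1)
    return OnePhaseFit(
        y0=float(popt[0]),
        plateau=float(popt[1]),
        k=float(popt[2]),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


@dataclass
class SizeDistributionComparison:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc z-tests."""

    groups: tuple
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame = field(repr=False)


def _dunn_pairwise(
    samples: Sequence[np.ndarray], labels: Sequence, adjust: str
) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term: sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    mean_ranks = []
    sizes = []
    start = 0
    for s in samples:
        stop = start + len(s)
        mean_ranks.append(ranks[start:stop].mean())
        sizes.append(len(s))
        start = stop
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
            1.0 / sizes[i] + 1.0 / sizes[j]
        )
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, p))
    df = pd.DataFrame(rows, columns=["group_1", "group_2", "z", "p"])
    m = len(df)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def compare_size_distributions(
    groups: Mapping[object, Sequence[float]],
    adjust: str = "bonferroni",
) -> SizeDistributionComparison:
    """Rank-based comparison of subunit-count distributions across groups.

    Kruskal-Wallis H test (tie-corrected) as the omnibus test, followed by
    Dunn's pairwise z-tests on the pooled ranks with multiplicity adjustment
    (Bonferroni by default, the common convention for Dunn's procedure).
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2:
        raise ValueError("at least 2 groups required")
    for lab, s in zip(labels, samples):
        if s.size < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        # all observations identical: no evidence of any difference
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(samples, labels, adjust)
    return SizeDistributionComparison(
        groups=tuple(labels), statistic=float(stat), pvalue=float(p),
        pairwise=pairwise,
    )


def _reflected_kde(
    x: np.ndarray, grid: np.ndarray, lower: float = 1.0
) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) with reflection at ``lower``.

    Subunit counts are bounded below (a detected focus has >= 1 subunit);
    reflecting the kernel mass that would fall below the bound keeps the
    density supported on [lower, inf) and integrating to 1.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        # degenerate sample: narrow Gaussian spike at the common value
        bw = 0.25
        dens = stats.norm.pdf(grid, loc=x[0], scale=bw) + stats.norm.pdf(
            2 * lower - grid, loc=x[0], scale=bw
        )
    else:
        kde = stats.gaussian_kde(x, bw_method="silverman")
        dens = kde(grid) + kde(2 * lower - grid)
    dens = np.where(grid >= lower, dens, 0.0)
    return dens


def size_violin_summary(
    records: Sequence[ComplexStoichiometry],
    selector: str = "bound",
    channel: str = "client",
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-condition median, IQR and kernel density of subunit counts.

    Parameters
    ----------
    records : sequence of ComplexStoichiometry
        Excluded records are dropped.
    selector : {"bound", "free", "all"}
        ``bound`` keeps complexes (>= 1 chaperone subunit), ``free`` keeps
        free clients (0 chaperone subunits).
    channel : {"client", "chaperone"}
        Which subunit count to summarize.

    Returns
    -------
    DataFrame indexed by condition with columns ``n``, ``median``, ``q1``,
    ``q3`` and object columns ``density_x`` / ``density_y`` sampling the
    reflected-boundary kernel density.
    """
    if selector not in ("bound", "free", "all"):
        raise ValueError("selector must be 'bound', 'free' or 'all'")
    if channel not in ("client", "chaperone"):
        raise ValueError("channel must be 'client' or 'chaperone'")
    kept = [r for r in records if not r.excluded]
    if selector == "bound":
        kept = [r for r in kept if r.n_chaperone >= 1]
    elif selector == "free":
        kept = [r for r in kept if r.n_chaperone == 0]
    by_cond: dict = {}
    for r in kept:
        by_cond.setdefault(r.condition, []).append(
            r.n_client if channel == "client" else r.n_chaperone
        )
    rows = []
    for cond, vals in by_cond.items():
        v = np.asarray(vals, dtype=float)
        if grid is None:
            g = np.linspace(1.0, max(v.max() + 4.0, 8.0), 512)
        else:
            g = np.asarray(grid, dtype=float)
        dens = _reflected_kde(v, g)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "condition": cond,
                "n": v.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "density_x": g,
                "density_y": dens,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
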