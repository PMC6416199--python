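"""Statistical assessment of strand-symmetry persistence.

Two comparison modes mirror the two control designs:

* group mode — each genome in a group is paired with one shuffled control;
  the per-order genomic-vs-control differences are tested with the Wilcoxon
  signed-rank test (paired differences are not normal);
* individual mode — one genome is compared against >= 2 (canonically 30)
  shuffled controls with a one-sample t test of the control values against
  the genome's fixed value (control values are close to normal).

Strand symmetry is deemed to persist at order k while the genomic distances
are significantly *smaller* than the control distances; the extent of
symmetry is the largest k such that every order from 2 up to k passes.
Orders at which the genomic values become significantly *larger* mark the
breakdown ("crossing") of symmetry.

Both one-sided p-values and the two-sided p-value are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedGroupTest",
    "IndividualTest",
    "ExtentDecision",
    "wilcoxon_signed_rank",
    "individual_t_test",
    "determine_extent",
    "bin_genomes",
]

DEFAULT_ALPHA = 0.05


@dataclass
class PairedGroupTest:
    k: int
    metric: str
    n_pairs: int
    statistic: float
    p_less: float  # alternative: genomic < control
    p_greater: float
    p_two_sided: float
    direction: str  # smaller | larger | none
    defined: bool = True


@dataclass
class IndividualTest:
    k: int
    genome_value: float
    control_values: list[float]
    t_statistic: float
    p_less: float  # small => genome value significantly below the controls
    p_greater: float
    direction: str
    defined: bool = True


@dataclass
class ExtentDecision:
    per_order: list[tuple[int, str, float]]  # (k, direction, p used)
    extent: int
    alpha: float
    metric: str
    breakdown_orders: list[int] = field(default_factory=list)


def _direction(p_less: float, p_greater: float, alpha: float) -> str:
    if p_less < alpha:
        return "smaller"
    if p_greater < alpha:
        return "larger"
    return "none"


def wilcoxon_signed_rank(
    genomic: Sequence[float],
    control: Sequence[float],
    k: int = 0,
    metric: str = "WSD2",
    alpha: float = DEFAULT_ALPHA,
) -> PairedGroupTest:
    """Paired Wilcoxon signed-rank test of genomic vs. control values.

    Zero differences are dropped (Wilcoxon's convention) and tied absolute
    differences are mid-ranked. The exact null distribution is used for
    n <= 25 untied differences; otherwise the normal approximation with
    continuity correction. Fewer than 5 nonzero differences, or none at
    all, yields an undefined (flagged) result.
    """
    x = np.asarray(genomic, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.shape != y.shape:
        raise ValueError("genomic and control must have equal length")
    d = x - y
    nz = d[d != 0]
    n = nz.size
    if n < 5:
        return PairedGroupTest(
            k=k, metric=metric, n_pairs=int(x.size), statistic=float("nan"),
            p_less=float("nan"), p_greater=float("nan"),
            p_two_sided=float("nan"), direction="none", defined=False,
        )
    has_ties = np.unique(np.abs(nz)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    kwargs = dict(zero_method="wilcox", method=method)
    if method == "approx":
        kwargs["correction"] = True
    res_less = stats.wilcoxon(x, y, alternative="less", **kwargs)
    res_greater = stats.wilcoxon(x, y, alternative="greater", **kwargs)
    res_two = stats.wilcoxon(x, y, alternative="two-sided", **kwargs)
    p_less = float(res_less.pvalue)
    p_greater = float(res_greater.pvalue)
    return PairedGroupTest(
        k=k,
        metric=metric,
        n_pairs=int(x.size),
        statistic=float(res_two.statistic),
        p_less=p_less,
        p_greater=p_greater,
        p_two_sided=float(res_two.pvalue),
        direction=_direction(p_less, p_greater, alpha),
    )


def individual_t_test(
    genome_value: float,
    control_values: Sequence[float],
    k: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> IndividualTest:
    """One-sample t test of the control values against one genome's value.

    t = (mean(controls) - genome_value) / (sd / sqrt(n)), df = n - 1.
    ``p_less`` is the probability of the control mean sitting as far above
    the genome value as observed, so a small ``p_less`` means the genome is
    significantly below its controls. Zero control spread is undefined.
    """
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size < 2:
        raise ValueError("need at least 2 control values")
    if np.ptp(ctrl) == 0:
        return IndividualTest(
            k=k, genome_value=float(genome_value),
            control_values=[float(v) for v in ctrl],
            t_statistic=float("nan"), p_less=float("nan"),
            p_greater=float("nan"), direction="none", defined=False,
        )
    res_less = stats.ttest_1samp(ctrl, popmean=genome_value, alternative="greater")
    res_greater = stats.ttest_1samp(ctrl, popmean=genome_value, alternative="less")
    p_less = float(res_less.pvalue)
    p_greater = float(res_greater.pvalue)
    return IndividualTest(
        k=k,
        genome_value=float(genome_value),
        control_values=[float(v) for v in ctrl],
        t_statistic=float(res_less.statistic),
        p_less=p_less,
        p_greater=p_greater,
        direction=_direction(p_less, p_greater, alpha),
    )


def determine_extent(
    per_order_tests: Sequence,
    alpha: float = DEFAULT_ALPHA,
    k_max: int | None = None,
    metric: str = "WSD2",
) -> ExtentDecision:
    """Highest order at which strand symmetry persists.

    ``per_order_tests`` must supply one test (anything with ``k``,
    ``p_less`` and ``p_greater`` attributes) for every order 2..k_max.
    The extent is the largest k such that the genomic values are
    significantly smaller at *every* order 2..k; an immediate failure at
    order 2 gives extent 1. Orders beyond the extent where the genomic
    values are significantly larger are reported as the breakdown signal.
    """
    by_k = {t.k: t for t in per_order_tests}
    if k_max is None:
        k_max = max(by_k) if by_k else 1
    missing = [k for k in range(2, k_max + 1) if k not in by_k]
    if missing:
        raise ValueError(f"missing tests for orders {missing}")
    per_order: list[tuple[int, str, float]] = []
    breakdown: list[int] = []
    extent = 1
    run_intact = True
    for k in range(2, k_max + 1):
        t = by_k[k]
        direction = _direction(t.p_less, t.p_greater, alpha)
        per_order.append((k, direction, float(t.p_less)))
        if run_intact and direction == "smaller":
            extent = k
        else:
            run_intact = False
            if direction == "larger":
                breakdown.append(k)
    return ExtentDecision(
        per_order=per_order, extent=extent, alpha=alpha, metric=metric,
        breakdown_orders=breakdown,
    )


def bin_genomes(
    values: Sequence[tuple[str, float]], edges: Sequence[float]
) -> tuple[dict[str, int], list[str]]:
    """Assign genomes to half-open covariate bins [e_i, e_{i+1}).

    The final bin is closed on the right, so a covariate equal to the last
    edge is still assigned. Returns (assignments: genome_id -> bin index,
    unassigned genome ids). Edges must be strictly increasing.
    """
    edges = list(edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    assignment: dict[str, int] = {}
    unassigned: list[str] = []
    for gid, v in values:
        if v < edges[0] or v > edges[-1]:
            unassigned.append(gid)
            continue
        if v == edges[-1]:
            assignment[gid] = len(edges) - 2
            continue
        idx = int(np.searchsorted(np.asarray(edges), v, side="right")) - 1
        assignment[gid] = idx
    return assignment, unassigned
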