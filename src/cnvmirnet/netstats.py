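"""Null-network comparison (two-sample KS on per-node metrics) and hub knockouts.

The null model resamples an equal number of miRNAs from outside the CNV set
and rebuilds the network the same way; it is a resampled-node null, not an
edge-rewiring null. Per-node metric distributions of the two networks are
compared with the two-sample Kolmogorov-Smirnov test, and hub-knockout effects
on count-valued global properties (connected components, isolated nodes) are
assessed with single-observation Poisson count tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .regnet import (
    NODE_METRICS,
    BipartiteNetwork,
    GlobalProperties,
    global_properties,
    node_properties,
)

__all__ = [
    "KsResult",
    "KnockoutRecord",
    "sample_null_mirnas",
    "ks_two_sample",
    "compare_networks",
    "poisson_count_test",
    "knockout_analysis",
]


@dataclass(frozen=True)
class KsResult:
    property_name: str
    d_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "asymptotic" | "exact"
    p_adjusted: float | None = None


@dataclass(frozen=True)
class KnockoutRecord:
    removed_node: str
    global_before: GlobalProperties
    global_after: GlobalProperties
    #: per count metric: (statistic, p_value, method) or None when both counts are 0
    tests: dict[str, tuple[float, float, str] | None]
    diameter_changed: bool
    cpl_changed: bool
    density_changed: bool


def sample_null_mirnas(universe: set[str], exclude: set[str], n: int, seed: int) -> set[str]:
    """Uniform sample of n miRNA ids from universe \\ exclude, reproducible by seed."""
    pool = sorted(set(universe) - set(exclude))
    if len(pool) < n:
        raise ValueError(
            f"cannot sample {n} miRNAs: only {len(pool)} available outside the excluded set "
            f"(short by {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=n, replace=False))


def _ecdf_gap(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| evaluated at the pooled sample points."""
    x = np.sort(x)
    y = np.sort(y)
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def _ks_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value of the two-sample KS statistic (no ties).

    Walking the pooled sorted sample defines a monotone lattice path from
    (0, 0) to (n, m); an assignment's D statistic in units of 1/(n*m) is the
    path's maximum |i*m - j*n|. The p-value is the fraction of the
    C(n+m, n) equally likely paths whose maximum reaches the observed value,
    counted by dynamic programming over the lattice with Python integers
    (identical to full enumeration of all label assignments).
    """
    n, m = len(x), len(y)
    # observed integer-valued deviation along the pooled order
    i = j = 0
    d_int = 0
    while i < n or j < m:
        if j >= m or (i < n and x[i] < y[j]):
            i += 1
        else:
            j += 1
        d_int = max(d_int, abs(i * m - j * n))
    # count paths that always stay strictly below d_int
    prev = [0] * (m + 1)
    prev[0] = 1
    for i in range(n + 1):
        row = [0] * (m + 1)
        for j in range(m + 1):
            if abs(i * m - j * n) >= d_int:
                continue
            if i == 0 and j == 0:
                row[j] = 1
                continue
            acc = prev[j] if i > 0 else 0
            if j > 0:
                acc += row[j - 1]
            row[j] = acc
        prev = row
    total = math.comb(n + m, n)
    inside = prev[m] if d_int > 0 else total
    return 1.0 - inside / total


def ks_two_sample(x, y, method: str = "asymptotic", property_name: str = "") -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute ECDF gap over the pooled sample points. The
    asymptotic p-value uses the Kolmogorov tail Q(lambda) with the
    small-sample-corrected argument lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D,
    ne = n_x n_y / (n_x + n_y). The exact p-value is the permutation p over all
    C(n_x + n_y, n_x) label assignments of the pooled sample, computed by
    lattice-path counting in exact integer arithmetic (requires
    n_x * n_y <= 10000 and no ties across the two samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    if method not in ("asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")
    d = _ecdf_gap(x, y)
    n_x, n_y = len(x), len(y)
    if method == "asymptotic":
        ne = n_x * n_y / (n_x + n_y)
        lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
        p = float(min(1.0, max(0.0, special.kolmogorov(lam))))
    else:
        if n_x * n_y > 10_000:
            raise ValueError("exact method requires n_x * n_y <= 10000")
        if np.intersect1d(x, y).size:
            raise ValueError("exact method requires no ties across the two samples")
        p = _ks_exact_p(np.sort(x), np.sort(y))
    return KsResult(property_name, d, p, n_x, n_y, method)


def compare_networks(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    properties: list[str] | None = None,
    method: str = "asymptotic",
    side: str | None = None,
) -> list[KsResult]:
    """KS-compare per-node metric distributions of two networks.

    ``properties`` defaults to all ten node metrics. ``side`` restricts the
    node vectors to one partition ("mirna" or "gene"); by default all nodes of
    each network contribute. Benjamini-Hochberg adjusted p-values are attached
    across the requested properties.
    """
    if net_a.n_nodes == 0 or net_b.n_nodes == 0:
        raise ValueError("both networks must be non-empty")
    properties = list(properties) if properties is not None else list(NODE_METRICS)
    unknown = [p for p in properties if p not in NODE_METRICS]
    if unknown:
        raise ValueError(
            f"unknown metric name(s) {unknown}; valid names: {', '.join(NODE_METRICS)}"
        )
    tables = []
    for net in (net_a, net_b):
        table = node_properties(net)
        if side == "mirna":
            table = table.loc[sorted(net.mirna_nodes)]
        elif side == "gene":
            table = table.loc[sorted(net.gene_nodes)]
        elif side is not None:
            raise ValueError(f"unknown side {side!r}; expected 'mirna' or 'gene'")
        tables.append(table)
    results = [
        ks_two_sample(tables[0][p].to_numpy(), tables[1][p].to_numpy(), method, property_name=p)
        for p in properties
    ]
    _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    return [
        KsResult(r.property_name, r.d_statistic, r.p_value, r.n_x, r.n_y, r.method, float(q))
        for r, q in zip(results, p_adj)
    ]


def poisson_count_test(x1: int, x2: int, method: str = "wald") -> tuple[float, float]:
    """Compare two single Poisson counts.

    ``wald``: z = (x2 - x1) / sqrt(x1 + x2), two-sided normal p-value.
    ``exact_conditional``: given N = x1 + x2, two-sided equal-tail binomial
    test of x2 successes at p = 1/2 (p-value = 2 * min(tail probabilities),
    capped at 1).
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if x1 + x2 == 0:
        raise ValueError("x1 = x2 = 0 carries no information")
    if method == "wald":
        z = (x2 - x1) / math.sqrt(x1 + x2)
        return z, float(2.0 * stats.norm.sf(abs(z)))
    if method == "exact_conditional":
        n = x1 + x2
        lower = float(stats.binom.cdf(min(x1, x2), n, 0.5))
        return float(x2), min(1.0, 2.0 * lower)
    raise ValueError(f"unknown method {method!r}")


def knockout_analysis(
    net: BipartiteNetwork,
    nodes_to_remove: list[str],
    count_metrics: tuple[str, ...] = ("connected_components", "isolated_nodes"),
    cumulative: bool = False,
    tol: float = 1e-9,
) -> list[KnockoutRecord]:
    """Remove hubs and test count-valued global properties for change.

    Each node is removed independently from the original network (one at a
    time); ``cumulative=True`` instead removes them sequentially. For each
    count metric the before/after counts are compared with both Poisson tests;
    a metric at 0 before and after is reported with ``tests[metric] = None``.
    Whether diameter, characteristic path length and density moved beyond
    ``tol`` is also reported.
    """
    for metric in count_metrics:
        if metric not in ("connected_components", "isolated_nodes"):
            raise ValueError(f"unknown count metric {metric!r}")
    records = []
    current = net
    before_all = global_properties(net)
    for node in nodes_to_remove:
        base = current if cumulative else net
        before = global_properties(base) if cumulative else before_all
        after_net = base.remove_node(node)
        after = global_properties(after_net)
        tests: dict[str, tuple[float, float, str] | None] = {}
        for metric in count_metrics:
            x1 = getattr(before, metric)
            x2 = getattr(after, metric)
            if x1 + x2 == 0:
                tests[metric] = None
            else:
                z, p_wald = poisson_count_test(x1, x2, "wald")
                _, p_exact = poisson_count_test(x1, x2, "exact_conditional")
                tests[metric] = (z, p_wald, "wald")
                tests[metric + "_exact"] = (float(x2), p_exact, "exact_conditional")
        records.append(
            KnockoutRecord(
                removed_node=node,
                global_before=before,
                global_after=after,
                tests=tests,
                diameter_changed=abs(after.diameter - before.diameter) > tol,
                cpl_changed=abs(after.characteristic_path_length - before.characteristic_path_length) > tol,
                density_changed=abs(after.density - before.density) > tol,
            )
        )
        if cumulative:
            current = after_net
    return records
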