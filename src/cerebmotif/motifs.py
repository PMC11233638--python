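"""Zone-combination motif analysis under an independence null model.

A motif is a zone-combination input pattern that occurs significantly more
or less often than predicted by a model in which input from each of the
four transverse zones arrives independently.  For a pattern S the null
probability is the product of the plug-in zone probabilities over zones in
S times the complements over zones outside S; the expected count is
``n_total * p(S)``.  Observed counts (cells whose exact zone set equals S)
are compared with an exact one-tailed binomial test, and p-values are
adjusted across the pattern family with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .connectivity import ConnectivityDataset, Zone, ZONES, ZoneMarginals, zone_marginals

Direction = Literal["enriched", "depleted", "equal"]

MotifPattern = frozenset  # frozenset[Zone]

#: All 16 subsets of the four zones, in a fixed canonical order
#: (by size, then by zone order).
ALL_PATTERNS: tuple[frozenset[Zone], ...] = tuple(
    frozenset(combo)
    for r in range(5)
    for combo in itertools.combinations(ZONES, r)
)


def pattern_label(pattern: frozenset[Zone]) -> str:
    """Human-readable label, e.g. 'central+posterior'; 'none' for the empty set."""
    if not pattern:
        return "none"
    return "+".join(z.value for z in ZONES if z in pattern)


def pattern_probability(marginals: ZoneMarginals, pattern: Iterable[Zone]) -> float:
    """Null probability of an exact zone set under zone independence.

    p(S) = prod_{z in S} p_z * prod_{z not in S} (1 - p_z).
    """
    pattern = frozenset(pattern)
    p = marginals.p_zone
    prob = 1.0
    for z in ZONES:
        prob *= p[z] if z in pattern else (1.0 - p[z])
    return prob


def binomial_tail(k: int, n: int, p: float, direction: Direction) -> float:
    """Exact one-tailed binomial probability.

    ``enriched`` -> P(X >= k); ``depleted`` -> P(X <= k) for
    X ~ Binomial(n, p).  Exact (no normal approximation).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if direction == "enriched":
        return float(stats.binom.sf(k - 1, n, p))
    if direction == "depleted":
        return float(stats.binom.cdf(k, n, p))
    raise ValueError(f"unknown direction: {direction!r}")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(i) = min_{j >= i} (m * p_(j) / j), capped at 1, where p_(j) are the
    ascending order statistics of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


@dataclass(frozen=True)
class MotifTestResult:
    """Enrichment test result for one zone-combination pattern."""

    pattern: frozenset[Zone]
    p_pattern: float
    expected: float
    observed: int
    fold: float | None           # observed / expected; None when expected == 0
    direction: Direction
    p_raw: float
    p_adj: float

    @property
    def label(self) -> str:
        return pattern_label(self.pattern)


Family = Literal["nonempty", "all", "observed"]


def _family_patterns(family: Family, observed_sets: set[frozenset[Zone]]) -> list[frozenset[Zone]]:
    if family == "all":
        return list(ALL_PATTERNS)
    if family == "nonempty":
        return [s for s in ALL_PATTERNS if s]
    if family == "observed":
        return [s for s in ALL_PATTERNS if s in observed_sets]
    raise ValueError(f"unknown pattern family: {family!r}")


def motif_report(
    dataset: ConnectivityDataset,
    family: Family = "nonempty",
    marginals: ZoneMarginals | None = None,
) -> list[MotifTestResult]:
    """Test every pattern in the chosen family against the independence null.

    Marginals default to plug-in estimates from the same dataset.  The test
    direction is chosen per pattern by the sign of observed - expected; the
    BH correction runs across the whole family (default: the 15 nonempty
    zone combinations).
    """
    if marginals is None:
        marginals = zone_marginals(dataset)
    n = dataset.n_total
    counts: dict[frozenset[Zone], int] = {s: 0 for s in ALL_PATTERNS}
    for cell in dataset.cells:
        counts[cell.zones] += 1
    patterns = _family_patterns(family, {s for s, c in counts.items() if c > 0})

    rows = []
    for s in patterns:
        p_s = pattern_probability(marginals, s)
        expected = n * p_s
        observed = counts[s]
        if observed > expected:
            direction: Direction = "enriched"
            p_raw = binomial_tail(observed, n, p_s, "enriched")
        elif observed < expected:
            direction = "depleted"
            p_raw = binomial_tail(observed, n, p_s, "depleted")
        else:
            direction = "equal"
            p_raw = 1.0
        fold = observed / expected if expected > 0 else None
        rows.append((s, p_s, expected, observed, fold, direction, p_raw))

    adj = bh_adjust([r[6] for r in rows])
    return [
        MotifTestResult(
            pattern=s,
            p_pattern=p_s,
            expected=expected,
            observed=observed,
            fold=fold,
            direction=direction,
            p_raw=p_raw,
            p_adj=p_adj,
        )
        for (s, p_s, expected, observed, fold, direction, p_raw), p_adj in zip(rows, adj)
    ]
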