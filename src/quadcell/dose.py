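"""Dose-response aggregation and monotone-trend testing.

Per-beat features from recordings at each drug dose are summarized into a
(dose, feature) table of mean, sample sd and count, and each feature is
tested for a monotone dose trend with a seeded two-sided permutation test
on the least-squares slope of value versus dose rank.  Rank (not
log-concentration) is used because typical panels have very few doses and
no curve model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class TrendResult:
    feature: str
    direction: str  # decreasing | increasing | none
    statistic: float
    p_value: float
    n_permutations: int


def aggregate_features(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(dose, feature) mean, sample sd (n-1 denominator) and count.

    ``records`` must carry columns ``dose_nM``, ``feature``, ``value``.
    Returns a tidy DataFrame with one row per (dose, feature).
    """
    required = {"dose_nM", "feature", "value"}
    if records is None or len(records) == 0:
        raise ValidationError("no feature records supplied")
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    out = (
        records.groupby(["dose_nM", "feature"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def _slope(values: np.ndarray, ranks: np.ndarray) -> float:
    return float(np.polyfit(ranks, values, 1)[0])


def _unique_permutations(labels: tuple):
    """All distinct orderings of a label multiset (lexicographic)."""
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    keys = sorted(counts)
    n = len(labels)
    perm = []

    def rec():
        if len(perm) == n:
            yield tuple(perm)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                perm.append(k)
                yield from rec()
                perm.pop()
                counts[k] += 1

    yield from rec()


def trend_test(
    records: pd.DataFrame,
    feature: str,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    method: str = "auto",
) -> TrendResult:
    """Two-sided permutation test for a monotone dose trend in one feature.

    The statistic is the least-squares slope of the per-beat values against
    the rank of their dose.  ``method='exhaustive'`` enumerates every
    distinct assignment of dose labels (exact p); ``'monte_carlo'`` shuffles
    labels ``n_permutations`` times with the usual add-one correction;
    ``'auto'`` picks exhaustive when the number of distinct assignments does
    not exceed ``n_permutations``.
    """
    sub = records[records["feature"] == feature] if "feature" in records.columns else records
    if len(sub) == 0:
        raise ValidationError(f"no records for feature {feature!r}")
    doses = np.asarray(sub["dose_nM"], dtype=float)
    values = np.asarray(sub["value"], dtype=float)
    levels = np.unique(doses)
    if levels.size < 2:
        raise ValidationError("trend test requires at least 2 doses")
    rank_of = {d: i for i, d in enumerate(levels)}
    ranks = np.array([rank_of[d] for d in doses], dtype=float)
    obs = _slope(values, ranks)

    from math import comb, prod

    n = len(values)
    counts = [int((doses == d).sum()) for d in levels]
    n_distinct = prod(
        comb(rem, k) for rem, k in zip(np.cumsum(counts[::-1])[::-1], counts)
    )
    if method == "auto":
        method = "exhaustive" if n_distinct <= max(n_permutations, 1) else "monte_carlo"

    if method == "exhaustive":
        if n_distinct > 200_000:
            raise ValidationError(
                f"{n_distinct} distinct label assignments; use monte_carlo"
            )
        hits = 0
        total = 0
        for perm in _unique_permutations(tuple(ranks)):
            total += 1
            if abs(_slope(values, np.asarray(perm))) >= abs(obs) - _TIE_EPS:
                hits += 1
        p = hits / total
        n_used = total
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        hits = 0
        perm_ranks = ranks.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm_ranks)
            if abs(_slope(values, perm_ranks)) >= abs(obs) - _TIE_EPS:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        n_used = n_permutations
    else:
        raise ValidationError(f"unknown method {method!r}")

    if p < alpha:
        direction = "decreasing" if obs < 0 else "increasing"
    else:
        direction = "none"
    return TrendResult(feature, direction, obs, float(p), n_used)
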