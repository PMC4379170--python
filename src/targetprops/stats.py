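"""Per-feature class comparison and dataset-homogeneity statistics.

For each feature the positive and unlabelled samples are compared with a
two-tailed Mann-Whitney U test (Bonferroni-corrected across the tested
features) and the probability of superiority PS = U/(m*n) — the chance
that a random positive protein exceeds a random unlabelled one on the
feature, with ties credited half.  PS = 0.5 means no effect.

Dataset homogeneity is summarised as the percentage of protein pairs
whose sequence identity reaches a threshold (default 20%), overall and
split into positive-positive, unlabelled-unlabelled and cross-class
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .constants import DEFAULT_UNTESTED_FEATURES

__all__ = [
    "FeatureStatsRow",
    "HomogeneityReport",
    "mann_whitney_u",
    "probability_superiority",
    "feature_analysis",
    "length_normalized_ps",
    "homogeneity",
    "homogeneity_crosstab",
    "stats_to_frame",
]

# Below this pooled sample size the exact permutation null is enumerated;
# above it the tie-corrected normal approximation with continuity
# correction is used.
EXACT_ENUMERATION_LIMIT = 20


def _u_statistic(pos: np.ndarray, unl: np.ndarray) -> float:
    """U of the positive sample via midranks (ties score 0.5 per pair)."""
    m = pos.size
    pooled = np.concatenate([pos, unl])
    ranks = rankdata(pooled)
    return float(ranks[:m].sum() - m * (m + 1) / 2.0)


def _exact_two_tailed_p(pooled: np.ndarray, m: int, u_obs: float) -> float:
    """Exact two-tailed p by enumerating all positive-index combinations.

    Valid with ties because U is computed from midranks of the fixed
    pooled sample; the null is the uniform distribution over which m of
    the m+n values are labelled positive.
    """
    n_total = pooled.size
    ranks = rankdata(pooled)
    base = m * (m + 1) / 2.0
    centre = m * (n_total - m) / 2.0
    dev = abs(u_obs - centre)
    hits = 0
    for combo in combinations(range(n_total), m):
        u = ranks[list(combo)].sum() - base
        if abs(u - centre) >= dev - 1e-9:
            hits += 1
    return hits / comb(n_total, m)


def _normal_two_tailed_p(pooled: np.ndarray, m: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n_total = pooled.size
    n = n_total - m
    mu = m * n / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = (m * n / 12.0) * (
        (n_total + 1) - tie_term / (n_total * (n_total - 1))
    )
    if var <= 0:  # all values tied
        return 1.0
    dev = abs(u_obs - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney_u(pos_values, unl_values) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test of the positive sample.

    Returns (U, p).  U counts pairs where the positive value exceeds the
    unlabelled one, ties scoring 0.5.  The p-value is exact (full
    enumeration, tie-aware) for pooled sizes up to
    ``EXACT_ENUMERATION_LIMIT`` and a tie- and continuity-corrected
    normal approximation beyond that.
    """
    pos = np.asarray(pos_values, dtype=float)
    unl = np.asarray(unl_values, dtype=float)
    if pos.size == 0 or unl.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(pos, unl)
    pooled = np.concatenate([pos, unl])
    if pos.size + unl.size <= EXACT_ENUMERATION_LIMIT:
        p = _exact_two_tailed_p(pooled, pos.size, u)
    else:
        p = _normal_two_tailed_p(pooled, pos.size, u)
    return u, p


def probability_superiority(u: float, m: int, n: int) -> float:
    """PS = U/(m*n), the common-language effect size."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if not 0.0 <= u <= m * n:
        raise ValueError(f"U={u} outside [0, {m * n}]")
    return u / (m * n)


@dataclass
class FeatureStatsRow:
    """Per-feature comparison of the positive and unlabelled classes."""

    feature: str
    u: float | None
    p: float | None
    significant: bool
    ps: float
    median_pos: float
    median_unl: float
    tested: bool


def feature_analysis(
    table: pd.DataFrame,
    labels,
    exclusions: frozenset[str] | set[str] | None = None,
    alpha: float = 0.05,
) -> list[FeatureStatsRow]:
    """Mann-Whitney/Bonferroni/PS analysis of every feature column.

    ``exclusions`` are feature names reported but not tested (defaults to
    the raw expression levels and the tiny/small fractions; the derived
    expression-breadth count is tested).  Bonferroni significance is at
    level ``alpha`` divided by the number of features actually tested in
    this run.  Excluded features still get a PS and medians.  Constant
    features get PS 0.5 and p = 1.
    """
    if exclusions is None:
        exclusions = DEFAULT_UNTESTED_FEATURES
    y = np.asarray(labels, dtype=int)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be non-empty")
    pos_rows = y == 1
    m = int(pos_rows.sum())
    n = int((~pos_rows).sum())
    tested_features = [c for c in table.columns if c not in exclusions]
    k = len(tested_features)

    rows = []
    for feature in table.columns:
        values = table[feature].to_numpy(dtype=float)
        pos = values[pos_rows]
        unl = values[~pos_rows]
        u = _u_statistic(pos, unl)
        ps = probability_superiority(u, m, n)
        tested = feature not in exclusions
        if tested:
            _, p = mann_whitney_u(pos, unl)
            significant = k > 0 and p * k <= alpha
        else:
            p = None
            significant = False
        rows.append(
            FeatureStatsRow(
                feature=feature,
                u=u,
                p=p,
                significant=significant,
                ps=ps,
                median_pos=float(np.median(pos)),
                median_unl=float(np.median(unl)),
                tested=tested,
            )
        )
    return rows


def length_normalized_ps(feature_values, sequence_lengths, labels) -> float:
    """PS of the per-residue-normalised feature (value / sequence length)."""
    values = np.asarray(feature_values, dtype=float)
    lengths = np.asarray(sequence_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("sequence lengths must be strictly positive")
    y = np.asarray(labels, dtype=int)
    normalised = values / lengths
    pos = normalised[y == 1]
    unl = normalised[y == 0]
    u = _u_statistic(pos, unl)
    return probability_superiority(u, pos.size, unl.size)


@dataclass
class HomogeneityReport:
    threshold: float
    percent_all: float
    percent_pos_pos: float
    percent_unl_unl: float
    percent_pos_unl: float
    similar_all: int
    similar_pos_pos: int
    similar_unl_unl: int
    similar_pos_unl: int


def _pair_counts(sim: np.ndarray, mask_a: np.ndarray,
                 mask_b: np.ndarray) -> int:
    if mask_a is mask_b:
        block = sim[np.ix_(mask_a, mask_a)]
        return int(np.triu(block, k=1).sum())
    return int(sim[np.ix_(mask_a, mask_b)].sum())


def homogeneity(labels, identity_matrix, threshold: float = 20.0
                ) -> HomogeneityReport:
    """Percentage of similar pairs overall and per class-pair type.

    ``identity_matrix`` is a symmetric percent-identity matrix (ndarray or
    DataFrame) over the dataset's proteins in label order.  A pair is
    similar when its identity is at least ``threshold``.  Within-class
    denominators are k(k-1)/2; the cross-class denominator is m*n.
    """
    ident = identity_matrix.to_numpy() if isinstance(
        identity_matrix, pd.DataFrame) else np.asarray(identity_matrix)
    y = np.asarray(labels, dtype=int)
    if ident.shape != (y.size, y.size):
        raise ValueError("identity matrix does not cover the dataset")
    sim = ident >= threshold
    pos = y == 1
    unl = ~pos
    m = int(pos.sum())
    n = int(unl.sum())
    total = m + n

    s_pp = _pair_counts(sim, pos, pos)
    s_uu = _pair_counts(sim, unl, unl)
    s_pu = _pair_counts(sim, pos, unl)
    s_all = s_pp + s_uu + s_pu

    def pct(count, denom):
        return 100.0 * count / denom if denom else 0.0

    return HomogeneityReport(
        threshold=threshold,
        percent_all=pct(s_all, comb(total, 2)),
        percent_pos_pos=pct(s_pp, comb(m, 2)),
        percent_unl_unl=pct(s_uu, comb(n, 2)),
        percent_pos_unl=pct(s_pu, m * n),
        similar_all=s_all,
        similar_pos_pos=s_pp,
        similar_unl_unl=s_uu,
        similar_pos_unl=s_pu,
    )


def homogeneity_crosstab(
    labels, partition, identity_matrix, threshold: float = 20.0
) -> pd.DataFrame:
    """Similar-pair counts cross-tabulated by (class, partition) group.

    ``partition`` assigns each protein to a named subpopulation (e.g.
    metallo vs non-metallo proteases); the result counts similar pairs
    for every unordered combination of (class, partition) groups.
    """
    ident = identity_matrix.to_numpy() if isinstance(
        identity_matrix, pd.DataFrame) else np.asarray(identity_matrix)
    y = np.asarray(labels, dtype=int)
    parts = np.asarray(partition)
    sim = ident >= threshold
    groups = []
    for cls, cls_name in ((1, "positive"), (0, "unlabelled")):
        for part in sorted(set(parts.tolist())):
            mask = (y == cls) & (parts == part)
            if mask.any():
                groups.append((f"{cls_name}:{part}", mask))
    names = [g[0] for g in groups]
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, (name_a, mask_a) in enumerate(groups):
        for j, (name_b, mask_b) in enumerate(groups):
            if j < i:
                continue
            if i == j:
                out.loc[name_a, name_b] = _pair_counts(sim, mask_a, mask_a)
            else:
                out.loc[name_a, name_b] = _pair_counts(sim, mask_a, mask_b)
    return out


def stats_to_frame(rows: list[FeatureStatsRow]) -> pd.DataFrame:
    """Stats report in the standard output schema."""
    return pd.DataFrame(
        {
            "Feature": [r.feature for r in rows],
            "P-value": [r.p for r in rows],
            "PS": [r.ps for r in rows],
            "PositiveMedian": [r.median_pos for r in rows],
            "UnlabelledMedian": [r.median_unl for r in rows],
            "Significant": [r.significant for r in rows],
            "Tested": [r.tested for r in rows],
        }
    )
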