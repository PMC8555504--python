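"""Robust rank aggregation of per-study ranked feature lists.

Each study contributes an ordered list (best first) drawn from a shared
universe of N features.  A feature at position k receives the normalised
rank r = k/N; features absent from a list score r = 1 (the worst possible).
For the sorted normalised ranks r_(1) <= ... <= r_(m) over m lists, the
score of the k-th order statistic is the probability that the k-th smallest
of m independent Uniform(0,1) draws falls at or below r_(k):

    b_k = P(Beta(k, m-k+1) <= r_(k)) = sum_{j=k..m} C(m,j) r^j (1-r)^(m-j)

The aggregation score is rho = min_k b_k, and the reported significance is
the Bonferroni-corrected min(1, m * rho).  Small corrected scores flag
features ranked consistently near the top across studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError


@dataclass
class RankedLists:
    """Per-study ranked lists over a shared feature universe.

    ``lists`` maps study ID -> ordered feature symbols, best first.  Every
    listed feature must belong to ``universe``; lists may be shorter than
    the universe (missing features score worst).
    """

    universe: list[str]
    lists: dict[str, list[str]]
    direction: str = "up"

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise DataError("universe contains duplicate features")
        if not self.universe:
            raise DataError("empty universe")
        for sid, lst in self.lists.items():
            if len(set(lst)) != len(lst):
                raise DataError(f"list {sid!r} repeats a feature")
            stray = set(lst) - uni
            if stray:
                raise DataError(f"list {sid!r} has features outside the universe: {sorted(stray)[:5]}")
            if len(lst) > len(self.universe):
                raise DataError(f"list {sid!r} longer than the universe")


def normalize_ranks(lists: RankedLists) -> pd.DataFrame:
    """Features x studies matrix of normalised ranks; absent features get 1.0."""
    n = len(lists.universe)
    idx = {f: i for i, f in enumerate(lists.universe)}
    mat = np.ones((n, len(lists.lists)))
    for j, (sid, lst) in enumerate(lists.lists.items()):
        for k, f in enumerate(lst, start=1):
            mat[idx[f], j] = k / n
    return pd.DataFrame(mat, index=lists.universe, columns=list(lists.lists))


def rho_score(r_sorted) -> float:
    """min_k P(Beta(k, m-k+1) <= r_(k)) for a sorted vector of normalised ranks."""
    r = np.asarray(r_sorted, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise DataError("rho_score expects a non-empty 1-D vector")
    if np.any(np.diff(r) < 0):
        raise DataError("ranks must be sorted non-decreasing")
    if np.any((r <= 0) | (r > 1)):
        raise DataError("normalised ranks must lie in (0, 1]")
    m = r.size
    k = np.arange(1, m + 1)
    b = stats.beta.cdf(r, k, m - k + 1)
    return float(b.min())


def _beta_scores_matrix(r: np.ndarray) -> np.ndarray:
    """Row-wise b_k scores for a (features x m) matrix of ranks (rows get sorted)."""
    r = np.sort(r, axis=1)
    m = r.shape[1]
    k = np.arange(1, m + 1)
    return stats.beta.cdf(r, k[None, :], (m - k + 1)[None, :])


def aggregate(lists: RankedLists, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate ranked lists into per-feature rho and corrected scores.

    Returns a DataFrame sorted by corrected score then symbol, with columns
    feature, rho, corrected, n_lists_present, direction, called
    (corrected < ``alpha``).
    """
    if not lists.lists:
        raise DataError("need at least one ranked list")
    ranks = normalize_ranks(lists)
    m = ranks.shape[1]
    b = _beta_scores_matrix(ranks.to_numpy())
    rho = b.min(axis=1)
    corrected = np.minimum(1.0, rho * m)
    present = np.zeros(len(lists.universe), dtype=int)
    membership = [set(lst) for lst in lists.lists.values()]
    for i, f in enumerate(lists.universe):
        present[i] = sum(f in s for s in membership)
    out = pd.DataFrame(
        {
            "feature": lists.universe,
            "rho": rho,
            "corrected": corrected,
            "n_lists_present": present,
            "direction": lists.direction,
            "called": corrected < alpha,
        }
    )
    return out.sort_values(["corrected", "feature"], kind="stable").reset_index(drop=True)


def ranked_lists_from_de(
    de_tables: dict[str, pd.DataFrame],
    direction: str,
    mode: str = "full",
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> RankedLists:
    """Build per-direction ranked lists from per-study DE tables.

    ``full`` mode ranks every feature whose log2FC has the requested sign by
    ascending p-value; ``thresholded`` mode ranks only features passing the
    |log2FC|/FDR thresholds.  The universe is the union of all study features.
    """
    if direction not in ("up", "down"):
        raise DataError("direction must be 'up' or 'down'")
    if mode not in ("full", "thresholded"):
        raise DataError("mode must be 'full' or 'thresholded'")
    sign = 1 if direction == "up" else -1
    universe = sorted({f for t in de_tables.values() for f in t["feature"]})
    lists = {}
    for sid, table in de_tables.items():
        sub = table[np.sign(table["log2fc"]) == sign]
        if mode == "thresholded":
            sub = sub[(sub["log2fc"].abs() >= lfc) & (sub["fdr"] < fdr)]
        sub = sub.sort_values(["p_value", "feature"], kind="stable")
        lists[sid] = list(sub["feature"])
    return RankedLists(universe=universe, lists=lists, direction=direction)


def consensus_calls(up_table: pd.DataFrame, down_table: pd.DataFrame, kind: str = "gene") -> dict[str, str]:
    """Merge per-direction aggregation tables into symbol -> direction calls.

    A feature called in both directions (possible only by noise) keeps the
    direction with the smaller corrected score.
    """
    from .dataio import canonical_symbol

    best: dict[str, tuple[float, str]] = {}
    for table in (up_table, down_table):
        for _, row in table[table["called"]].iterrows():
            key = canonical_symbol(row["feature"], kind)
            score = float(row["corrected"])
            if key not in best or score < best[key][0]:
                best[key] = (score, row["direction"])
    return {k: d for k, (_, d) in best.items()}
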