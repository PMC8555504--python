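"""Per-study differential expression: Welch t-tests, BH correction and
|log2FC| / FDR threshold calls.

The same code path serves mRNA and miRNA studies; the calling criteria
(|log2FC| >= 1 and FDR < 0.05 by default) are identical for both.  The
log2 fold change is simply mean(case) - mean(control), since the input
matrices are already on the log2 scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CASE, CONTROL, DataError, ExpressionStudy

DE_COLUMNS = ["feature", "log2fc", "t_stat", "p_value", "fdr", "direction", "passed", "degenerate"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_test(study: ExpressionStudy, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per feature, case vs control.

    Features with zero variance in both groups cannot be tested: equal group
    means get p = 1, unequal means p = 0; either way the row is flagged
    ``degenerate``.  Returns a DataFrame with columns ``DE_COLUMNS``.
    """
    case = study.group_values(CASE)
    ctrl = study.group_values(CONTROL)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise DataError(f"{study.study_id}: need >=2 samples per group")

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger scipy precision warnings; they are
        # repaired explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    degenerate = zero_var.copy()
    equal_means = zero_var & (log2fc == 0)
    t[equal_means], p[equal_means] = 0.0, 1.0
    shifted = zero_var & (log2fc != 0)
    t[shifted] = np.sign(log2fc[shifted]) * np.inf
    p[shifted] = 0.0

    fdr = bh_adjust(p)
    passed = (np.abs(log2fc) >= lfc_threshold) & (fdr < fdr_threshold)
    direction = np.where(~passed, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "feature": study.features,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "passed": passed,
            "degenerate": degenerate,
        }
    )


def threshold_de(table: pd.DataFrame, lfc: float = 1.0, fdr: float = 0.05) -> tuple[frozenset, frozenset]:
    """(up, down) feature sets at |log2FC| >= lfc (inclusive) and q < fdr (strict)."""
    if lfc <= 0 or fdr <= 0:
        raise DataError("thresholds must be positive")
    hit = (table["log2fc"].abs() >= lfc) & (table["fdr"] < fdr)
    up = frozenset(table.loc[hit & (table["log2fc"] > 0), "feature"])
    down = frozenset(table.loc[hit & (table["log2fc"] < 0), "feature"])
    return up, down


def de_calls(table: pd.DataFrame, lfc: float = 1.0, fdr: float = 0.05, kind: str = "gene") -> dict[str, str]:
    """Canonical-symbol -> direction map for features passing the thresholds."""
    from .dataio import canonical_symbol

    up, down = threshold_de(table, lfc=lfc, fdr=fdr)
    calls: dict[str, str] = {}
    for sym in up:
        calls[canonical_symbol(sym, kind)] = "up"
    for sym in down:
        calls[canonical_symbol(sym, kind)] = "down"
    return calls
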