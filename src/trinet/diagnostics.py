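"""Validation of network relationships and marker value.

Pearson correlation screens of TF-target pairs across pooled samples
(|r| > 0.3 and p < 0.05 flags a correlation), per-gene ROC/AUC marker
evaluation (AUC > 0.9 flags a good marker), and the 2^-ddCt relative
quantification utility for qPCR cycle-threshold tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .dataio import CASE, CONTROL, DataError, ExpressionStudy


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p-value from the t transform with
    n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson expects two equal-length 1-D vectors")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DataError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(
    expr: ExpressionStudy,
    pairs: list[tuple[str, str]],
    r_cut: float = 0.3,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Correlate each (tf, target) pair across all samples (cases + controls).

    ``correlated`` is True iff |r| > r_cut and p < p_cut (both strict).
    Pairs with a symbol absent from the study are kept with status
    ``missing`` rather than dropped.
    """
    rows = []
    for tf, target in pairs:
        xt = expr.row(tf)
        yt = expr.row(target)
        if xt is None or yt is None:
            rows.append((tf, target, np.nan, np.nan, False, "missing"))
            continue
        r, p = pearson(xt, yt)
        rows.append((tf, target, r, p, bool(abs(r) > r_cut and p < p_cut), "ok"))
    return pd.DataFrame(rows, columns=["tf", "target", "r", "p", "correlated", "status"])


def roc_auc(scores, labels) -> float:
    """Case-high ROC AUC: the tie-adjusted Mann-Whitney U statistic divided
    by n_case x n_control."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be equal-length 1-D vectors")
    bad = set(labels) - {CASE, CONTROL}
    if bad:
        raise DataError(f"labels must be 'case'/'control', got {sorted(bad)}")
    y = (labels == CASE).astype(int)
    if y.min() == y.max():
        raise DataError("both classes must be present")
    return float(roc_auc_score(y, scores))


def marker_screen(
    expr: ExpressionStudy,
    genes: list[str],
    auc_cut: float = 0.9,
) -> pd.DataFrame:
    """Per-gene diagnostic AUC in case-vs-control discrimination.

    Genes expressed lower in cases are evaluated with inverted orientation
    (the reported AUC is max(a, 1-a)) and the orientation is recorded, so a
    strongly down-regulated marker scores high rather than near zero.
    ``good_marker`` is True iff AUC > auc_cut (strict).
    """
    labels = np.array([expr.design[s] for s in expr.samples])
    rows = []
    for gene in genes:
        vals = expr.row(gene)
        if vals is None:
            rows.append((gene, np.nan, "missing", False, "missing"))
            continue
        a = roc_auc(vals, labels)
        orientation = "case-high" if a >= 0.5 else "case-low"
        best = max(a, 1.0 - a)
        rows.append((gene, best, orientation, bool(best > auc_cut), "ok"))
    return pd.DataFrame(rows, columns=["gene", "auc", "orientation", "good_marker", "status"])


def ddct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """2^-ddCt relative quantification from a long-format Ct table.

    ``ct`` needs columns (sample, group, gene, ct); ``group`` is
    case/control.  Per sample, dCt = Ct_gene - Ct_reference; per gene,
    ddCt = mean dCt(case) - mean dCt(control) and fold = 2^-ddCt.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise DataError(f"Ct table needs columns {sorted(required)}")
    bad = set(ct["group"]) - {CASE, CONTROL}
    if bad:
        raise DataError(f"groups must be 'case'/'control', got {sorted(bad)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    samples = ct["sample"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise DataError(f"reference gene {reference_gene!r} not measured in samples {missing}")

    work = ct[ct["gene"] != reference_gene].copy()
    work["dct"] = work["ct"].to_numpy(dtype=float) - ref.loc[work["sample"]].to_numpy(dtype=float)
    rows = []
    for gene, sub in work.groupby("gene", sort=True):
        case_d = sub.loc[sub["group"] == CASE, "dct"]
        ctrl_d = sub.loc[sub["group"] == CONTROL, "dct"]
        if case_d.empty or ctrl_d.empty:
            raise DataError(f"gene {gene!r} lacks measurements in one group")
        dd = float(case_d.mean() - ctrl_d.mean())
        rows.append((gene, dd, 2.0 ** (-dd)))
    return pd.DataFrame(rows, columns=["gene", "ddct", "fold_change"])
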