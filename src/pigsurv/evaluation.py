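"""Validation criteria for genomic prediction of survival.

Computed on the validation generation: accuracy (Pearson correlation of EBV
with true breeding value), dispersion bias (OLS slope of whole-data EBV on
reference-data EBV), realized selection differentials (mean TBV of the top
1% / 30% on total EBV), and paired t-tests across replicates for the
significance letters of the summary tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy",
    "dispersion_regression",
    "selection_differential",
    "paired_t_test",
    "significance_letters",
]


def accuracy(ebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between EBV and TBV over the validation set."""
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if ebv.size < 3:
        raise ValueError("need at least 3 validation individuals")
    if np.std(ebv) == 0 or np.std(tbv) == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(np.corrcoef(ebv, tbv)[0, 1])


def dispersion_regression(ebv_whole: np.ndarray, ebv_reference: np.ndarray) -> float:
    """OLS slope of whole-data EBV on reference-data EBV.

    A slope of 1 indicates dispersion-unbiased predictions from the reduced
    (reference) data relative to the fully informed fit.
    """
    x = np.asarray(ebv_reference, dtype=float)
    y = np.asarray(ebv_whole, dtype=float)
    vx = np.var(x)
    if vx == 0:
        raise ValueError("reference EBV has zero variance")
    return float(np.cov(x, y, ddof=0)[0, 1] / vx)


def selection_differential(
    ebv_total: pd.Series, tbv: pd.DataFrame, fraction: float
) -> dict:
    """Mean TBV (a, m, a+m) of the top ``fraction`` ranked on total EBV.

    ``tbv`` must be indexed by id with columns ``tbv_a`` and ``tbv_m``.
    Selects ceil(fraction * n) individuals; ties broken by (EBV desc, id).
    """
    n = len(ebv_total)
    k = int(np.ceil(fraction * n))
    if k < 1:
        raise ValueError("selected fraction yields an empty selection")
    df = pd.DataFrame({"ebv": ebv_total}).join(tbv, how="left")
    df = df.sort_values(["ebv"], ascending=False, kind="stable").head(k)
    return {
        "a": float(df["tbv_a"].mean()),
        "m": float(df["tbv_m"].mean()),
        "total": float((df["tbv_a"] + df["tbv_m"]).mean()),
    }


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test; returns (t, two-sided p).

    Conventions for degenerate input: identical vectors give (0.0, 1.0);
    constant non-zero differences give (+/-inf, 0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired replicates")
    d = x - y
    if np.std(d) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def significance_letters(
    values: dict, alpha: float = 0.05
) -> dict:
    """Compact letter display from pairwise paired t-tests.

    ``values`` maps group label -> per-replicate vector (all equal length).
    Groups are sorted by descending mean; each letter marks a maximal run of
    consecutive groups that are pairwise non-significant at ``alpha``.
    """
    labels = sorted(values, key=lambda k: -np.mean(values[k]))
    n = len(labels)
    differ = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            _, p = paired_t_test(values[labels[i]], values[labels[j]])
            differ[i, j] = differ[j, i] = p < alpha
    letters = {lab: "" for lab in labels}
    letter_ord = ord("a")
    i = 0
    covered_until = -1
    while i < n:
        j = i
        while j + 1 < n and not differ[i : j + 2, i : j + 2].any():
            j += 1
        if j > covered_until:
            ch = chr(letter_ord)
            letter_ord += 1
            for k in range(i, j + 1):
                letters[labels[k]] += ch
            covered_until = j
        i += 1
    return letters
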