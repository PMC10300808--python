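"""Group comparison of shape proportions with FDR control.

Per proportion: a Kolmogorov–Smirnov screen against a fitted normal, a
two-sample Welch t-test between groups, and Benjamini–Hochberg adjustment
of the eight p-values of one comparison table.  The KS screen fits the
normal's mean and standard deviation from the sample, which is known to be
anticonservative (the Lilliefors effect); an optional Lilliefors-corrected
variant is exposed for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .landmarks import PROPORTION_CODES, ProportionVector

__all__ = [
    "ks_normality",
    "welch_t",
    "bh_adjust",
    "compare_groups",
    "normality_report",
    "GroupComparisonTable",
]


def ks_normality(sample: Sequence[float], lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test of ``sample`` against N(sample mean, sample sd).

    Returns (D, p) with p from the asymptotic KS distribution.  With
    ``lilliefors`` the p-value instead comes from the Lilliefors table,
    which accounts for the estimated parameters.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("KS normality screen needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        D, p = _lf(x, dist="norm")
        return float(D), float(p)
    D, p = sps.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return float(D), float(p)


def welch_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; Welch (unequal variances) by default.

    Returns (t, degrees of freedom, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("both samples constant and equal: t undefined")
        # constant samples with different means: infinitely significant
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(a.size + b.size - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        na, nb = a.size, b.size
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparisonTable:
    """Per-proportion group means and BH-adjusted Welch p-values."""

    label_a: str
    label_b: str
    table: pd.DataFrame  # index P01..P08; columns mean_a, mean_b, t, df, raw_p, adj_p, significant
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        df = self.table.copy()
        if decimals is not None:
            for col in ("mean_a", "mean_b", "raw_p", "adj_p"):
                df[col] = df[col].round(decimals)
        return df

    def to_text(self) -> str:
        """Fixed-width report: Proportion | mean A | mean B | Adj. p-Value."""
        lines = [
            f"{'Proportion':<12}{self.label_a:>10}{self.label_b:>10}{'Adj. p':>10}"
        ]
        for code, row in self.table.iterrows():
            lines.append(
                f"{code:<12}{row['mean_a']:>10.3f}{row['mean_b']:>10.3f}"
                f"{row['adj_p']:>10.3f}"
            )
        return "\n".join(lines)


def _prop_matrix(props: Sequence[ProportionVector]) -> np.ndarray:
    return np.stack([p.as_array() for p in props])


def compare_groups(
    props_a: Sequence[ProportionVector],
    props_b: Sequence[ProportionVector],
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = False,
) -> GroupComparisonTable:
    """Compare two groups proportion-by-proportion with BH over the 8 tests."""
    if not props_a or not props_b:
        raise ValueError("both groups must be non-empty")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    A, B = _prop_matrix(props_a), _prop_matrix(props_b)
    rows = []
    for j, code in enumerate(PROPORTION_CODES):
        try:
            t, df, p = welch_t(A[:, j], B[:, j], equal_var=equal_var)
        except ValueError:
            # both groups constant and equal: no evidence of a difference
            t, df, p = 0.0, float("nan"), 1.0
        rows.append((code, A[:, j].mean(), B[:, j].mean(), t, df, p))
    df_out = pd.DataFrame(
        rows, columns=["proportion", "mean_a", "mean_b", "t", "df", "raw_p"]
    ).set_index("proportion")
    df_out["adj_p"] = bh_adjust(df_out["raw_p"].to_numpy())
    df_out["significant"] = df_out["adj_p"] < alpha
    return GroupComparisonTable(label_a=label_a, label_b=label_b, table=df_out, alpha=alpha)


def normality_report(
    groups: dict[str, Sequence[ProportionVector]],
    alpha: float = 0.05,
    lilliefors: bool = False,
) -> pd.DataFrame:
    """KS normality screen for every group x proportion cell."""
    rows = []
    for label, props in groups.items():
        M = _prop_matrix(props)
        for j, code in enumerate(PROPORTION_CODES):
            try:
                D, p = ks_normality(M[:, j], lilliefors=lilliefors)
                rows.append((label, code, D, p, p >= alpha))
            except ValueError:
                # degenerate (constant) sample: screen is undefined
                rows.append((label, code, float("nan"), float("nan"), False))
    return pd.DataFrame(
        rows, columns=["group", "proportion", "D", "p", "normal_assumed"]
    )
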