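"""Group comparisons between survivors and nonsurvivors.

Clinical validation of the prognostic ratio compares its distribution
(and routine clinical covariates) between outcome groups.  Continuous
parameters get a two-sided Welch t-test when both groups pass a
Shapiro normality screen at 0.05, otherwise a Mann-Whitney U test; the
gender ratio gets a chi-square test on the 2x2 contingency table
(no continuity correction by default).  Significance convention:
P < 0.05.

Records travel as a pandas DataFrame with an ``outcome`` column holding
``survivor`` / ``nonsurvivor`` plus named numeric covariate columns and
an optional ``gender`` column (M/F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "compare_groups", "compare_gender", "cohort_table"]

OUTCOMES = ("survivor", "nonsurvivor")
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_sd: dict                 # group -> (mean, sd) or counts for chi2
    n: dict                       # group -> sample size
    test_used: str                # 't' | 'mann_whitney' | 'chi2'
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def formatted(self) -> dict:
        row = {"parameter": self.parameter}
        for g in OUTCOMES:
            v = self.mean_sd.get(g)
            if isinstance(v, tuple):
                row[g] = f"{v[0]:.2f} ± {v[1]:.2f}"
            else:
                row[g] = str(v)
        row["test"] = self.test_used
        row["P"] = "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"
        return row


def _groups(records: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    if "outcome" not in records.columns:
        raise ValueError("records need an 'outcome' column")
    out: list[np.ndarray] = []
    for g in OUTCOMES:
        x = pd.to_numeric(records.loc[records["outcome"] == g, parameter],
                          errors="coerce").dropna().to_numpy()
        if len(x) == 0:
            raise ValueError(f"no '{g}' values for parameter '{parameter}'")
        out.append(x)
    return out[0], out[1]


def compare_groups(records: pd.DataFrame, parameter: str,
                   test_policy: str = "auto") -> GroupComparison:
    """Two-sided survivor-vs-nonsurvivor comparison of one parameter.

    ``test_policy``: 'auto' (normality screen), 't', or 'mann_whitney'.
    """
    a, b = _groups(records, parameter)
    if test_policy == "auto":
        normal = all(
            len(x) >= 3 and (np.ptp(x) > 0) and stats.shapiro(x).pvalue > NORMALITY_ALPHA
            for x in (a, b)
        )
        test = "t" if normal else "mann_whitney"
    elif test_policy in ("t", "mann_whitney"):
        test = test_policy
    else:
        raise ValueError(f"unknown test policy '{test_policy}'")

    if test == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError(f"zero variance in both groups for '{parameter}'")
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        parameter=parameter,
        mean_sd={g: (float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0)
                 for g, x in zip(OUTCOMES, (a, b))},
        n={g: len(x) for g, x in zip(OUTCOMES, (a, b))},
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_gender(records: pd.DataFrame | None = None, *,
                   counts: np.ndarray | None = None,
                   correction: bool = False) -> GroupComparison:
    """Chi-square test of the gender ratio between outcome groups.

    Either pass `records` with 'outcome' and 'gender' columns, or the
    2x2 `counts` table [[surv_M, surv_F], [nonsurv_M, nonsurv_F]].
    No Yates continuity correction unless requested.
    """
    if counts is None:
        if records is None:
            raise ValueError("need records or counts")
        tab = pd.crosstab(records["outcome"], records["gender"])
        counts = tab.reindex(index=list(OUTCOMES), columns=["M", "F"]).to_numpy()
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or counts.min() < 0:
        raise ValueError("counts must be a non-negative 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=correction)
    return GroupComparison(
        parameter="gender_ratio",
        mean_sd={g: f"{int(c[0])} : {int(c[1])}" for g, c in zip(OUTCOMES, counts)},
        n={g: int(c.sum()) for g, c in zip(OUTCOMES, counts)},
        test_used="chi2", statistic=float(chi2), p_value=float(p),
    )


def cohort_table(records: pd.DataFrame, parameters: list[str],
                 test_policy: str = "auto", include_gender: bool = None) -> pd.DataFrame:
    """One comparison row per parameter, in input order (CSV-ready).

    The gender row is appended automatically when a 'gender' column is
    present (or forced/suppressed via `include_gender`).
    """
    if not parameters:
        raise ValueError("at least one parameter required")
    rows = [compare_groups(records, p, test_policy=test_policy).formatted()
            for p in parameters]
    if include_gender is None:
        include_gender = "gender" in records.columns
    if include_gender:
        rows.append(compare_gender(records).formatted())
    return pd.DataFrame(rows)
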