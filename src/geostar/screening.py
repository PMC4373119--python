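"""Bivariate screening: mortality cross-tabulations with chi-square tests.

The screening stage cross-tabulates the death indicator against each
categorical factor, reports per-level death/survival counts with row
percentages, and tests independence with Pearson's chi-square (no
continuity correction).  Screening flags factors at the 5% level but never
drops them — covariate selection for the model stage is user-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

SIGNIFICANCE_LEVEL = 0.05


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (1.005 -> 1.01, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ContingencyTable:
    """Counts of died/alive by factor level with row percentages."""

    factor: str
    levels: list[str]
    died: np.ndarray
    alive: np.ndarray

    def __post_init__(self) -> None:
        self.died = np.asarray(self.died, dtype=float)
        self.alive = np.asarray(self.alive, dtype=float)
        if not (len(self.levels) == len(self.died) == len(self.alive)):
            raise ValueError("levels/died/alive lengths differ")
        if len(self.levels) < 2:
            raise ValueError(
                f"factor {self.factor!r} has a single observed level; "
                "chi-square test undefined"
            )

    @property
    def row_totals(self) -> np.ndarray:
        return self.died + self.alive

    def death_percentages(self, ndigits: int = 2) -> np.ndarray:
        """Row percentage died, rounded half-up to ``ndigits`` decimals."""
        pct = 100.0 * self.died / self.row_totals
        return np.array([round_half_up(p, ndigits) for p in pct])

    def counts(self) -> np.ndarray:
        """levels × 2 matrix of (died, alive) counts."""
        return np.column_stack([self.died, self.alive])


def crosstab(table, factor: str) -> ContingencyTable:
    """Cross-tabulate the outcome against one factor of an ObservationTable."""
    if factor not in table.categorical.columns:
        raise ValueError(f"factor {factor!r} not in the observation table")
    values = table.categorical[factor].astype(str).to_numpy()
    levels = sorted(np.unique(values).tolist())
    died = np.array([np.sum((values == lv) & (table.outcome == 1))
                     for lv in levels], dtype=float)
    alive = np.array([np.sum((values == lv) & (table.outcome == 0))
                      for lv in levels], dtype=float)
    return ContingencyTable(factor=factor, levels=levels, died=died, alive=alive)


def chi_square_test(ct: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a levels × 2 table.

    Returns (statistic, df, p) with df = levels − 1 and p from the
    chi-square upper tail.  Zero expected counts make the statistic
    undefined and raise with advice to merge levels.
    """
    observed = ct.counts()
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if (expected <= 0).any():
        raise ValueError(
            f"zero expected count in factor {ct.factor!r}; merge sparse levels"
        )
    res = stats.chi2_contingency(observed, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def screening_report(table, factors: list[str]) -> "pd.DataFrame":
    """One screening block per factor: counts, percentages, chi-square."""
    import pandas as pd

    rows = []
    for factor in factors:
        ct = crosstab(table, factor)
        stat, df, p = chi_square_test(ct)
        pct = ct.death_percentages()
        for j, level in enumerate(ct.levels):
            rows.append({
                "factor": factor,
                "level": level,
                "died": int(ct.died[j]),
                "alive": int(ct.alive[j]),
                "pct_died": pct[j],
                "chi2": round_half_up(stat, 3) if j == 0 else np.nan,
                "df": df if j == 0 else np.nan,
                "p_value": p if j == 0 else np.nan,
                "significant_5pct": (p < SIGNIFICANCE_LEVEL) if j == 0 else None,
            })
    return pd.DataFrame(rows)
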