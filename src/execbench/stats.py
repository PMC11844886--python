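"""Statistical evaluation of the executability benchmark.

Per complexity level, a chi-square test of independence asks whether the
split of executable vs non-executable trials differs across prompting
strategies; the per-level p-values are then Benjamini–Hochberg adjusted
(the family is the set of complexity levels) and labelled with the usual
significance stars.  Full precision is carried throughout; rounding happens
only at display, to three significant figures with halves away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .bench import TrialRecord


class DegenerateTableError(ValueError):
    """A contingency table with a zero row or column total."""


@dataclass(frozen=True)
class ContingencyTable:
    """Strategies x {executable, not_executable} count matrix."""

    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    col_labels: tuple[str, str] = ("executable", "not_executable")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if arr.shape[0] != len(self.row_labels):
            raise ValueError("row_labels length does not match counts")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "BH"


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("x must be non-negative")
    return float(sps.chi2.sf(x, df))


def chisq_independence(
    table: ContingencyTable, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default (the benchmark tables are
    strategies x 2 with df > 1, where the correction does not apply); a flag
    enables Yates' correction for 2x2 inputs.
    """
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "zero row or column total gives expected counts of 0"
        )
    statistic, p, df, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    return ChiSquareResult(float(statistic), int(df), float(p))


def bh_adjust(raw_p: Sequence[float]) -> AdjustedPValues:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise ValueError("raw_p must be non-empty")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return AdjustedPValues(tuple(p.tolist()), tuple(float(a) for a in adjusted))


def stars(p: float) -> str:
    """Significance label: *** <0.001, ** <0.01, * <0.05, else ns."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures, halves away from zero.

    Plain float rounding is banker's and would turn 3.525e-3 into 3.52e-3;
    the published tables round halves up.
    """
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    exponent = d.adjusted()  # position of most significant digit
    quantum = Decimal(1).scaleb(exponent - digits + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def executability_tables(
    records: Sequence[TrialRecord],
) -> dict[int, ContingencyTable]:
    """Per-complexity strategies x {executable, not} contingency tables."""
    usable = [r for r in records if not r.infrastructure_error]
    tables: dict[int, ContingencyTable] = {}
    for complexity in sorted({r.complexity for r in usable}):
        group = [r for r in usable if r.complexity == complexity]
        strategies = sorted({r.strategy for r in group})
        counts = []
        for s in strategies:
            n_exec = sum(1 for r in group if r.strategy == s and r.executable)
            n_not = sum(1 for r in group if r.strategy == s and not r.executable)
            counts.append((n_exec, n_not))
        tables[complexity] = ContingencyTable(tuple(strategies), tuple(counts))
    return tables


def strategy_comparison_table(
    records: Sequence[TrialRecord], skip_degenerate: bool = True
) -> pd.DataFrame:
    """The headline statistics table: one row per complexity level with the
    chi-square statistic, raw and BH-adjusted p-value, and significance.

    Adjustment is applied across the complexity levels present.  The
    ``statistic``, ``p_value`` and ``adjusted_p`` columns carry full
    precision; ``*_display`` columns hold the 3-significant-figure rendering.
    A level where the test is undefined (every trial in one outcome column)
    is dropped when ``skip_degenerate`` is set, else raises.
    """
    tables = executability_tables(records)
    complexities, results = [], []
    for c, table in tables.items():
        try:
            result = chisq_independence(table)
        except DegenerateTableError:
            if skip_degenerate:
                continue
            raise
        complexities.append(c)
        results.append(result)
    if not results:
        raise DegenerateTableError("no complexity level admits the test")
    adjusted = bh_adjust([r.p_value for r in results]).adjusted
    return pd.DataFrame(
        {
            "complexity": complexities,
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": list(adjusted),
            "statistic_display": [round_sig(r.statistic) for r in results],
            "p_display": [round_sig(r.p_value) for r in results],
            "adjusted_p_display": [round_sig(a) for a in adjusted],
            "significance": [stars(a) for a in adjusted],
        }
    )


def write_comparison_csv(records: Sequence[TrialRecord], path: str | Path) -> Path:
    """Write the per-complexity comparison table as CSV."""
    frame = strategy_comparison_table(records)
    out = frame[
        ["complexity", "statistic_display", "p_display", "adjusted_p_display", "significance"]
    ].rename(
        columns={
            "statistic_display": "chi_square_statistic",
            "p_display": "p_value",
            "adjusted_p_display": "adjusted_p_value",
        }
    )
    path = Path(path)
    out.to_csv(path, index=False)
    return path
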