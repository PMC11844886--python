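"""Chi-square / BH statistics layer, checked against independent oracles:
the even-df closed-form survival series, a brute-force expected-count loop,
and a hand-written step-up BH implementation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from execbench.bench import TrialRecord
from execbench.stats import (
    ContingencyTable,
    DegenerateTableError,
    bh_adjust,
    chi2_sf,
    chisq_independence,
    executability_tables,
    round_sig,
    stars,
    strategy_comparison_table,
)

# Published per-complexity test results for the five-strategy benchmark:
# (raw p, printed adjusted p, significance), complexities 1..5.
TABLE_ROWS = [
    (2.82e-3, 3.53e-3, "**"),
    (1.33e-3, 2.22e-3, "**"),
    (1.50e-9, 7.51e-9, "***"),
    (4.58e-4, 1.14e-3, "**"),
    (6.33e-2, 6.33e-2, "ns"),
]


def sf_even_df_series(x: float, df: int) -> float:
    """Closed-form chi-square upper tail for even df:
    exp(-x/2) * sum_{k<df/2} (x/2)^k / k!."""
    assert df % 2 == 0
    half = x / 2.0
    return math.exp(-half) * sum(half**k / math.factorial(k) for k in range(df // 2))


def brute_force_chisq(counts: np.ndarray) -> tuple[float, int]:
    """Direct sum of (observed-expected)^2/expected over all cells."""
    total = counts.sum()
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = rows[i] * cols[j] / total
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat, (counts.shape[0] - 1) * (counts.shape[1] - 1)


def step_up_bh(p: list[float]) -> list[float]:
    """Reference BH: sort, scale by m/rank, enforce monotonicity from the
    bottom, cap at 1, report in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


class TestChi2Sf:
    def test_zero_statistic_gives_one(self):
        assert chi2_sf(0.0, 1) == pytest.approx(1.0)
        assert chi2_sf(0.0, 7) == pytest.approx(1.0)

    def test_df2_closed_form(self):
        assert chi2_sf(4.0, 2) == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_df4_series_value(self):
        # exp(-2) * (1 + 2) for x = 4, df = 4
        assert chi2_sf(4.0, 4) == pytest.approx(0.4060058497098381, abs=1e-9)

    @pytest.mark.parametrize("df", [2, 4, 6, 8])
    def test_matches_even_df_series(self, df):
        for x in np.linspace(0.0, 40.0, 81):
            assert chi2_sf(float(x), df) == pytest.approx(
                sf_even_df_series(float(x), df), abs=1e-12
            )

    def test_strictly_decreasing_in_x(self):
        values = [chi2_sf(x, 4) for x in np.linspace(0, 30, 61)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)
        with pytest.raises(ValueError):
            chi2_sf(-0.5, 2)


class TestChisqIndependence:
    def test_proportional_rows_give_zero_statistic(self):
        table = ContingencyTable(("a", "b"), ((10, 10), (20, 20)))
        result = chisq_independence(table)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # n(ad - bc)^2 / (r1 r2 c1 c2) = 60*(100-400)^2/(30*30*30*30)
        table = ContingencyTable(("a", "b"), ((10, 20), (20, 10)))
        result = chisq_independence(table)
        assert result.statistic == pytest.approx(60 * 300**2 / 30**4, abs=1e-10)
        assert result.df == 1

    def test_df_for_5x2(self):
        counts = tuple((i + 1, 2 * i + 1) for i in range(5))
        table = ContingencyTable(tuple("abcde"), counts)
        assert chisq_independence(table).df == 4

    def test_degenerate_table_rejected(self):
        table = ContingencyTable(("a", "b"), ((5, 0), (3, 0)))
        with pytest.raises(DegenerateTableError):
            chisq_independence(table)

    def test_matches_brute_force_on_random_tables(self):
        """1,000 random <=5x2 tables agree with the direct loop to 1e-10."""
        rng = np.random.default_rng(20240901)
        checked = 0
        while checked < 1000:
            n_rows = int(rng.integers(2, 6))
            counts = rng.integers(0, 51, size=(n_rows, 2))
            if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
                continue
            table = ContingencyTable(
                tuple(f"s{i}" for i in range(n_rows)),
                tuple(tuple(int(v) for v in row) for row in counts),
            )
            result = chisq_independence(table)
            stat, df = brute_force_chisq(counts.astype(float))
            assert result.statistic == pytest.approx(stat, abs=1e-10)
            assert result.df == df
            assert result.p_value == pytest.approx(chi2_sf(stat, df), abs=1e-12)
            checked += 1

    def test_table_shape_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ((1, 2),))
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), ((0, 0), (0, 0)))


class TestBhAdjust:
    def test_published_raw_column_reproduced(self):
        adjusted = bh_adjust([row[0] for row in TABLE_ROWS]).adjusted
        assert adjusted == pytest.approx(
            [3.525e-3, 2.2166666666e-3, 7.50e-9, 1.145e-3, 6.33e-2], rel=1e-9
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).adjusted == pytest.approx([0.03])

    def test_all_equal_p_unchanged(self):
        assert bh_adjust([0.2] * 4).adjusted == pytest.approx([0.2] * 4)

    def test_adjusted_dominates_raw_and_capped_at_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            raw = rng.uniform(1e-8, 1.0, size=rng.integers(1, 10)).tolist()
            adjusted = bh_adjust(raw).adjusted
            assert all(a >= r - 1e-15 for a, r in zip(adjusted, raw))
            assert all(a <= 1.0 for a in adjusted)

    def test_matches_step_up_reference_on_random_vectors(self):
        """1,000 random vectors agree with the hand-written step-up rule."""
        rng = np.random.default_rng(20240902)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            raw = rng.uniform(1e-10, 1.0, size=m).tolist()
            assert bh_adjust(raw).adjusted == pytest.approx(
                step_up_bh(raw), rel=1e-12
            )

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.001, 0.9, size=8).tolist()
        adjusted = bh_adjust(raw).adjusted
        perm = rng.permutation(8)
        permuted_adjusted = bh_adjust([raw[i] for i in perm]).adjusted
        assert permuted_adjusted == pytest.approx([adjusted[i] for i in perm])

    def test_rejection_set_matches_classical_step_up_rule(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = int(rng.integers(1, 10))
            raw = rng.uniform(1e-6, 1.0, size=m)
            alpha = float(rng.uniform(0.01, 0.2))
            adjusted = np.array(bh_adjust(raw.tolist()).adjusted)
            # classical rule: reject the k smallest where k is the largest
            # rank with p_(k) <= k/m * alpha
            order = np.argsort(raw)
            ranks = np.arange(1, m + 1)
            passing = np.nonzero(raw[order] <= ranks / m * alpha)[0]
            classical = set(order[: passing.max() + 1]) if passing.size else set()
            assert set(np.nonzero(adjusted <= alpha)[0]) == classical

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([])


class TestStarsAndRounding:
    @pytest.mark.parametrize(
        "p,label",
        [(6.33e-2, "ns"), (2.22e-3, "**"), (7.51e-9, "***"), (0.04, "*"),
         (0.05, "ns"), (0.01, "*"), (0.001, "**"), (1.0, "ns")],
    )
    def test_thresholds(self, p, label):
        assert stars(p) == label

    def test_full_significance_column(self):
        assert [stars(adj) for _, adj, _ in TABLE_ROWS] == [
            sig for _, _, sig in TABLE_ROWS
        ]

    def test_round_sig_half_away_from_zero(self):
        assert round_sig(3.525e-3) == pytest.approx(3.53e-3)
        assert round_sig(16.16) == pytest.approx(16.2)
        assert round_sig(0.0) == 0.0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            stars(0.0)


class TestComparisonPipeline:
    def _records(self):
        rng = np.random.default_rng(5)
        records = []
        rates = {"simple": 0.4, "selfCorrect": 0.8}
        for strategy, rate in rates.items():
            for complexity in (1, 2):
                for i in range(40):
                    records.append(
                        TrialRecord(
                            task_id=f"t{i % 4}", complexity=complexity,
                            strategy=strategy, model_name="m", cycle=i // 4 + 1,
                            response_chars=500, executable=bool(rng.random() < rate),
                            attempts_used=3 if strategy == "selfCorrect" else 1,
                        )
                    )
        return records

    def test_tables_have_strategy_rows_and_outcome_columns(self):
        tables = executability_tables(self._records())
        assert set(tables) == {1, 2}
        table = tables[1]
        assert table.row_labels == ("selfCorrect", "simple")
        assert all(sum(row) == 40 for row in table.counts)

    def test_comparison_table_is_coherent(self):
        frame = strategy_comparison_table(self._records())
        assert list(frame["complexity"]) == [1, 2]
        assert (frame["df"] == 1).all()
        assert (frame["adjusted_p"] >= frame["p_value"] - 1e-15).all()
        assert [stars(p) for p in frame["adjusted_p"]] == list(frame["significance"])
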