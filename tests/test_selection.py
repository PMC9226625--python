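"""Variable-selection strategies against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from wheatn.indices import PREDICTORS
from wheatn.modeling import CVSpec
from wheatn.selection import (
    DEFAULT_GROUPS,
    VariableGroup,
    compare_strategies,
    pcc_select,
    virrfr_rank,
    virrfr_select,
)
from conftest import TINY_GRID


def two_step_oracle(table, target, group, threshold=0.5):
    """Independent re-statement of the two-step rule via plain correlations."""
    r = lambda a, b: np.corrcoef(table[a], table[b])[0, 1]
    first = max(group.members, key=lambda m: abs(r(m, target)))
    candidates = [
        m for m in group.members
        if m != first and abs(r(m, first)) < threshold
    ]
    second = max(candidates, key=lambda m: abs(r(m, target))) if candidates else None
    return first, second


def planted_group_table(rng, n=200):
    """Target driven by one variable per group, with a decoy collinear twin."""
    t = rng.normal(size=n)
    df = pd.DataFrame({"y": t, "NDRE": t * 0.5 + rng.normal(size=n)})
    # A: strong and clean; B: near-duplicate of A (should be blocked);
    # C: weaker but independent (should be the second pick)
    df["A"] = 0.9 * t + 0.45 * rng.normal(size=n)
    df["B"] = df["A"] + 0.15 * rng.normal(size=n)
    df["C"] = 0.35 * t + rng.normal(size=n)
    return df


class TestPCC:
    def test_blocks_collinear_twin_and_keeps_independent_signal(self):
        rng = np.random.default_rng(0)
        df = planted_group_table(rng)
        group = VariableGroup("g", ("A", "B", "C"))
        result = pcc_select(df, "y", [group])
        assert result.selected == ["NDRE", "A", "C"]
        first, second = two_step_oracle(df, "y", group)
        assert result.selected[1:] == [first, second]

    def test_singleton_group_is_its_own_pick(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(size=50), "NDRE": rng.normal(size=50),
                           "X": rng.normal(size=50)})
        result = pcc_select(df, "y", [VariableGroup("g", ("X",))])
        assert result.selected == ["NDRE", "X"]

    def test_group_of_mutually_correlated_variables_yields_one_pick(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=300)
        base = rng.normal(size=300)
        df = pd.DataFrame({
            "y": t,
            "NDRE": rng.normal(size=300),
            "P": 0.8 * t + 0.3 * base + 0.2 * rng.normal(size=300),
        })
        df["Q"] = df["P"] + 0.1 * rng.normal(size=300)
        df["R"] = 0.95 * df["P"] + 0.15 * rng.normal(size=300)
        result = pcc_select(df, "y", [VariableGroup("g", ("P", "Q", "R"))])
        assert len(result.selected) == 2  # NDRE + single group winner

    def test_matches_oracle_on_random_structures(self):
        """Exhaustive-rule agreement on random correlation structures."""
        rng = np.random.default_rng(7)
        group = VariableGroup("g", ("V1", "V2", "V3", "V4"))
        for _ in range(30):
            n = 80
            latent = rng.normal(size=n)
            df = pd.DataFrame({"y": latent + 0.5 * rng.normal(size=n),
                               "NDRE": rng.normal(size=n)})
            mix = rng.uniform(-1, 1, size=4)
            share = rng.uniform(0, 1, size=4)
            for j, m in enumerate(group.members):
                df[m] = (
                    mix[j] * latent * share[j]
                    + (1 - share[j]) * rng.normal(size=n)
                )
            result = pcc_select(df, "y", [group])
            first, second = two_step_oracle(df, "y", group)
            expected = ["NDRE", first] + ([second] if second else [])
            assert result.selected == expected

    def test_deterministic_given_table(self, feature_table):
        a = pcc_select(feature_table, "AGB")
        b = pcc_select(feature_table, "AGB")
        assert a.selected == b.selected

    def test_group_picks_respect_threshold(self, feature_table):
        result = pcc_select(feature_table, "PNU")
        for group in DEFAULT_GROUPS:
            picks = [v for v in result.selected if v in group.members]
            assert 1 <= len(picks) <= 2
            if len(picks) == 2:
                r = np.corrcoef(feature_table[picks[0]], feature_table[picks[1]])[0, 1]
                assert abs(r) < 0.5

    def test_constant_column_treated_as_zero_correlation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(size=30), "NDRE": rng.normal(size=30),
                           "K": np.ones(30), "X": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            result = pcc_select(df, "y", [VariableGroup("g", ("K", "X"))])
        assert result.selected[1] == "X"

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "NDRE": [0.1, 0.2], "X": [1.0, 0.0]})
        with pytest.raises(ValueError):
            pcc_select(df, "y", [VariableGroup("g", ("X",))])


def noise_plus_signal_table(rng, n=150, n_noise=12):
    x1 = rng.normal(size=n)
    df = pd.DataFrame({"NDRE": x1 + 0.05 * rng.normal(size=n)})
    for j in range(n_noise):
        df[f"Z{j}"] = rng.normal(size=n)
    df["y"] = np.sin(x1) * 2 + x1 + 0.05 * rng.normal(size=n)
    return df


class TestVIRRFR:
    def test_informative_predictor_ranked_first(self):
        rng = np.random.default_rng(5)
        df = noise_plus_signal_table(rng)
        preds = [c for c in df.columns if c != "y"]
        ranking = virrfr_rank(df, "y", TINY_GRID, seed=1, predictors=preds)
        assert ranking[0] == "NDRE"

    def test_prefix_curve_covers_all_candidates(self, feature_table):
        sub = feature_table.iloc[:120]
        result = virrfr_select(sub, "NNI", CVSpec(folds=3, seed=0), TINY_GRID, 0)
        assert len(result.diagnostics) == len(PREDICTORS)
        assert "NDRE" in result.selected
        # selected set is a prefix of the ranking
        ranking = list(result.diagnostics["variable_added"])
        assert result.selected == ranking[: len(result.selected)]

    def test_best_prefix_no_worse_than_shortest_eligible(self, feature_table):
        """The chosen prefix scores at least as well as the shortest prefix
        containing the fixed NDRE predictor (equal to the 1-variable prefix
        whenever NDRE tops the importance ranking)."""
        sub = feature_table.iloc[:120]
        result = virrfr_select(sub, "PNU", CVSpec(folds=3, seed=0), TINY_GRID, 0)
        curve = result.diagnostics
        ranking = list(curve["variable_added"])
        min_k = ranking.index("NDRE") + 1
        best = curve[curve.k == len(result.selected)].iloc[0].cv_r2
        assert best >= curve[curve.k == min_k].iloc[0].cv_r2 - 1e-12
        if min_k == 1:
            assert best >= curve[curve.k == 1].iloc[0].cv_r2 - 1e-12

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(6)
        df = noise_plus_signal_table(rng, n=90, n_noise=4)
        a = virrfr_select(df, "y", CVSpec(folds=3, seed=3), TINY_GRID, 3,
                          predictors=[c for c in df.columns if c != "y"])
        b = virrfr_select(df, "y", CVSpec(folds=3, seed=3), TINY_GRID, 3,
                          predictors=[c for c in df.columns if c != "y"])
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.diagnostics, b.diagnostics)

    def test_duplicated_best_predictor_resolved_deterministically(self):
        rng = np.random.default_rng(8)
        df = noise_plus_signal_table(rng, n=120, n_noise=3)
        df["NDRE2"] = df["NDRE"]
        preds = [c for c in df.columns if c != "y"]
        a = virrfr_rank(df, "y", TINY_GRID, seed=2, predictors=preds)
        b = virrfr_rank(df, "y", TINY_GRID, seed=2, predictors=preds)
        assert a == b
        assert set(a[:2]) == {"NDRE", "NDRE2"}

    def test_degenerate_target_rejected(self):
        df = pd.DataFrame({"y": np.ones(40), "NDRE": np.arange(40.0),
                           "X": np.arange(40.0) ** 2})
        with pytest.raises(ValueError):
            virrfr_select(df, "y", CVSpec(folds=2, seed=0), TINY_GRID, 0,
                          predictors=["NDRE", "X"])


class TestCompareStrategies:
    def test_identical_entries_normalize_to_one(self):
        m = {"r2": 0.8, "rmse": 0.5, "re": 20.0, "n_vars": 6}
        rel = compare_strategies({"PCC": m, "VIRRFR": m, "full": m})
        assert np.allclose(rel.to_numpy(), 1.0)

    def test_variable_count_normalization(self):
        base = {"r2": 0.8, "rmse": 0.5, "re": 20.0}
        rel = compare_strategies({
            "PCC": {**base, "n_vars": 7},
            "VIRRFR": {**base, "n_vars": 10},
            "full": {**base, "n_vars": 13},
        })
        assert rel["RN"].to_list() == pytest.approx(
            [7 / 13, 10 / 13, 1.0], abs=1e-3
        )

    def test_maximum_entry_is_fixed_point(self):
        rel = compare_strategies({
            "PCC": {"r2": 0.9, "rmse": 0.4, "re": 15.0, "n_vars": 6},
            "full": {"r2": 0.85, "rmse": 0.5, "re": 18.0, "n_vars": 13},
        })
        assert rel.loc["PCC", "RR2"] == 1.0
        assert rel.loc["full", "RRMSE"] == 1.0
        assert ((rel > 0) & (rel <= 1)).all().all()
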