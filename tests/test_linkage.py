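"""Interval mapping: RI recombination operator, dosage grid geometry,
Haley-Knott scan vs a brute-force OLS oracle, permutation calibration."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bxdeqtl import (
    GenotypeMatrix,
    InvalidParameterError,
    MarkerMap,
    ValidationError,
    empirical_p,
    expected_dosage,
    hk_scan,
    lrs_lod_convert,
    permutation_null,
    ri_recombination_fraction,
    simulate_ri_genotypes,
)
from bxdeqtl.linkage import NullDistribution

from _oracles import ols_lrs, ri_pedigree_recombinant_fraction


class TestRiRecombinationFraction:
    def test_zero_distance(self):
        assert ri_recombination_fraction(0.0) == 0.0

    def test_infinite_distance_limit(self):
        assert abs(ri_recombination_fraction(1e6) - 0.5) < 1e-12

    def test_r_point_one_gives_quarter(self):
        d = -50 * np.log(1 - 2 * 0.1)  # inverse Haldane at r = 0.1
        assert abs(ri_recombination_fraction(d) - 0.25) < 1e-12

    def test_negative_distance(self):
        with pytest.raises(InvalidParameterError):
            ri_recombination_fraction(-1.0)

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.3])
    def test_matches_sib_mating_pedigree_oracle(self, r):
        """The map-expansion formula agrees with forward simulation of
        sib-mated pedigrees to fixation, within Monte-Carlo error."""
        d = -50 * np.log(1 - 2 * r)
        analytic = ri_recombination_fraction(d)
        n_lines = 4000
        simulated = ri_pedigree_recombinant_fraction(r, n_lines, seed=int(r * 1000))
        se = np.sqrt(analytic * (1 - analytic) / n_lines)
        assert abs(simulated - analytic) < 4 * se


class TestLrsLodConvert:
    def test_values_and_round_trip(self):
        assert lrs_lod_convert(0.0) == 0.0
        assert abs(lrs_lod_convert(50.0, "to_lrs") - 230.2585093) < 1e-6
        x = 17.3
        assert abs(lrs_lod_convert(lrs_lod_convert(x, "to_lod"), "to_lrs") - x) < 1e-12

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            lrs_lod_convert(-1.0)


def _toy_genotypes(calls: dict[str, list[float]], cm: list[float]) -> GenotypeMatrix:
    mm = MarkerMap(pd.DataFrame({
        "marker_id": list(calls),
        "chrom": "1",
        "cm": cm,
        "mb": [c * 2.0 for c in cm],
    }))
    strains = [f"S{i}" for i in range(len(next(iter(calls.values()))))]
    return GenotypeMatrix(pd.DataFrame(calls, index=strains), mm)


class TestExpectedDosage:
    def test_grid_geometry(self, small_genotypes, small_grid):
        pos = small_grid.positions
        mm = small_genotypes.map.table
        # all marker positions present, step never exceeds 1 cM
        for chrom, sub in mm.groupby("chrom"):
            gsub = pos[pos["chrom"] == chrom]
            assert set(np.round(sub["cm"], 9)).issubset(set(np.round(gsub["cm"], 9)))
            assert np.diff(gsub["cm"]).max() <= 1.0 + 1e-9
            assert (np.diff(gsub["mb"]) > 0).all()

    def test_marker_positions_carry_observed_codes(self, small_genotypes, small_grid):
        pos = small_grid.positions
        markers = pos.index[pos["is_marker"]]
        mm = small_genotypes.map.table
        for k in markers[:50]:
            row = pos.loc[k]
            mid = mm[(mm["chrom"] == row["chrom"]) & (np.isclose(mm["cm"], row["cm"]))]["marker_id"].iloc[0]
            np.testing.assert_array_equal(
                small_grid.dosage[:, k], small_genotypes.calls[mid].to_numpy()
            )

    def test_midpoint_between_opposite_flanks_is_zero(self):
        g = _toy_genotypes({"a": [-1.0, 1.0], "b": [1.0, -1.0]}, [0.0, 10.0])
        grid = expected_dosage(g, step_cm=5.0)
        mid = grid.positions[np.isclose(grid.positions["cm"], 5.0)].index[0]
        np.testing.assert_allclose(grid.dosage[:, mid], [0.0, 0.0], atol=1e-12)

    def test_midpoint_between_matching_flanks_positive_and_tightening(self):
        wide = _toy_genotypes({"a": [1.0], "b": [1.0]}, [0.0, 20.0])
        tight = _toy_genotypes({"a": [1.0], "b": [1.0]}, [0.0, 4.0])
        # reuse one strain with both flanks D
        wide = _toy_genotypes({"a": [1.0, 1.0], "b": [1.0, 1.0]}, [0.0, 20.0])
        tight = _toy_genotypes({"a": [1.0, 1.0], "b": [1.0, 1.0]}, [0.0, 4.0])
        dw = expected_dosage(wide, step_cm=10.0)
        dt = expected_dosage(tight, step_cm=2.0)
        mid_w = dw.positions[np.isclose(dw.positions["cm"], 10.0)].index[0]
        mid_t = dt.positions[np.isclose(dt.positions["cm"], 2.0)].index[0]
        assert 0 < dw.dosage[0, mid_w] < dt.dosage[0, mid_t] <= 1

    def test_missing_genotype_uses_nearest_informative_flank(self):
        g = _toy_genotypes(
            {"a": [1.0, -1.0], "b": [np.nan, -1.0], "c": [1.0, 1.0]},
            [0.0, 5.0, 10.0],
        )
        grid = expected_dosage(g, step_cm=5.0)
        # strain 0 at marker b (missing): conditioned on a=D and c=D
        b_pos = grid.positions[np.isclose(grid.positions["cm"], 5.0)].index[0]
        assert grid.dosage[0, b_pos] > 0.5
        # strain 1: a missing, b=-1, c=-1 -> strongly B everywhere
        assert grid.dosage[1, b_pos] < -0.5

    def test_bad_step(self, small_genotypes):
        with pytest.raises(InvalidParameterError):
            expected_dosage(small_genotypes, step_cm=0.0)


class TestHkScan:
    def test_matches_brute_force_ols_at_markers(self, small_genotypes, small_grid):
        rng = np.random.default_rng(5)
        pos = small_grid.positions
        marker_cols = np.flatnonzero(pos["is_marker"].to_numpy())
        for _ in range(20):
            y = rng.normal(size=small_genotypes.n_strains)
            trait = pd.Series(y, index=small_genotypes.strains)
            res = hk_scan(trait, small_grid)
            for k in marker_cols[::5]:
                lrs, slope = ols_lrs(y, small_grid.dosage[:, k])
                assert abs(res.lrs[k] - lrs) < 1e-9
                assert abs(res.additive[k] - slope) < 1e-9

    def test_perfect_fit_saturates_at_the_marker(self, small_genotypes, small_grid):
        mid = small_genotypes.map.marker_ids[3]
        trait = small_genotypes.calls[mid].astype(float)
        res = hk_scan(trait, small_grid)
        peak = res.peak()
        assert peak["saturated"]
        mrow = small_genotypes.map.table.set_index("marker_id").loc[mid]
        assert peak["chrom"] == mrow["chrom"] and abs(peak["cm"] - mrow["cm"]) < 1e-9

    def test_affine_invariance_of_lrs(self, small_genotypes, small_grid):
        rng = np.random.default_rng(6)
        y = rng.normal(size=small_genotypes.n_strains)
        a = hk_scan(pd.Series(y, index=small_genotypes.strains), small_grid)
        b = hk_scan(pd.Series(3.0 * y - 7.0, index=small_genotypes.strains), small_grid)
        np.testing.assert_allclose(a.lrs, b.lrs, atol=1e-9)

    def test_constant_trait_rejected(self, small_genotypes, small_grid):
        trait = pd.Series(1.0, index=small_genotypes.strains)
        with pytest.raises(ValidationError, match="constant"):
            hk_scan(trait, small_grid)

    def test_too_few_strains_rejected(self, small_grid):
        trait = pd.Series([1.0, 2.0, 3.0], index=small_grid.strains[:3])
        with pytest.raises(ValidationError):
            hk_scan(trait, small_grid)

    def test_pairwise_deletion_matches_subset_scan(self):
        mm = MarkerMap(pd.DataFrame({
            "marker_id": ["a", "b"], "chrom": ["1", "2"],
            "cm": [0.0, 0.0], "mb": [0.0, 0.0],
        }))
        # marker b missing for the last two strains
        rng = np.random.default_rng(8)
        n = 12
        calls = pd.DataFrame({
            "a": rng.choice([-1.0, 1.0], n),
            "b": np.concatenate([rng.choice([-1.0, 1.0], n - 2), [np.nan, np.nan]]),
        }, index=[f"S{i}" for i in range(n)])
        g = GenotypeMatrix(calls, mm)
        grid = expected_dosage(g, step_cm=1.0)
        y = rng.normal(size=n)
        res = hk_scan(pd.Series(y, index=g.strains), grid)
        kb = grid.positions[grid.positions["chrom"] == "2"].index[0]
        m = ~np.isnan(calls["b"].to_numpy())
        lrs, slope = ols_lrs(y[m], calls["b"].to_numpy()[m])
        assert abs(res.lrs[kb] - lrs) < 1e-9
        assert abs(res.additive[kb] - slope) < 1e-9


class TestPermutationNull:
    def test_deterministic_and_monotone_thresholds(self, small_genotypes, small_grid):
        rng = np.random.default_rng(9)
        trait = pd.Series(rng.normal(size=small_genotypes.n_strains),
                          index=small_genotypes.strains)
        a = permutation_null(trait, small_grid, 200, seed=4)
        b = permutation_null(trait, small_grid, 200, seed=4)
        np.testing.assert_array_equal(a.max_lrs, b.max_lrs)
        assert a.threshold(0.01) >= a.threshold(0.05) >= a.threshold(0.10)
        assert (a.max_lrs >= 0).all()

    def test_minimum_permutations_enforced(self, small_genotypes, small_grid):
        trait = pd.Series(np.arange(small_genotypes.n_strains, dtype=float),
                          index=small_genotypes.strains)
        with pytest.raises(InvalidParameterError):
            permutation_null(trait, small_grid, 99, seed=0)


class TestEmpiricalP:
    def test_plus_one_rule_cases(self):
        null = NullDistribution(999, np.linspace(1, 10, 999), seed=0)
        assert empirical_p(1e9, null) == pytest.approx(1 / 1000)
        assert empirical_p(-1.0, null) == pytest.approx(1.0)
        med = float(np.median(null.max_lrs))
        assert abs(empirical_p(med, null) - 0.5) < 0.01

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=10, max_size=10),
           st.floats(0, 100))
    def test_matches_enumeration(self, vals, obs):
        null = NullDistribution(10, np.array(vals), seed=0)
        brute = (sum(v >= obs for v in vals) + 1) / 11
        assert empirical_p(obs, null) == pytest.approx(brute)
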