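"""LHS design properties, output measures, PRCC and monotonicity sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drinkdyn.sensitivity import (
    INPUT_NAMES,
    OUTPUT_NAMES,
    SamplingRange,
    default_ranges,
    evaluate_outputs,
    lhs_design,
    monotonicity_sweep,
    prcc,
    prcc_significance,
    run_lhs_prcc,
)


def design_row(**overrides):
    base = {
        "a1": 0.0, "a2": 0.0, "a3": 0.0, "d1": 0.0, "d2": 0.0, "d3": 0.0,
        "A0": 0.0, "A1": 0.0, "D1": 0.0,
    }
    base.update(overrides)
    return base


class TestDefaultRanges:
    def test_published_overrides(self):
        r = default_ranges()
        assert r.bounds["a1"] == (0.001, 1.0015)
        assert r.bounds["d1"] == (0.001, 2.2742)

    def test_floor_applies_to_d2(self):
        r = default_ranges()
        lo, hi = r.bounds["d2"]
        assert lo == 0.001  # 0.4110 - 2*0.2168 < 0 floors at 0.001
        assert hi == pytest.approx(0.4110 + 2 * 0.2168)

    def test_plus_minus_two_sd_for_unconstrained(self):
        r = default_ranges()
        assert r.bounds["a3"] == (
            pytest.approx(-0.4539 - 2 * 0.4475),
            pytest.approx(-0.4539 + 2 * 0.4475),
        )

    def test_ic_ranges_floored(self):
        r = default_ranges()
        lo, hi = r.bounds["A1"]
        assert lo == max(0.001, 4.7297 - 2 * 4.0665)
        assert hi == pytest.approx(4.7297 + 2 * 4.0665)

    def test_degenerate_sd_without_override_flagged(self):
        summary = pd.DataFrame(
            {
                "parameter": ["a1", "a2", "a3", "d1", "d2", "d3"],
                "mean": [0.28, 0.99, -0.45, 0.81, 0.41, -0.06],
                "sd": [0.0, 0.0, 0.4, 0.0, 0.2, 0.3],  # a2 degenerate, no override
            }
        )
        with pytest.raises(ValueError, match="a2"):
            default_ranges(summary)


class TestLhsDesign:
    @pytest.mark.parametrize("n", [2, 17, 100])
    @pytest.mark.parametrize("seed", [0, 5])
    def test_exact_stratification_every_column(self, n, seed):
        r = default_ranges()
        design = lhs_design(r, n_samples=n, seed=seed)
        for name in design.columns:
            lo, hi = r.bounds[name]
            strata = np.floor((design[name] - lo) / (hi - lo) * n).astype(int)
            strata = np.clip(strata, 0, n - 1)
            assert sorted(strata) == list(range(n))

    def test_marginal_uniformity(self):
        r = default_ranges()
        for seed in (1, 2, 3):
            design = lhs_design(r, n_samples=1000, seed=seed)
            lo, hi = r.bounds["d2"]
            unit = (design["d2"] - lo) / (hi - lo)
            assert stats.kstest(unit, "uniform").pvalue > 0.01

    def test_reproducible_under_seed(self):
        r = default_ranges()
        a = lhs_design(r, n_samples=50, seed=4)
        b = lhs_design(r, n_samples=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            lhs_design(default_ranges(), n_samples=1)


class TestOutputMeasures:
    def test_zero_row_gives_zero_outputs(self):
        design = pd.DataFrame([design_row()])
        out = evaluate_outputs(design, horizon=30)
        assert (out.iloc[0] == 0.0).all()

    def test_constant_drinking_closed_form(self):
        c, h = 3.5, 84
        design = pd.DataFrame([design_row(a2=1.0, A0=c, A1=c)])
        out = evaluate_outputs(design, horizon=h)
        assert out.loc[0, "sumA"] == pytest.approx(c * h)
        assert out.loc[0, "maxA"] == pytest.approx(c)

    def test_clipping_keeps_measures_nonnegative(self):
        # strong negative trend coefficient drives the raw path negative
        design = pd.DataFrame([design_row(a3=-5.0, A0=1.0, A1=6.0)])
        out = evaluate_outputs(design, horizon=50)
        assert (out.iloc[0] >= 0.0).all()

    def test_max_bounded_by_sum(self, rng):
        r = default_ranges()
        design = lhs_design(r, n_samples=64, seed=12)
        out = evaluate_outputs(design, horizon=84)
        assert np.all(out["maxA"] <= out["sumA"] + 1e-12)
        assert np.all(out["maxD"] <= out["sumD"] + 1e-12)

    def test_year_horizon_runs(self):
        design = lhs_design(default_ranges(), n_samples=16, seed=0)
        out = evaluate_outputs(design, horizon=365)
        assert len(out) == 16 and np.all(np.isfinite(out))


class TestPrcc:
    def _random_design(self, rng, n=400):
        return pd.DataFrame(
            {name: rng.uniform(0, 1, n) for name in INPUT_NAMES}
        )

    def test_perfect_monotone_dependence(self, rng):
        design = self._random_design(rng)
        outputs = pd.DataFrame({"y": design["d2"].to_numpy()})
        r = prcc(design, outputs)
        assert r.loc["d2", "y"] > 0.99
        assert np.all(r.drop(index="d2")["y"].abs() < 0.2)

    def test_perfect_negative_dependence(self, rng):
        design = self._random_design(rng)
        outputs = pd.DataFrame({"y": -design["a1"].to_numpy()})
        assert prcc(design, outputs).loc["a1", "y"] < -0.99

    def test_independent_input_stays_in_null_band(self):
        n = 400
        inside, values = 0, []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            design = self._random_design(rng, n)
            # output depends on everything except a3
            y = design["d2"] + 0.5 * design["a1"] + rng.normal(0, 0.1, n)
            r = prcc(design, pd.DataFrame({"y": y})).loc["a3", "y"]
            values.append(abs(r))
            inside += abs(r) < 2 / np.sqrt(n)
        assert inside >= 16  # ~2-sigma band holds for nearly all seeds
        assert np.mean(values) < 2 / np.sqrt(n)

    def test_invariant_under_monotone_transform(self, rng):
        design = self._random_design(rng)
        y = design["d1"] ** 2 + design["a2"]
        r1 = prcc(design, pd.DataFrame({"y": y}))
        design2 = design.copy()
        design2["d1"] = np.exp(design2["d1"])  # strictly monotone transform
        r2 = prcc(design2, pd.DataFrame({"y": y}))
        pd.testing.assert_frame_equal(r1, r2)

    def test_constant_column_flagged_nan(self, rng):
        design = self._random_design(rng)
        design["a3"] = 1.0
        r = prcc(design, pd.DataFrame({"y": design["d2"]}))
        assert np.isnan(r.loc["a3", "y"])

    def test_too_few_samples_rejected(self, rng):
        design = self._random_design(rng, n=8)
        with pytest.raises(ValueError):
            prcc(design, pd.DataFrame({"y": np.ones(8)}))


class TestPrccSignificance:
    def test_zero_prcc_gives_p_one(self):
        assert prcc_significance(0.0, 1000, 9) == pytest.approx(1.0)

    def test_monotone_in_magnitude(self):
        ps = [prcc_significance(r, 1000, 9) for r in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_unit_correlation(self):
        assert prcc_significance(1.0, 1000, 9) == 0.0

    def test_null_p_values_roughly_uniform(self):
        n = 300
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            design = pd.DataFrame({name: rng.uniform(0, 1, n) for name in INPUT_NAMES})
            y = design["d2"] + rng.normal(0, 0.5, n)
            r = prcc(design, pd.DataFrame({"y": y})).loc["a3", "y"]
            ps.append(prcc_significance(float(r), n, 9))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_t_reference_close_to_normal_at_large_n(self):
        pn = prcc_significance(0.1, 1000, 9, reference="normal")
        pt = prcc_significance(0.1, 1000, 9, reference="t")
        assert pn == pytest.approx(pt, rel=0.05)


class TestMonotonicitySweep:
    def test_persistence_sweep_increases_total_alcohol(self):
        # pure geometric regime: sumA = A1 * sum(a2^k), strictly increasing
        base = design_row(A0=2.0, A1=2.0)
        curve, verdict = monotonicity_sweep(
            "a2", (0.1, 0.99), base=base, n_grid=15, horizon=40
        )
        assert verdict["sumA"]
        assert np.all(np.diff(curve["sumA"]) > 0)

    def test_ineffective_input_gives_flat_curve(self):
        base = design_row(a2=1.0, A0=3.0, A1=3.0)  # constant-A regime
        curve, verdict = monotonicity_sweep(
            "a3", (-1.0, 1.0), base=base, n_grid=9, horizon=40
        )
        assert np.ptp(curve["sumA"]) == pytest.approx(0.0, abs=1e-9)
        assert verdict["sumA"]

    def test_population_d2_sweep_sensitive_only_in_upper_range(self):
        curve, verdict = monotonicity_sweep("d2", n_grid=41)
        y = curve["sumA"].to_numpy()
        n = len(y)
        lower_half_range = np.ptp(y[: n // 2])
        top_fifth_range = np.ptp(y[-n // 5:])
        assert top_fifth_range > 5 * lower_half_range
        assert verdict["sumA"]

    def test_grid_size_enforced(self):
        with pytest.raises(ValueError):
            monotonicity_sweep("d2", n_grid=2)


class TestEndToEnd:
    def test_run_bundle_shapes_and_bounds(self):
        res = run_lhs_prcc(n_samples=120, horizon=84, seed=3)
        assert res.design.shape == (120, 9)
        assert list(res.outputs.columns) == list(OUTPUT_NAMES)
        finite = res.prcc.to_numpy()
        assert np.all(np.abs(finite[np.isfinite(finite)]) <= 1.0)
        assert res.p_values.shape == res.prcc.shape

    def test_horizon_stability_of_strong_conclusions(self):
        # strong inputs keep their PRCC sign between the study horizon and a
        # one-year horizon
        res84 = run_lhs_prcc(n_samples=300, horizon=84, seed=21)
        res365 = run_lhs_prcc(n_samples=300, horizon=365, seed=21)
        for m in OUTPUT_NAMES:
            strong = res84.prcc[res84.prcc[m].abs() > 0.3].index
            for name in strong:
                assert np.sign(res84.prcc.loc[name, m]) == np.sign(
                    res365.prcc.loc[name, m]
                )
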