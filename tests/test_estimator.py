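"""Residual estimator: identities, conservation, oracle recovery, bias."""

import dataclasses

import numpy as np
import pytest

import physmig as pm
from conftest import small_random_config


class TestNationalAttrition:
    def test_no_attrition_identity(self):
        for x in (0.0, 1.0, 7416.0, 1e8):
            assert pm.estimate_national_attrition(x, x) == 0.0

    def test_negative_result_rejected_in_strict_mode(self):
        with pytest.raises(pm.ValidationError, match="negative"):
            pm.estimate_national_attrition(100.0, 150.0)
        assert pm.estimate_national_attrition(
            100.0, 150.0, allow_negative=True
        ) == -50.0

    def test_negative_licensing_rejected(self):
        with pytest.raises(pm.ValidationError):
            pm.estimate_national_attrition(-1.0, 0.0)


class TestMeanStock:
    def test_two_point_mean(self):
        rec = pm.PrefectureRecord("A", {1994: 100.0, 2014: 300.0}, {})
        assert pm.mean_stock(rec, 1994, 2014) == 200.0

    def test_constant_stock(self):
        rec = pm.PrefectureRecord("A", {y: 42.0 for y in range(2000, 2011, 2)}, {})
        assert pm.mean_stock(rec, 2000, 2010) == 42.0

    def test_biennial_linear_ramp_mean_is_midpoint(self):
        # 11 biennial observations of stock = 100 + 7*(y-1994): the mean of an
        # arithmetic progression is its midpoint value, at y = 2004.
        rec = pm.PrefectureRecord(
            "A", {y: 100.0 + 7.0 * (y - 1994) for y in range(1994, 2015, 2)}, {}
        )
        assert pm.mean_stock(rec, 1994, 2014) == pytest.approx(100.0 + 7.0 * 10)

    def test_window_restricts_observations(self):
        rec = pm.PrefectureRecord("A", {1990: 1.0, 2000: 10.0, 2010: 20.0}, {})
        assert pm.mean_stock(rec, 2000, 2010) == 15.0
        with pytest.raises(pm.ValidationError):
            pm.mean_stock(rec, 2011, 2020)


class TestAllocateAttrition:
    def test_symmetry_and_proportionality(self):
        assert pm.allocate_attrition(100.0, {"A": 1.0, "B": 1.0}) == {
            "A": 50.0, "B": 50.0,
        }
        assert pm.allocate_attrition(100.0, {"A": 3.0, "B": 1.0}) == {
            "A": 75.0, "B": 25.0,
        }

    def test_conservation_over_47_random_stocks(self):
        rng = np.random.default_rng(0)
        stocks = {f"P{i:02d}": float(s) for i, s in
                  enumerate(rng.uniform(100, 20000, 47))}
        shares = pm.allocate_attrition(67640.0, stocks)
        assert sum(shares.values()) == pytest.approx(67640.0, abs=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(pm.ValidationError):
            pm.allocate_attrition(10.0, {"A": 0.0, "B": 0.0})
        with pytest.raises(pm.ValidationError):
            pm.allocate_attrition(-1.0, {"A": 1.0})


class TestEstimateMigration:
    def test_two_prefecture_forced_arithmetic(self, two_pref_panel):
        est = {e.prefecture_id: e for e in pm.estimate_migration(two_pref_panel)}
        a, b = est["A"], est["B"]
        assert (a.allocated_attrition, b.allocated_attrition) == (40.0, 60.0)
        assert (a.adjusted_new_licensed, b.adjusted_new_licensed) == (60.0, 40.0)
        assert (a.actual_increase, b.actual_increase) == (30.0, 70.0)
        assert (a.net_migrants, b.net_migrants) == (30.0, -30.0)
        assert a.migration_ratio == pytest.approx(0.30)
        assert b.migration_ratio == pytest.approx(-0.30)
        assert (a.label, b.label) == ("outflow", "inflow")

    def test_net_migrants_identity_and_zero_sum(self, two_pref_panel):
        for e in pm.estimate_migration(two_pref_panel):
            assert e.net_migrants == e.adjusted_new_licensed - e.actual_increase

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_sum_on_random_panels(self, seed):
        panel, _ = pm.simulate_panel(small_random_config(seed))
        est = pm.estimate_migration(panel)
        assert sum(e.net_migrants for e in est) == pytest.approx(0.0, abs=1e-6)

    def test_oracle_equivalence_uniform_attrition(self):
        """Deterministic panel whose attrition satisfies the proportional-
        allocation assumption: estimates must equal truth exactly."""
        cfg = pm.make_paperlike_config(
            seed=11, deterministic=True, attrition_base="mean_stock"
        )
        panel, truth = pm.simulate_panel(cfg)
        for e in pm.estimate_migration(panel):
            assert e.net_migrants == pytest.approx(
                truth.true_net_migrants[e.prefecture_id], abs=1e-6
            )
            assert e.migration_ratio == pytest.approx(
                truth.true_migration_ratio[e.prefecture_id], abs=1e-9
            )
            assert e.allocated_attrition == pytest.approx(
                truth.true_attrition[e.prefecture_id], abs=1e-6
            )

    def test_heterogeneous_attrition_biases_estimates_but_conserves(self):
        """With a 2:1 attrition-rate gradient the equal-rate assumption is
        violated: estimates deviate from truth, but deviations sum to zero."""
        n = 10
        rates = tuple(np.linspace(0.01, 0.02, n))
        cfg = small_random_config(
            12, n_prefectures=n, deterministic=True, attrition_rate=rates,
            migration_model=pm.MigrationModel(gamma0=0, gamma_newppr=2, noise_sd=0),
        )
        panel, truth = pm.simulate_panel(cfg)
        dev = [
            e.net_migrants - truth.true_net_migrants[e.prefecture_id]
            for e in pm.estimate_migration(panel)
        ]
        assert max(abs(d) for d in dev) > 0.1
        assert sum(dev) == pytest.approx(0.0, abs=1e-6)

    def test_scale_equivariance(self, two_pref_panel):
        k = 3.5
        scaled = pm.PrefecturePanel(
            [
                pm.PrefectureRecord(
                    r.prefecture_id,
                    {y: v * k for y, v in r.stock_by_year.items()},
                    {y: v * k for y, v in r.new_licensed_by_year.items()},
                )
                for r in two_pref_panel.records
            ],
            two_pref_panel.baseline_year,
            two_pref_panel.final_year,
        )
        base = pm.estimate_migration(two_pref_panel)
        for e0, ek in zip(base, pm.estimate_migration(scaled)):
            assert ek.net_migrants == pytest.approx(k * e0.net_migrants)
            assert ek.migration_ratio == pytest.approx(e0.migration_ratio)

    def test_sign_convention(self, two_pref_panel):
        for e in pm.estimate_migration(two_pref_panel):
            if e.adjusted_new_licensed > e.actual_increase:
                assert e.net_migrants > 0 and e.label == "outflow"
            else:
                assert e.net_migrants < 0 and e.label == "inflow"

    def test_missing_stock_names_prefecture(self, two_pref_panel):
        broken = pm.PrefecturePanel(
            two_pref_panel.records
            + [pm.PrefectureRecord("C", {1994: 10.0}, {2000: 1.0})],
            1994,
            2014,
        )
        with pytest.raises(pm.ValidationError, match="C"):
            pm.estimate_migration(broken)

    def test_strict_mode_on_implausible_panel(self):
        # stock grows by more than licensing: negative national attrition
        records = [
            pm.PrefectureRecord("A", {2000: 100.0, 2010: 300.0}, {2005: 50.0}),
            pm.PrefectureRecord("B", {2000: 100.0, 2010: 200.0}, {2005: 50.0}),
        ]
        panel = pm.PrefecturePanel(records, 2000, 2010)
        with pytest.raises(pm.ValidationError):
            pm.estimate_migration(panel, strict=True)
        est = pm.estimate_migration(panel, strict=False)
        assert sum(e.net_migrants for e in est) == pytest.approx(0.0, abs=1e-9)

    def test_undefined_ratio_when_no_licensing(self):
        records = [
            pm.PrefectureRecord("A", {2000: 100.0, 2010: 90.0}, {}),
            pm.PrefectureRecord("B", {2000: 100.0, 2010: 90.0}, {2005: 10.0}),
        ]
        est = pm.estimate_migration(pm.PrefecturePanel(records, 2000, 2010))
        by_id = {e.prefecture_id: e for e in est}
        assert by_id["A"].migration_ratio is None
        assert by_id["B"].migration_ratio is not None


class TestFlowDifference:
    def test_worked_extremes(self):
        ests = _estimates_with_ratios([0.68, -2.45, 0.10, -0.50])
        assert pm.flow_difference(ests) == pytest.approx(313.0)

    def test_equal_ratios_give_zero(self):
        assert pm.flow_difference(_estimates_with_ratios([0.2, 0.2, 0.2])) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        ests = _estimates_with_ratios(rng.normal(0, 1, 12))
        assert pm.flow_difference(ests) >= 0.0

    def test_requires_two_defined_ratios(self):
        with pytest.raises(pm.ValidationError):
            pm.flow_difference(_estimates_with_ratios([0.5]))


def _estimates_with_ratios(ratios):
    return [
        pm.MigrationEstimate(
            prefecture_id=f"P{i:02d}", mean_stock=1.0, allocated_attrition=0.0,
            new_licensed_total=100.0, adjusted_new_licensed=100.0 * r,
            actual_increase=0.0, net_migrants=100.0 * r, migration_ratio=float(r),
            label="outflow" if r > 0 else "inflow",
        )
        for i, r in enumerate(ratios)
    ]


def test_estimates_csv_round_trip(tmp_path, two_pref_panel):
    est = pm.estimate_migration(two_pref_panel)
    path = tmp_path / "est.csv"
    pm.write_estimates(est, path)
    assert pm.read_estimates(path) == est
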