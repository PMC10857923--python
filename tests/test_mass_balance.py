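"""The ingestion-excretion budget: X, fates, losses, prevalence, biomass."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenobalance import (
    ChemProfile,
    CompoundCatalog,
    Compound,
    FeedingRecord,
    GeneratorConfig,
    balance,
    balance_table,
    classify_fate,
    consumed_dry,
    generate_experiment,
    percent_loss,
    prevalence_filter,
    retained_biomass,
    retention_estimates,
)


class TestConsumedDry:
    @pytest.mark.parametrize(
        "fresh,ratio,remaining,expected",
        [
            (2.0, 2.5, 0.5, 0.3),
            (2.0, 2.5, 0.8, 0.0),  # boundary non-feeder
            (0.0, 2.5, 0.0, 0.0),
        ],
    )
    def test_hand_values(self, fresh, ratio, remaining, expected):
        assert math.isclose(consumed_dry(fresh, ratio, remaining), expected, abs_tol=1e-12)

    def test_ratio_must_exceed_one(self):
        with pytest.raises(ValueError):
            consumed_dry(2.0, 0.8, 0.1)


def _record(w_leaf, c_leaf, w_frass, c_frass, catalog):
    leaf = ChemProfile({cid: c_leaf for cid in catalog.ids})
    frass = ChemProfile({cid: c_frass for cid in catalog.ids})
    return FeedingRecord(
        caterpillar="c1", phase=1, phase1_host="acer", phase2_host=None,
        fresh_offered=1.0, dry_remaining=0.0, frass_dry=w_frass,
        frass_profile=frass, leaf_profile=leaf, w_leaf=w_leaf,
    )


ONE_COMPOUND = CompoundCatalog([Compound("CA1", "x", "cinnamic_acid_derivative")])


class TestBalance:
    @pytest.mark.parametrize(
        "c_frass,x_expected,fate",
        [
            (20.0, 0.0, "passive"),   # ingested 2.0 = excreted 2.0
            (4.0, 1.6, "lost"),
            (30.0, -1.0, "produced"),
        ],
    )
    def test_hand_values(self, c_frass, x_expected, fate):
        rec = _record(0.2, 10.0, 0.1, c_frass, ONE_COMPOUND)
        (mb, ox, pp) = balance(rec, ONE_COMPOUND)
        assert math.isclose(mb.X, x_expected, abs_tol=1e-12)
        assert mb.fate == fate
        assert math.isclose(mb.X, mb.ingested - mb.excreted, abs_tol=1e-15)

    def test_activities_use_same_arithmetic(self):
        rec = _record(0.2, 10.0, 0.1, 4.0, ONE_COMPOUND)
        rec.leaf_profile.oxidative_activity = 10.0
        rec.frass_profile.oxidative_activity = 4.0
        results = balance(rec, ONE_COMPOUND)
        ox = next(r for r in results if r.variable == "Ox")
        assert math.isclose(ox.X, 1.6, abs_tol=1e-12)

    def test_missing_leaf_profile_is_linkage_error(self):
        rec = _record(0.2, 10.0, 0.1, 4.0, ONE_COMPOUND)
        rec.leaf_profile = None
        with pytest.raises(ValueError, match="leaf profile"):
            balance(rec, ONE_COMPOUND)

    def test_excluded_record_rejected(self):
        rec = _record(0.2, 10.0, 0.1, 4.0, ONE_COMPOUND)
        rec.excluded = True
        with pytest.raises(ValueError, match="excluded"):
            balance(rec, ONE_COMPOUND)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_concentrations(self, k):
        base = balance(_record(0.2, 10.0, 0.1, 4.0, ONE_COMPOUND), ONE_COMPOUND)[0]
        scaled = balance(_record(0.2, 10.0 * k, 0.1, 4.0 * k, ONE_COMPOUND), ONE_COMPOUND)[0]
        assert math.isclose(scaled.X, k * base.X, rel_tol=1e-12)


class TestClassifyFate:
    @pytest.mark.parametrize(
        "x,ingested,epsilon,expected",
        [
            (0.0, 5.0, 0.0, "passive"),
            (0.0, 5.0, 0.5, "passive"),
            (1.6, 2.0, 0.1, "lost"),       # 1.6 > 0.2
            (-0.05, 2.0, 0.1, "passive"),  # |-0.05| <= 0.2
            (-0.5, 2.0, 0.1, "produced"),
            (0.0005, 0.0, 0.1, "passive"),  # floor keeps trace thresholds nonzero
            (0.005, 0.0, 0.1, "lost"),
        ],
    )
    def test_banding(self, x, ingested, epsilon, expected):
        assert classify_fate(x, ingested, epsilon) == expected

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            classify_fate(0.0, 1.0, -0.1)


class TestPercentLoss:
    @pytest.mark.parametrize(
        "ingested,excreted,expected",
        [(5.0, 0.05, 0.99), (2.0, 2.0, 0.0), (2.0, 2.68, -0.34)],
    )
    def test_hand_values(self, ingested, excreted, expected):
        assert math.isclose(percent_loss(ingested, excreted), expected, abs_tol=1e-12)

    def test_zero_ingested_is_missing(self):
        assert math.isnan(percent_loss(0.0, 1.0))


class TestPrevalenceFilter:
    def _profiles(self, present_in, total, conc=0.5):
        """`present_in` of `total` profiles carry CA1 at `conc`; rest at 0."""
        out = []
        for i in range(total):
            out.append(ChemProfile({"CA1": conc if i < present_in else 0.0}))
        return out

    def test_exact_quarter_excluded_strict(self):
        kept = prevalence_filter(self._profiles(2, 8), ONE_COMPOUND)
        assert "CA1" not in kept  # 25% is not > 25%

    def test_above_quarter_included(self):
        kept = prevalence_filter(self._profiles(3, 8), ONE_COMPOUND)
        assert "CA1" in kept

    def test_exact_threshold_concentration_excluded(self):
        kept = prevalence_filter(self._profiles(8, 8, conc=0.01), ONE_COMPOUND)
        assert "CA1" not in kept  # 0.01 is not > 0.01

    def test_activities_always_kept(self):
        kept = prevalence_filter(self._profiles(0, 8), ONE_COMPOUND)
        assert "Ox" in kept and "PP" in kept

    def test_monotone_in_min_prev(self):
        profiles = self._profiles(5, 8)
        lo = set(prevalence_filter(profiles, ONE_COMPOUND, min_prev=0.25))
        hi = set(prevalence_filter(profiles, ONE_COMPOUND, min_prev=0.7))
        assert hi <= lo

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            prevalence_filter([], ONE_COMPOUND)


class TestRetainedBiomass:
    def _phase2(self, caterpillar, p1, p2, w_leaf, frass):
        return FeedingRecord(
            caterpillar=caterpillar, phase=2, phase1_host=p1, phase2_host=p2,
            fresh_offered=1.0, dry_remaining=0.0, frass_dry=frass, w_leaf=w_leaf,
        )

    def test_relative_decrease_hand_value(self):
        records = [
            self._phase2("stay", "q", "q", 0.15, 0.05),   # baseline retained 0.10
            self._phase2("moved", "a", "q", 0.10, 0.04),  # retained 0.06
        ]
        results, baselines = retained_biomass(records)
        assert math.isclose(baselines["q"], 0.10, abs_tol=1e-12)
        moved = next(r for r in results if r.caterpillar == "moved")
        assert math.isclose(moved.relative_decrease, 0.4, abs_tol=1e-12)
        stay = next(r for r in results if r.caterpillar == "stay")
        assert stay.relative_decrease == 0.0

    def test_negative_decrease_allowed(self):
        records = [
            self._phase2("stay", "q", "q", 0.15, 0.05),
            self._phase2("moved", "a", "q", 0.20, 0.04),  # retained 0.16 > baseline
        ]
        results, _ = retained_biomass(records)
        moved = next(r for r in results if r.caterpillar == "moved")
        assert moved.relative_decrease < 0

    def test_missing_baseline_is_configuration_error(self):
        records = [self._phase2("moved", "a", "q", 0.10, 0.04)]
        with pytest.raises(ValueError, match="baseline"):
            retained_biomass(records)


class TestRetentionRecovery:
    def test_noiseless_recovery_is_exact(self, noiseless_config):
        experiment, truth = generate_experiment(noiseless_config, seed=0)
        table = balance_table(experiment.phase_records(1), experiment.catalog)
        est = retention_estimates(table, experiment.catalog)
        for (host, cid), row in est.iterrows():
            assert abs(row["lambda_hat"] - truth.lambda_base[host][cid]) < 1e-9
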