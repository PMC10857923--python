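"""Generator contracts: determinism, conservation, zero-noise limits, design."""

import math

import numpy as np
import pytest

from phenobalance import (
    GeneratorConfig,
    balance_table,
    default_catalog,
    generate_experiment,
    generate_feeding,
    generate_leaves,
)


def _zero_noise(**kwargs):
    base = dict(
        tree_cv=0.0, batch_cv=0.0, measurement_cv=0.0,
        lambda_sd=0.0, assimilation_sd=0.0, consumption_cv=0.0,
    )
    base.update(kwargs)
    return GeneratorConfig(**base)


def _uniform_retention(value: float):
    catalog = default_catalog()
    return {sp: {cid: value for cid in catalog.ids} for sp in ("acer", "carpinus", "quercus")}


class TestLeaves:
    def test_zero_tree_cv_makes_trees_identical(self):
        config = _zero_noise()
        leaves, _ = generate_leaves(config, seed=0)
        acer = [s for s in leaves if s.species == "acer"]
        ref = acer[0].profile
        for s in acer[1:]:
            for cid in config.catalog.ids:
                assert s.profile.value(cid) == ref.value(cid)

    def test_absent_compound_is_zero_in_all_trees(self):
        config = GeneratorConfig()
        leaves, _ = generate_leaves(config, seed=0)
        # geraniin (HH1) is in the hornbeam support set only
        for s in leaves:
            if s.species != "carpinus":
                assert s.profile.value("HH1") == 0.0

    def test_one_feeding_tree_per_species(self):
        leaves, _ = generate_leaves(GeneratorConfig(), seed=0)
        for sp in ("acer", "carpinus", "quercus"):
            assert sum(s.is_feeding_tree for s in leaves if s.species == sp) == 1

    def test_seeded_determinism(self):
        a, _ = generate_leaves(GeneratorConfig(), seed=7)
        b, _ = generate_leaves(GeneratorConfig(), seed=7)
        for sa, sb in zip(a, b):
            assert sa.tree == sb.tree
            for cid in ("CA1", "HH1", "PC4"):
                assert sa.profile.value(cid) == sb.profile.value(cid)


class TestFeeding:
    def test_passive_excretion_limit_gives_zero_balance(self):
        """lambda = 0 and no noise: every ingested mg comes out again."""
        config = _zero_noise(retention=_uniform_retention(0.0))
        experiment, _ = generate_experiment(config, seed=0)
        table = balance_table(experiment.phase_records(1), experiment.catalog)
        compounds = table[~table["variable"].isin(["Ox", "PP"])]
        # per-compound X vanishes outside isomer families; family totals vanish too
        fam = set(experiment.catalog.family_members("caffeoyl_quinic_acid"))
        outside = compounds[~compounds["variable"].isin(fam)]
        assert outside["X"].abs().max() < 1e-9
        family_total = compounds[compounds["variable"].isin(fam)].groupby("caterpillar")["X"].sum()
        assert family_total.abs().max() < 1e-9

    def test_half_retention_halves_excretion(self):
        config = _zero_noise(retention=_uniform_retention(0.5))
        experiment, _ = generate_experiment(config, seed=0)
        table = balance_table(experiment.phase_records(1), experiment.catalog)
        compounds = table[~table["variable"].isin(["Ox", "PP"])]
        fam = set(experiment.catalog.family_members("caffeoyl_quinic_acid"))
        outside = compounds[(~compounds["variable"].isin(fam)) & (compounds["ingested"] > 0)]
        ratio = outside["excreted"] / outside["ingested"]
        assert np.allclose(ratio, 0.5, atol=1e-9)

    def test_isomer_family_redistributed_to_ph_targets(self):
        from phenobalance import simulate_fractions

        config = _zero_noise(retention=_uniform_retention(0.0))
        experiment, _ = generate_experiment(config, seed=0)
        rec = experiment.phase_records(1)[0]
        members = experiment.catalog.family_members("caffeoyl_quinic_acid")
        excreted = np.array([rec.w_frass * rec.frass_profile.value(m) for m in members])
        target = simulate_fractions(config.isomer_model, config.gut_ph_true)
        assert np.allclose(excreted / excreted.sum(), target, atol=1e-9)

    def test_family_mass_conserved_under_redistribution(self):
        """The worked conservation example: leaf fractions shuffled, total kept."""
        config = _zero_noise(retention=_uniform_retention(0.0))
        experiment, _ = generate_experiment(config, seed=0)
        members = experiment.catalog.family_members("caffeoyl_quinic_acid")
        for rec in experiment.phase_records(1)[:10]:
            ingested = sum(rec.w_leaf * rec.leaf_profile.value(m) for m in members)
            excreted = sum(rec.w_frass * rec.frass_profile.value(m) for m in members)
            assert math.isclose(ingested, excreted, abs_tol=1e-9)

    def test_retention_monotonicity_in_lambda(self):
        """Raising one compound's retention weakly raises its mean X."""
        lo = _uniform_retention(0.1)
        hi = _uniform_retention(0.1)
        hi["acer"]["FL1"] = 0.6
        mean_x = {}
        for name, retention in (("lo", lo), ("hi", hi)):
            config = GeneratorConfig(retention=retention)
            experiment, _ = generate_experiment(config, seed=3)
            table = balance_table(experiment.phase_records(1), experiment.catalog)
            sel = table[(table["current_host"] == "acer") & (table["variable"] == "FL1")]
            mean_x[name] = sel["X"].mean()
        assert mean_x["hi"] > mean_x["lo"]

    def test_habituation_lowers_two_host_retention(self):
        config = _zero_noise(habituation_delta=0.2)
        experiment, truth = generate_experiment(config, seed=0)
        stay = [(c, p) for (c, p) in truth.lambda_realized if p == 2]
        for cat_id, phase in stay:
            rec = next(
                r for r in experiment.records if r.caterpillar == cat_id and r.phase == 2
            )
            lam = truth.lambda_realized[(cat_id, 2)]
            base = truth.lambda_base[rec.phase2_host]
            for cid, value in lam.items():
                expected = base[cid] if rec.is_one_host else max(base[cid] - 0.2, 0.0)
                assert math.isclose(value, expected, abs_tol=1e-12)

    def test_seeded_determinism_full_experiment(self):
        e1, t1 = generate_experiment(seed=11)
        e2, t2 = generate_experiment(seed=11)
        assert len(e1.records) == len(e2.records)
        for a, b in zip(e1.records, e2.records):
            assert a.caterpillar == b.caterpillar and a.w_leaf == b.w_leaf
            assert a.frass_profile.value("CA1") == b.frass_profile.value("CA1")
        assert t1.assimilation_realized == t2.assimilation_realized


class TestDesign:
    def test_default_counts_follow_study_design(self):
        experiment, _ = generate_experiment(seed=0)
        phase1 = experiment.phase_records(1)
        by_host = {sp: sum(r.phase1_host == sp for r in phase1) for sp in ("acer", "carpinus", "quercus")}
        assert by_host == {"acer": 59, "carpinus": 59, "quercus": 65}
        phase2 = experiment.phase_records(2)
        by_current = {sp: sum(r.phase2_host == sp for r in phase2) for sp in ("acer", "carpinus", "quercus")}
        assert by_current == {"acer": 41, "carpinus": 39, "quercus": 35}
        trees = {sp: len({s.tree for s in experiment.leaves if s.species == sp})
                 for sp in ("acer", "carpinus", "quercus")}
        assert trees == {"acer": 10, "carpinus": 9, "quercus": 11}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(tree_cv=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(assimilation_mean=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(retention=_uniform_retention(1.2))

    def test_truth_serializes(self, tmp_path):
        import json

        _, truth = generate_experiment(seed=0)
        payload = truth.to_json_dict()
        text = json.dumps(payload)
        assert json.loads(text)["gut_ph_true"] == 9.9
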