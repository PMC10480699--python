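"""The synthetic-data generator: trees, traits, tables, determinism."""

import json

import numpy as np
import pandas as pd
import pytest

import phylorange as pr
from phylorange.simulate import CORRELATE_COLUMNS, write_study


class TestSimulateTree:
    def test_two_tips_is_unit_cherry(self):
        t = pr.simulate_tree(2, seed=0)
        assert len(t) == 2
        assert all(d == pytest.approx(1.0) for d in t.tip_depths().values())

    def test_deterministic_per_seed(self):
        assert pr.simulate_tree(12, seed=9).to_newick() == pr.simulate_tree(12, seed=9).to_newick()
        assert pr.simulate_tree(12, seed=9).to_newick() != pr.simulate_tree(12, seed=10).to_newick()

    def test_unit_depth_ultrametric(self):
        t = pr.simulate_tree(25, seed=4)
        d = np.array(list(t.tip_depths().values()))
        np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            pr.simulate_tree(1, seed=0)

    def test_pairwise_depth_distribution_matches_pure_birth_oracle(self):
        # Monte-Carlo cross-check of the Yule process: the mean relative
        # MRCA depth (mean off-diagonal over mean diagonal of the VCV) for
        # 20-tip pure-birth trees was computed with an independent
        # simulator (phytools::pbtree, 60 trees, seed 1): 0.2787 with a
        # per-tree SD of 0.0882 (standard error 0.0114).
        oracle_mean, oracle_se = 0.2787, 0.0114

        def mean_rel_mrca(vcv):
            C = vcv.matrix
            off = C[np.triu_indices_from(C, k=1)]
            return off.mean() / np.diag(C).mean()

        ours = [mean_rel_mrca(pr.to_vcv(pr.simulate_tree(20, seed=s))) for s in range(60)]
        se = np.hypot(np.std(ours) / np.sqrt(60), oracle_se)
        assert abs(np.mean(ours) - oracle_mean) < 4 * se


class TestSimulateBMTrait:
    def test_star_tree_unit_variance(self):
        # at lambda=0 on a unit-depth tree, tips are iid N(0, sigma2)
        tree = pr.simulate_tree(50, seed=7)
        draws = np.concatenate(
            [pr.simulate_bm_trait(tree, 1.0, 0.0, 100 + i).to_numpy() for i in range(20)]
        )
        assert np.var(draws) == pytest.approx(1.0, abs=0.1)

    def test_lambda_zero_not_phylogenetic(self):
        lams = []
        for i in range(100):
            tree = pr.simulate_tree(100, seed=3000 + i)
            y = pr.simulate_bm_trait(tree, 1.0, 0.0, 4000 + i)
            table = pd.DataFrame({"y": y})
            fit = pr.fit_pgls(pr.ModelSpec(pr.Term("y")), table, tree)
            lams.append(fit.lambda_hat)
        assert np.mean(lams) < 0.1

    def test_identical_seed_identical_vector(self):
        tree = pr.simulate_tree(10, seed=1)
        a = pr.simulate_bm_trait(tree, 1.0, 0.5, 42)
        b = pr.simulate_bm_trait(tree, 1.0, 0.5, 42)
        pd.testing.assert_series_equal(a, b)

    def test_bad_sigma_rejected(self):
        tree = pr.simulate_tree(5, seed=1)
        with pytest.raises(ValueError):
            pr.simulate_bm_trait(tree, 0.0, 0.5, 0)


class TestSimulateTable:
    def test_expected_columns_present(self, strong_study):
        _, table, _ = strong_study
        for col in ("ahr_km2", "dd_km", "ad_km", "ddad", "predation_risk",
                    "age_eyes_open", "route_tracing", "juvenile_mortality"):
            assert col in table.columns
        for col in CORRELATE_COLUMNS:
            assert col in table.columns

    def test_byte_identical_csv_per_config(self, tmp_path):
        cfg = pr.strong_preset(seed=12)
        p1 = write_study(cfg, tmp_path / "a")
        p2 = write_study(cfg, tmp_path / "b")
        assert p1["table"].read_bytes() == p2["table"].read_bytes()
        assert p1["tree"].read_bytes() == p2["tree"].read_bytes()
        truth = json.loads(p1["truth"].read_text())
        assert truth["seed"] == 12

    def test_missing_rate_bookkeeping(self):
        cfg = pr.SimulationConfig(n_species=40, seed=5,
                                  missing_rate={"body_mass": 0.2})
        tree, table, _ = pr.simulate_study(cfg)
        n_obs = table["body_mass"].notna().sum()
        fit = pr.fit_pgls(
            pr.ModelSpec(pr.Term("body_mass"), (pr.Term("ahr_km2", "log"),)),
            table, tree)
        assert fit.n == n_obs
        assert table["route_tracing"].notna().all()

    def test_zero_effects_controls_type_i(self):
        # with nothing planted, the route-tracing ~ DD:AD test is a true null
        hits = 0
        for seed in range(100):
            tree, table, _ = pr.simulate_study(pr.null_preset(seed=seed))
            fit = pr.fit_pgls(
                pr.ModelSpec(pr.Term("route_tracing"), (pr.Term("ddad", "log", "-"),)),
                table, tree)
            hits += fit.p_value("ddad") < 0.05
        assert hits <= 12  # binomial 95% band around 5% of 100

    def test_ddad_spans_realistic_range(self, strong_study):
        _, table, _ = strong_study
        dd = table["ddad"].dropna()
        assert dd.min() < 0.2 and dd.max() > 0.3  # itinerant through sedentary

    def test_cycle_detected(self):
        cfg = pr.SimulationConfig(effects=(("a", "b", 1.0), ("b", "a", 1.0)))
        tree = pr.simulate_tree(40, seed=0)
        with pytest.raises(ValueError, match="cycle"):
            pr.simulate_species_table(cfg, tree)

    def test_table_passes_validator(self, strong_study):
        _, table, _ = strong_study
        assert pr.validate_trait_table(table) is table

    def test_tree_smaller_than_request_rejected(self):
        cfg = pr.SimulationConfig(n_species=10)
        with pytest.raises(ValueError, match="tips"):
            pr.simulate_species_table(cfg, pr.simulate_tree(5, seed=0))


class TestTables:
    def test_load_round_trip(self, tmp_path, strong_study):
        _, table, _ = strong_study
        path = tmp_path / "traits.csv"
        table.to_csv(path)
        loaded = pr.load_trait_table(path)
        pd.testing.assert_frame_equal(loaded, table)

    def test_duplicate_species_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]}, index=["Canis_lupus", "canis lupus"])
        with pytest.raises(ValueError, match="duplicate"):
            pr.validate_trait_table(df)

    def test_match_species_split(self, strong_study):
        tree, table, _ = strong_study
        extra = table.copy()
        extra.loc["mystery_species"] = np.nan
        in_tree, missing = pr.match_species(extra, tree)
        assert missing == ["mystery_species"]
        assert len(in_tree) == len(table)
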