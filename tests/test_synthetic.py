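"""The synthetic-data generator: trees, trait tables, specimen tables."""

import numpy as np
import pandas as pd
import pytest

import carapace as cp


class TestSimulateTree:
    def test_ultrametric_with_requested_tips(self):
        tree = cp.simulate_tree(cp.SimulationConfig(n_tips=50, seed=1))
        assert tree.n_tips == 50
        depths = np.array(list(tree.tip_depths.values()))
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)

    def test_deterministic_under_seed(self):
        cfg = cp.SimulationConfig(n_tips=30, seed=5)
        assert (
            cp.simulate_tree(cfg).write_newick()
            == cp.simulate_tree(cfg).write_newick()
        )

    def test_different_seeds_differ(self):
        a = cp.simulate_tree(cp.SimulationConfig(n_tips=30, seed=5))
        b = cp.simulate_tree(cp.SimulationConfig(n_tips=30, seed=6))
        assert a.write_newick() != b.write_newick()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            cp.simulate_tree(cp.SimulationConfig(n_tips=2, seed=0))

    def test_covariance_is_positive_definite(self):
        # the post-speciation holding time keeps pendant edges > 0
        for seed in range(5):
            tree = cp.simulate_tree(cp.SimulationConfig(n_tips=40, seed=seed))
            assert np.linalg.eigvalsh(tree.vcv().matrix).min() > 0


class TestAllometricDataset:
    def test_noise_free_line(self):
        cfg = cp.SimulationConfig(
            n_tips=20, seed=2, sigma2_resid=0.0, covariate_effect=0.0
        )
        tree = cp.simulate_tree(cfg)
        tab, truth = cp.simulate_allometric_dataset(tree, cfg)
        np.testing.assert_allclose(
            tab.log10_scl, cfg.a + cfg.b * tab.log10_hl, atol=1e-12
        )
        assert truth["b"] == cfg.b

    def test_deterministic_tables(self):
        cfg = cp.SimulationConfig(n_tips=25, seed=9)
        tree = cp.simulate_tree(cfg)
        a, _ = cp.simulate_allometric_dataset(tree, cfg)
        b, _ = cp.simulate_allometric_dataset(tree, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_covariate_fraction(self):
        cfg = cp.SimulationConfig(n_tips=40, seed=3, covariate_fraction=0.25)
        tree = cp.simulate_tree(cfg)
        tab, truth = cp.simulate_allometric_dataset(tree, cfg)
        assert tab.ecology_terrestrial.sum() == 10 == truth["n_flagged"]

    def test_predictor_covariance_tracks_tree(self):
        """Sample covariance of x across replicates approximates s2_x * C."""
        n = 500
        cfg = cp.SimulationConfig(n_tips=n, seed=0, sigma2_x=0.15)
        tree = cp.simulate_tree(cfg)
        C = tree.vcv()
        n_rep = 200
        xs = np.empty((n_rep, n))
        for i in range(n_rep):
            tab, _ = cp.simulate_allometric_dataset(
                tree,
                cp.SimulationConfig(n_tips=n, seed=1000 + i, sigma2_x=0.15),
            )
            tab = tab.set_index("species").loc[list(C.taxa)]
            xs[i] = tab.log10_hl.to_numpy()
        emp = np.cov(xs.T, bias=True)
        target = 0.15 * C.matrix
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        # Wishart noise floor: E||S-Sigma||_F^2 = (tr Sigma^2 + tr(Sigma)^2)/B
        floor = np.sqrt(
            (np.trace(target) ** 2 + np.sum(target * target)) / n_rep
        ) / np.linalg.norm(target)
        assert rel < 1.25 * floor
        # calibration: entrywise regression of sample on expected covariance
        slope = float(
            np.sum(emp * target) / np.sum(target * target)
        )
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_no_residual_signal_when_lambda_zero(self):
        """lambda_resid=0 residuals show no phylogenetic signal under a
        neighbor-correlation permutation test."""
        rng = np.random.default_rng(0)
        detections = 0
        n_rep = 30
        for i in range(n_rep):
            cfg = cp.SimulationConfig(n_tips=100, seed=500 + i,
                                      lambda_resid=0.0)
            tree = cp.simulate_tree(cfg)
            tab, _ = cp.simulate_allometric_dataset(tree, cfg)
            resid = (
                tab.log10_scl
                - cfg.a
                - cfg.b * tab.log10_hl
                - cfg.covariate_effect * tab.ecology_terrestrial
            ).to_numpy()
            C = tree.vcv(order=list(tab.species)).matrix
            W = C - np.diag(np.diag(C))
            stat = resid @ W @ resid
            perms = np.array(
                [
                    (lambda r: r @ W @ r)(rng.permutation(resid))
                    for _ in range(199)
                ]
            )
            p = (1 + np.sum(perms >= stat)) / 200
            detections += p < 0.05
        assert detections <= 0.1 * n_rep + 1


@pytest.fixture(scope="module")
def tables():
    cfg = cp.SimulationConfig(n_tips=40, seed=7)
    tree = cp.simulate_tree(cfg)
    species, _ = cp.simulate_allometric_dataset(tree, cfg)
    specimens, maxima = cp.simulate_specimen_table(species, cfg)
    return cfg, species, specimens, maxima


class TestSpecimenTable:

    def test_filter_decisions_match_rule_replay(self, tables):
        """Independent brute-force replay of the maturity rules agrees with
        apply_maturity_filter on every synthetic specimen."""
        cfg, _, specimens, maxima = tables
        kept, log = cp.apply_maturity_filter(specimens, maxima)
        kept_ids = set(kept["specimen_id"])
        mx = {
            (r["species"], r["sex"]): r["max_scl_mm"]
            for _, r in maxima.iterrows()
        }
        for _, row in specimens.iterrows():
            sp = row["species"]
            larger = max(mx[(sp, "female")], mx[(sp, "male")])
            if not row["somatic_mature"]:
                expect = False
            elif row["include_override"]:
                expect = True
            elif row["sex"] == "unknown":
                expect = row["scl_mm"] >= 0.6 * larger
            else:
                expect = row["scl_mm"] >= 0.6 * mx[(sp, row["sex"])]
            assert (row["specimen_id"] in kept_ids) == expect

    def test_dimorphism_ratio_sets_thresholds(self, tables):
        cfg, _, _, maxima = tables
        wide = maxima.pivot(index="species", columns="sex",
                            values="max_scl_mm")
        np.testing.assert_allclose(
            wide["female"] / wide["male"], cfg.dimorphism_ratio
        )

    def test_all_juveniles_filtered_to_empty(self):
        cfg = cp.SimulationConfig(
            n_tips=10, seed=4, specimen_size_range=(0.2, 0.5),
            immature_somatic_fraction=0.0,
        )
        tree = cp.simulate_tree(cfg)
        species, _ = cp.simulate_allometric_dataset(tree, cfg)
        specimens, maxima = cp.simulate_specimen_table(species, cfg)
        kept, log = cp.apply_maturity_filter(specimens, maxima)
        # all draws are below 0.6 x male max <= 0.6 x sex max
        assert kept.empty
        assert len(log) == len(specimens)

    def test_gravid_only_above_threshold(self, tables):
        _, _, specimens, maxima = tables
        mx = {
            (r["species"], r["sex"]): r["max_scl_mm"]
            for _, r in maxima.iterrows()
        }
        gravid = specimens[specimens.gravid]
        assert (gravid.sex == "female").all()
        for _, row in gravid.iterrows():
            assert row.scl_mm >= 0.6 * mx[(row.species, "female")]

    def test_deterministic(self, tables):
        cfg, species, specimens, _ = tables
        again, _ = cp.simulate_specimen_table(species, cfg)
        pd.testing.assert_frame_equal(specimens, again)
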