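import numpy as np
import pytest
from scipy import stats

from anchorcorr import (
    SimulationConfig,
    collapse_probes,
    group_log2_ratio,
    planted_effect_size,
    probe_map_for,
    simulate_collection,
    simulate_dataset,
)
from anchorcorr.correlation import _matrix_pairwise_r


class TestPlantedEffectSize:
    @pytest.mark.parametrize(
        "r,anchor_sd,noise_sd,expected",
        [
            (0.0, 1.0, 1.0, 0.0),
            (0.0, 2.5, 0.3, 0.0),
            (0.6, 1.0, 1.0, 0.75),  # 0.6 / sqrt(1 - 0.36)
        ],
    )
    def test_closed_form(self, r, anchor_sd, noise_sd, expected):
        assert planted_effect_size(r, anchor_sd, noise_sd) == pytest.approx(expected)

    @pytest.mark.parametrize("r", [0.3, 0.8, 0.95])
    def test_sign_flip_symmetry(self, r):
        beta = planted_effect_size(r, 1.3, 0.7)
        assert planted_effect_size(-r, 1.3, 0.7) == pytest.approx(-beta)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_degenerate_target_rejected(self, r):
        with pytest.raises(ValueError):
            planted_effect_size(r, 1.0, 1.0)

    def test_plants_the_population_correlation(self, rng):
        # one huge sample: empirical r should sit on the target
        beta = planted_effect_size(0.62, 1.4, 0.9)
        anchor = rng.normal(0, 1.4, 200_000)
        gene = beta * anchor + rng.normal(0, 0.9, 200_000)
        assert np.corrcoef(anchor, gene)[0, 1] == pytest.approx(0.62, abs=0.01)


class TestSimulateDataset:
    def test_same_seed_is_byte_identical(self):
        config = SimulationConfig(n_genes=40, planted_genes=(("PG1", 0.5),), seed=5)
        a, _ = simulate_dataset(config, tissue="colon", dataset_id="colon01")
        b, _ = simulate_dataset(config, tissue="colon", dataset_id="colon01")
        assert a.values.equals(b.values)

    def test_different_master_seeds_differ(self):
        a, _ = simulate_dataset(SimulationConfig(n_genes=10, seed=1), dataset_id="d")
        b, _ = simulate_dataset(SimulationConfig(n_genes=10, seed=2), dataset_id="d")
        assert not a.values.equals(b.values)

    def test_null_anchor_fold_recovers_zero_log2fc(self):
        # fold 1 => planted log2 FC of 0; the mean observed FC over
        # replicates must be within 3 standard errors of 0
        fcs = []
        for rep in range(200):
            config = SimulationConfig(
                n_genes=0, anchor_fold_change=1.0, output_scale="log2", seed=rep,
                n_samples={"cancer": 20, "disease": 0, "normal": 20},
            )
            ds, _ = simulate_dataset(config, dataset_id="null01")
            fcs.append(group_log2_ratio(ds, "cancer", "normal").loc["PSME3"])
        fcs = np.array(fcs)
        assert abs(fcs.mean()) < 3 * fcs.std(ddof=1) / np.sqrt(len(fcs))

    def test_planted_r_concentrates_on_target(self):
        # Fisher-z CI at n=100 puts +-0.1 around r=0.8 well above 95% coverage
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            config = SimulationConfig(
                n_genes=0, planted_genes=(("PG1", 0.8),), output_scale="log2", seed=rep
            )
            _, truth = simulate_dataset(config, dataset_id="rep01")
            hits += abs(truth.planted["achieved_r"].iloc[0] - 0.8) <= 0.1
        assert hits / n_rep >= 0.95

    def test_achieved_r_is_unbiased(self):
        # mean empirical r over replicates converges to the target
        rs = []
        for rep in range(500):
            config = SimulationConfig(
                n_genes=0,
                planted_genes=(("PG1", 0.55),),
                n_samples={"cancer": 100, "disease": 0, "normal": 100},
                output_scale="log2",
                seed=rep,
            )
            _, truth = simulate_dataset(config, dataset_id="rep01")
            rs.append(truth.planted["achieved_r"].iloc[0])
        assert abs(np.mean(rs) - 0.55) < 0.02

    def test_background_tail_matches_fisher_z(self):
        # background genes are independent of the anchor: the fraction with
        # |r| above a threshold must match the Fisher-z tail probability
        config = SimulationConfig(
            n_genes=4000, anchor_fold_change=1.0, output_scale="log2", seed=42,
            n_samples={"cancer": 25, "disease": 0, "normal": 25},
        )
        ds, _ = simulate_dataset(config, dataset_id="bg01")
        X = ds.values.drop(index="PSME3").to_numpy()
        a = ds.values.loc["PSME3"].to_numpy()
        r, _ = _matrix_pairwise_r(X, a)
        thr = 0.28
        p_tail = 2 * stats.norm.sf(np.arctanh(thr) * np.sqrt(50 - 3))
        observed = int((np.abs(r) > thr).sum())
        expected = 4000 * p_tail
        assert abs(observed - expected) < 4 * np.sqrt(expected)
        # |r| > 0.6 at n=50 is a ~2e-6 event; none expected among 4,000
        assert int((np.abs(r) > 0.6).sum()) == 0

    def test_duplicate_probe_mode_supports_collapse(self):
        config = SimulationConfig(
            n_genes=20, planted_genes=(("PG1", 0.6),), duplicate_probes=True, seed=3
        )
        ds, _ = simulate_dataset(config, dataset_id="probes01")
        assert len(ds.feature_ids) == 2 * 22
        collapsed = collapse_probes(ds, probe_map_for(ds), anchor_symbol="PSME3")
        assert len(collapsed.feature_ids) == 22
        assert "PSME3" in collapsed.feature_ids

    def test_symbol_collision_rejected(self):
        config = SimulationConfig(n_genes=5, planted_genes=(("G000001", 0.5),))
        with pytest.raises(ValueError, match="collide"):
            simulate_dataset(config, dataset_id="x")


class TestSimulateCollection:
    def test_default_tissue_layout_gives_13_datasets(self):
        config = SimulationConfig(n_genes=5, seed=1)
        datasets, truth = simulate_collection(config)
        assert len(datasets) == 13
        by_tissue = {}
        for ds in datasets:
            by_tissue.setdefault(ds.metadata.tissue, []).append(ds.metadata.dataset_id)
        assert {t: len(v) for t, v in by_tissue.items()} == {
            "colon": 3, "liver": 4, "lung": 3, "thyroid": 3,
        }
        assert len(truth.anchor) == 13

    def test_zero_planted_genes_truth_lists_only_anchor(self):
        config = SimulationConfig(n_genes=5, seed=1)
        _, truth = simulate_collection(config)
        assert truth.planted.empty
        assert not truth.anchor.empty

    def test_planted_identities_shared_and_unique_per_dataset(self):
        config = SimulationConfig(n_genes=5, planted_genes=(("PG1", 0.5), ("PG2", -0.5)), seed=1)
        datasets, truth = simulate_collection(config)
        for ds in datasets:
            assert {"PG1", "PG2"} <= set(ds.feature_ids)
        # every planted symbol appears exactly once per dataset in the truth
        counts = truth.planted.groupby(["dataset_id", "gene"]).size()
        assert (counts == 1).all()
        assert len(truth.planted) == 13 * 2

    def test_adjacent_master_seeds_decorrelate(self):
        a, _ = simulate_collection(SimulationConfig(n_genes=5, seed=9))
        b, _ = simulate_collection(SimulationConfig(n_genes=5, seed=10))
        assert not a[0].values.equals(b[0].values)
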