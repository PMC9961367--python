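"""Synthetic cohort generator: distributions, splits, features, phantoms."""
import numpy as np
import pytest

import popgraph_stager as pg
from popgraph_stager.cohort import (ADNI1_COVARIATES, SCORE_NAMES, SEVERITY,
                                    atrophy_mask, planted_signal_params)


class TestCohortGeneration:
    def test_default_class_counts_match_adni1(self):
        cohort = pg.generate_cohort(pg.CohortConfig())
        counts = {d: cohort.diagnoses.count(d) for d in ("CN", "MCI", "AD")}
        assert counts == {"CN": 229, "MCI": 382, "AD": 187}

    def test_empty_cohort(self):
        cfg = pg.CohortConfig(class_counts={"CN": 0, "MCI": 0, "AD": 0})
        cohort = pg.generate_cohort(cfg)
        assert len(cohort) == 0 and cohort.split == {}

    def test_same_seed_reproduces_field_for_field(self, small_config):
        a = pg.generate_cohort(small_config)
        b = pg.generate_cohort(small_config)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_different_seed_differs(self, small_config, small_cohort):
        cfg = pg.CohortConfig(**{**small_config.__dict__, "seed": 99})
        other = pg.generate_cohort(cfg)
        assert not other.to_dataframe().equals(small_cohort.to_dataframe())

    def test_subject_validation(self):
        with pytest.raises(ValueError, match="apoe4"):
            pg.Subject("s", "AD", 70.0, "M", 3,
                       {k: 0.0 for k in SCORE_NAMES})
        with pytest.raises(ValueError, match="missing scores"):
            pg.Subject("s", "AD", 70.0, "M", 1, {"MMSE": 25.0})

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pg.CohortConfig(split_fractions=(0.8, 0.1, 0.2))

    def test_csv_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.to_csv(path)
        back = pg.Cohort.from_csv(path)
        assert back.ids == small_cohort.ids
        assert back.split == small_cohort.split

    def test_yaml_config_requires_seed(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("feature_dim: 8\n")
        with pytest.raises(ValueError, match="seed"):
            pg.CohortConfig.from_yaml(path)

    def test_yaml_config_round_trip(self, small_config, tmp_path):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        back = pg.CohortConfig.from_yaml(path)
        assert back == small_config


class TestSplit:
    def test_split_partitions_and_stratifies(self, small_cohort):
        masks = small_cohort.masks()
        total = sum(m.astype(int) for m in masks.values())
        assert np.all(total == 1)
        # per-class allocation within one subject of the exact fractions
        diag = np.array(small_cohort.diagnoses)
        for d in ("CN", "MCI", "AD"):
            n = int((diag == d).sum())
            for name, frac in zip(("train", "val", "test"), (0.7, 0.1, 0.2)):
                got = int((masks[name] & (diag == d)).sum())
                assert abs(got - frac * n) <= 1

    def test_resplit_changes_assignment_not_subjects(self, small_cohort):
        other = pg.experiments.resplit(small_cohort, seed=5)
        assert other.ids == small_cohort.ids
        assert other.split != small_cohort.split


class TestCovariates:
    @pytest.mark.parametrize("diagnosis", ["CN", "MCI", "AD"])
    def test_sample_means_converge_to_configured_means(self, diagnosis):
        n = 400
        cfg = pg.CohortConfig(
            class_counts={"CN": 0, "MCI": 0, "AD": 0} | {diagnosis: n},
            seed=7)
        cohort = pg.generate_cohort(cfg)
        params = ADNI1_COVARIATES[diagnosis]
        # unclipped (or effectively unclipped) covariates only
        mean, sd = params["age"]
        assert abs(cohort.covariate("age").mean() - mean) < 3 * sd / np.sqrt(n)
        for score in ("ADNI_MEM", "ADNI_EF", "ADNI_LAN", "ADNI_VS"):
            mean, sd = params["scores"][score]
            assert abs(cohort.covariate(score).mean() - mean) \
                < 3 * sd / np.sqrt(n)

    def test_categorical_proportions(self):
        cfg = pg.CohortConfig(class_counts={"CN": 800, "MCI": 0, "AD": 0},
                              seed=3)
        cohort = pg.generate_cohort(cfg)
        p_male = np.mean(cohort.covariate("gender") == "M")
        assert abs(p_male - ADNI1_COVARIATES["CN"]["gender_p_male"]) < 0.06
        p0 = np.mean(np.asarray(cohort.covariate("apoe4"), int) == 0)
        assert abs(p0 - ADNI1_COVARIATES["CN"]["apoe4_probs"][0]) < 0.06

    def test_planted_params_stagger_only_the_planted_score(self):
        params = planted_signal_params(planted="CDR_SB")
        for score in SCORE_NAMES:
            means = [params[d]["scores"][score][0] for d in ("CN", "MCI", "AD")]
            if score == "CDR_SB":
                assert means[0] < means[1] < means[2]
            else:
                assert len(set(means)) == 1


def _nearest_centroid_accuracy(features, labels, train, test):
    """Independent oracle: classify held-out rows by nearest class centroid."""
    X = features.values
    cents = {c: X[train & (labels == c)].mean(axis=0) for c in set(labels)}
    correct = 0
    for i in np.flatnonzero(test):
        dists = {c: np.linalg.norm(X[i] - mu) for c, mu in cents.items()}
        correct += min(dists, key=dists.get) == labels[i]
    return correct / test.sum()


class TestFeatures:
    def test_default_shape_is_n_by_512(self):
        cfg = pg.CohortConfig(class_counts={"CN": 5, "MCI": 4, "AD": 3})
        cohort = pg.generate_cohort(cfg)
        feats = pg.generate_features(cohort, cfg)
        assert feats.values.shape == (12, 512)
        assert np.all(feats.values >= 0)

    def test_deterministic_given_seed(self, small_cohort, small_config):
        a = pg.generate_features(small_cohort, small_config)
        b = pg.generate_features(small_cohort, small_config)
        assert np.array_equal(a.values, b.values)

    def test_zero_separation_gives_chance_level_features(self):
        cfg = pg.CohortConfig(class_counts={"CN": 80, "MCI": 80, "AD": 0},
                              feature_dim=32, class_separation=0.0, seed=5)
        cohort = pg.generate_cohort(cfg)
        feats = pg.generate_features(cohort, cfg)
        labels = cohort.labels(("CN", "MCI"))
        masks = cohort.masks()
        acc = _nearest_centroid_accuracy(feats, labels, masks["train"],
                                         masks["test"])
        assert 0.25 <= acc <= 0.75

    def test_large_separation_exceeds_95pct_heldout_accuracy(self):
        cfg = pg.CohortConfig(class_counts={"CN": 100, "MCI": 100, "AD": 100},
                              feature_dim=64, class_separation=10.0,
                              noise_sd=1.0, seed=5)
        cohort = pg.generate_cohort(cfg)
        feats = pg.generate_features(cohort, cfg)
        labels = cohort.labels()
        masks = cohort.masks()
        acc = _nearest_centroid_accuracy(feats, labels, masks["train"],
                                         masks["test"])
        assert acc > 0.95

    def test_empty_cohort_rejected(self, small_config):
        empty = pg.Cohort(subjects=[], split={})
        with pytest.raises(ValueError, match="empty"):
            pg.generate_features(empty, small_config)

    def test_accuracy_monotone_in_class_separation(self):
        """Downstream GCN accuracy should not decrease with separation."""
        def mean_acc(sep):
            accs = []
            for seed in range(10):
                cfg = pg.CohortConfig(
                    class_counts={"CN": 30, "MCI": 30, "AD": 0},
                    feature_dim=16, class_separation=sep, seed=21)
                cohort = pg.generate_cohort(cfg)
                cohort = pg.experiments.resplit(cohort, seed=seed)
                feats = pg.generate_features(cohort, cfg)
                sub = cohort.subset(("CN", "MCI"))
                labels = cohort.labels(("CN", "MCI"))
                graph = pg.build_graph(feats, sub, pg.EdgeSpec("baseline"))
                cfg_g = pg.GCNConfig(seed=seed, learning_rate=3e-3)
                model, _ = pg.train_transductive(graph, labels, cfg_g)
                pred, _ = pg.predict(model, graph)
                test = graph.masks["test"]
                accs.append(np.mean(pred[test] == labels[test]))
            return float(np.mean(accs))

        assert mean_acc(4.0) >= mean_acc(0.5) - 0.02


class TestVolumes:
    def test_default_shape_64_cubed(self):
        cfg = pg.CohortConfig(class_counts={"CN": 2, "MCI": 2, "AD": 2})
        cohort = pg.generate_cohort(cfg)
        vols = pg.generate_volumes(cohort, seed=0)
        assert vols.shape == (64, 64, 64)
        assert np.all(vols.data >= 0)

    def test_zero_amplitude_erases_class_differences(self):
        cfg = pg.CohortConfig(class_counts={"CN": 30, "MCI": 0, "AD": 30})
        cohort = pg.generate_cohort(cfg)
        vols = pg.generate_volumes(cohort, shape=(16, 16, 16),
                                   atrophy_amplitude=0.0, seed=2)
        mask = atrophy_mask((16, 16, 16))
        sev = np.array([SEVERITY[d] for d in cohort.diagnoses])
        region = vols.data[:, mask].mean(axis=1)
        assert abs(region[sev == 2].mean() - region[sev == 0].mean()) < 0.01

    def test_atrophy_lowers_region_intensity_for_ad(self):
        cfg = pg.CohortConfig(class_counts={"CN": 50, "MCI": 0, "AD": 50})
        cohort = pg.generate_cohort(cfg)
        vols = pg.generate_volumes(cohort, shape=(16, 16, 16),
                                   atrophy_amplitude=0.5, seed=2)
        mask = atrophy_mask((16, 16, 16))
        sev = np.array([SEVERITY[d] for d in cohort.diagnoses])
        region = vols.data[:, mask].mean(axis=1)
        assert region[sev == 2].mean() < region[sev == 0].mean() - 0.05

    def test_nifti_round_trip(self, tmp_path):
        cfg = pg.CohortConfig(class_counts={"CN": 2, "MCI": 1, "AD": 1})
        cohort = pg.generate_cohort(cfg)
        vols = pg.generate_volumes(cohort, shape=(8, 8, 8), seed=4)
        vols.write_nifti(tmp_path)
        back = pg.VolumeSet.read_nifti(tmp_path, cohort.ids)
        assert np.allclose(back.data, vols.data, atol=1e-6)
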