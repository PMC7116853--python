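"""Training procedure: splits, batch composition, schedules and a short
seeded optimisation run on small phantoms."""

import numpy as np
import pytest

from jointseg import ArchConfig, HeteroUNet, build_task_datasets
from jointseg.trainer import (TrainingConfig, TrainingDatasets, TrainingError,
                              learning_rate, sample_paired_batch,
                              split_dataset, train)


@pytest.fixture(scope="module")
def small_cohort():
    from jointseg.phantom import LesionParams, TissueLayout, wmh_scenario

    cfg = wmh_scenario(
        seed=11, grid_shape=(32, 32),
        tissue_layout=TissueLayout(center_jitter=0.5),
        lesion_params=LesionParams(count_range=(1, 2),
                                   radius_range=(1.5, 3.0)))
    control, lesion, pseudo, test = build_task_datasets(cfg, (8, 8, 2, 2))
    datasets = TrainingDatasets(
        control=control.subset(range(6)), lesion=lesion.subset(range(6)),
        pseudo=pseudo, val_control=control.subset(range(6, 8)),
        val_lesion=lesion.subset(range(6, 8)))
    return cfg, datasets, test


def small_model(cfg, seed=0):
    arch = ArchConfig(num_modalities=2, num_classes=cfg.taxonomy.num_classes,
                      levels=2, base_channels=4, ndim=2)
    return HeteroUNet(arch, seed=seed)


class TestSplitDataset:
    def test_ten_subjects_split_7_1_2(self, small_cohort):
        cfg, _, _ = small_cohort
        control, *_ = build_task_datasets(cfg, (10, 0, 0, 0))
        tr, va, te = split_dataset(control, fold=0, seed=1)
        assert (len(tr), len(va), len(te)) == (7, 1, 2)

    def test_deterministic_and_disjoint(self, small_cohort):
        cfg, _, _ = small_cohort
        control, *_ = build_task_datasets(cfg, (10, 0, 0, 0))
        parts_a = split_dataset(control, fold=1, seed=3)
        parts_b = split_dataset(control, fold=1, seed=3)
        ids = lambda m: [s.subject_id for s in m.subjects]
        assert [ids(m) for m in parts_a] == [ids(m) for m in parts_b]
        all_ids = sum((ids(m) for m in parts_a), [])
        assert sorted(all_ids) == sorted(ids(control))
        assert len(set(all_ids)) == len(all_ids)

    def test_folds_rotate_membership(self, small_cohort):
        cfg, _, _ = small_cohort
        control, *_ = build_task_datasets(cfg, (10, 0, 0, 0))
        test_ids = [set(s.subject_id for s in
                        split_dataset(control, fold=f, seed=3)[2].subjects)
                    for f in (0, 1, 2)]
        assert test_ids[0] != test_ids[1]

    def test_invalid_fold_and_tiny_dataset(self, small_cohort):
        cfg, _, _ = small_cohort
        control, *_ = build_task_datasets(cfg, (10, 0, 0, 0))
        with pytest.raises(ValueError):
            split_dataset(control, fold=3, seed=0)
        tiny, *_ = build_task_datasets(cfg, (3, 0, 0, 0))
        with pytest.raises(ValueError):
            split_dataset(tiny, fold=0, seed=0)


class TestLearningRateSchedule:
    def test_halved_every_10k_iterations(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 5e-4
        assert learning_rate(cfg, 0) == 5e-4
        assert learning_rate(cfg, 9_999) == 5e-4
        assert learning_rate(cfg, 10_000) == 2.5e-4
        assert learning_rate(cfg, 20_000) == 1.25e-4

    def test_plateau_halvings_compose_with_fixed_schedule(self):
        cfg = TrainingConfig()
        assert learning_rate(cfg, 10_000, plateau_halvings=1) == 1.25e-4


class TestBatchSampling:
    def test_group_sizes(self, small_cohort):
        _, datasets, _ = small_cohort
        rng = np.random.default_rng(0)
        batch = sample_paired_batch(datasets, TrainingConfig(mode="pseudo"),
                                    rng)
        assert len(batch.lesion) == 2
        assert len(batch.control) == 2
        assert len(batch.pseudo) == 2
        for s in batch.lesion:
            assert s.image.available.all()
        for s in batch.control:
            assert s.image.available.tolist() == [True, False]

    def test_augm_da_control_pair_shares_subject(self, small_cohort):
        _, datasets, _ = small_cohort
        rng = np.random.default_rng(1)
        batch = sample_paired_batch(datasets, TrainingConfig(mode="augm_da"),
                                    rng)
        assert len(batch.control) == 2
        assert batch.control[0].subject_id == batch.control[1].subject_id
        assert np.array_equal(batch.control[0].image.channels,
                              batch.control[1].image.channels)

    def test_fixed_rng_reproduces_batch(self, small_cohort):
        _, datasets, _ = small_cohort
        cfg = TrainingConfig(mode="no_da")
        a = sample_paired_batch(datasets, cfg, np.random.default_rng(7))
        b = sample_paired_batch(datasets, cfg, np.random.default_rng(7))
        for ga, gb in zip((a.lesion, a.control), (b.lesion, b.control)):
            for sa, sb in zip(ga, gb):
                assert sa.subject_id == sb.subject_id
                assert np.array_equal(sa.image.channels, sb.image.channels)

    def test_empty_manifest_raises(self, small_cohort):
        _, datasets, _ = small_cohort
        empty = TrainingDatasets(control=datasets.control, lesion=None)
        with pytest.raises(TrainingError):
            sample_paired_batch(empty, TrainingConfig(mode="no_da"),
                                np.random.default_rng(0))


class TestTrainingLoop:
    def _run(self, small_cohort, seed=0, **overrides):
        cfg, datasets, _ = small_cohort
        options = dict(mode="no_da", max_epochs=4, consistency_warmup=1,
                       learning_rate=5e-3, seed=seed, iters_per_epoch=5)
        options.update(overrides)
        model = small_model(cfg, seed=seed)
        return train(model, datasets, TrainingConfig(**options))

    def test_loss_decreases_and_log_contract(self, small_cohort):
        # constant component set (no warmup transition) for a fair trend
        _, log = self._run(small_cohort, consistency_warmup=0, max_epochs=8)
        iters = [r for r in log if "total" in r]
        epochs = [r for r in log if "validation_loss" in r]
        assert len(iters) == 40
        assert len(epochs) == 8
        assert all("lesion" in r and "tissue_control" in r and "lr" in r
                   for r in iters)
        first = np.mean([r["total"] for r in iters[:5]])
        last = np.mean([r["total"] for r in iters[-5:]])
        assert last < first

    def test_two_seeded_runs_are_identical(self, small_cohort):
        _, log_a = self._run(small_cohort, seed=3)
        _, log_b = self._run(small_cohort, seed=3)
        totals_a = [r["total"] for r in log_a if "total" in r]
        totals_b = [r["total"] for r in log_b if "total" in r]
        assert totals_a == totals_b

    def test_consistency_term_respects_warmup(self, small_cohort):
        _, log = self._run(small_cohort, consistency_warmup=2)
        for r in log:
            if "total" not in r:
                continue
            if r["epoch"] < 2:
                assert "consistency" not in r
                assert not r["consistency_active"]
            else:
                assert "consistency" in r

    def test_augmentation_da_mode_adds_term_after_warmup(self, small_cohort):
        _, log = self._run(small_cohort, mode="augm_da", da_warmup=2,
                           max_epochs=3)
        for r in log:
            if "total" not in r:
                continue
            assert ("da" in r) == (r["epoch"] >= 2)

    def test_adversarial_mode_runs_and_gates_da_term(self, small_cohort):
        _, log = self._run(small_cohort, mode="adv_da", da_warmup=1,
                           max_epochs=2, iters_per_epoch=3)
        iters = [r for r in log if "total" in r]
        assert not any("da" in r for r in iters if r["epoch"] == 0)
        assert all("da" in r for r in iters if r["epoch"] == 1)

    def test_pseudo_mode_has_both_tissue_terms(self, small_cohort):
        _, log = self._run(small_cohort, mode="pseudo", max_epochs=1)
        iters = [r for r in log if "total" in r]
        assert all("tissue_pseudo" in r and "tissue_control" in r
                   for r in iters)

    def test_log_written_to_jsonl(self, small_cohort, tmp_path):
        import json

        cfg, datasets, _ = small_cohort
        model = small_model(cfg)
        path = tmp_path / "log.jsonl"
        train(model, datasets,
              TrainingConfig(mode="no_da", max_epochs=1, iters_per_epoch=2,
                             seed=0),
              log_path=path)
        records = [json.loads(line) for line in path.read_text().splitlines()]
        assert len(records) == 3  # 2 iterations + 1 epoch record
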