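"""Label decomposition, group losses, the tractable segmentation loss in its
modes, and the triangle-inequality upper bound."""

import numpy as np
import pytest

from jointseg import ClassTaxonomy, prob_multiclass_jaccard
from jointseg.autodiff import Tensor
from jointseg.data import MultiModalImage, Subject
from jointseg.objective import (Batch, LossReport, check_tissue_upper_bound,
                                decompose_labels, lesion_loss, one_hot,
                                seg_loss, tissue_loss, total_loss)
from conftest import random_simplex


WMH_TAX = ClassTaxonomy(tuple(range(1, 7)), (7,))


class TestDecomposeLabels:
    def test_worked_example(self):
        yt, yl = decompose_labels(np.array([0, 2, 7]), WMH_TAX)
        assert yt.tolist() == [0, 2, 0]
        assert yl.tolist() == [0, 0, 7]

    def test_lesion_free_map(self, taxonomy):
        y = np.array([[0, 1], [3, 4]])
        yt, yl = decompose_labels(y, taxonomy)
        assert np.array_equal(yt, y)
        assert not yl.any()

    def test_sum_reconstructs_exactly(self, taxonomy):
        rng = np.random.default_rng(0)
        y = rng.choice(taxonomy.all_classes, size=(9, 9))
        yt, yl = decompose_labels(y, taxonomy)
        assert np.array_equal(yt + yl, y)

    def test_out_of_taxonomy_label_rejected(self, taxonomy):
        with pytest.raises(ValueError):
            decompose_labels(np.array([0, 99]), taxonomy)


class TestGroupLosses:
    def test_perfect_prediction_is_zero(self, taxonomy, weights):
        rng = np.random.default_rng(1)
        y = rng.choice(taxonomy.all_classes, size=(8, 8))
        p = one_hot(y, taxonomy)
        assert float(tissue_loss(p, y, weights)) == 0.0
        assert float(lesion_loss(p, y, weights)) == 0.0

    def test_empty_lesion_target_and_prediction_gives_zero(self, taxonomy,
                                                           weights):
        y = np.zeros((6, 6), dtype=int)  # background only
        p = one_hot(y, taxonomy)
        assert float(lesion_loss(p, y, weights)) == 0.0

    def test_lesion_channels_do_not_enter_tissue_loss(self, taxonomy,
                                                      weights):
        rng = np.random.default_rng(2)
        u = random_simplex(rng, taxonomy.num_classes, 40)
        v = random_simplex(rng, taxonomy.num_classes, 40)
        base = float(tissue_loss(u, v, weights))
        u2 = u.copy()
        # move mass between lesion and background channels only
        u2[-1], u2[0] = u[0], u[-1]
        assert float(tissue_loss(u2, v, weights)) == pytest.approx(
            base, abs=1e-12)

    def test_decomposition_oracle(self, taxonomy, weights):
        """tissue + lesion losses complement each other: their sum is the
        full-taxonomy distance (background term vanishes at ω_0 = 0)."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            u = random_simplex(rng, taxonomy.num_classes, 30)
            v = random_simplex(rng, taxonomy.num_classes, 30)
            full = float(prob_multiclass_jaccard(u, v, weights))
            assert full == (float(tissue_loss(u, v, weights))
                            + float(lesion_loss(u, v, weights)))

    def test_losses_accept_probability_targets(self, taxonomy, weights):
        rng = np.random.default_rng(4)
        u = random_simplex(rng, taxonomy.num_classes, 20)
        v = random_simplex(rng, taxonomy.num_classes, 20)
        assert float(tissue_loss(u, v, weights)) > 0


class TestUpperBound:
    def test_holds_on_random_triples(self, taxonomy, weights):
        rng = np.random.default_rng(5)
        for _ in range(300):
            pred_full = random_simplex(rng, taxonomy.num_classes, 30)
            pred_shared = random_simplex(rng, taxonomy.num_classes, 30)
            target = rng.choice(taxonomy.all_classes, size=30)
            slack = check_tissue_upper_bound(pred_full, pred_shared, target,
                                             weights)
            assert slack >= -1e-9

    def test_holds_under_training_weight_policy(self, taxonomy,
                                                training_weights):
        rng = np.random.default_rng(6)
        for _ in range(100):
            pf = random_simplex(rng, taxonomy.num_classes, 25)
            ps = random_simplex(rng, taxonomy.num_classes, 25)
            tgt = rng.choice(taxonomy.all_classes, size=25)
            assert check_tissue_upper_bound(pf, ps, tgt,
                                            training_weights) >= -1e-9


class _OracleModel:
    """Stub segmenter returning the one-hot of a fixed label map."""

    class config:
        num_modalities = 2
        shared_modality = 0

    def __init__(self, labels_by_key, taxonomy):
        self.labels_by_key = labels_by_key
        self.taxonomy = taxonomy

    def forward(self, x, mask):
        maps = []
        for b in range(x.shape[0]):
            key = round(float(x[b].sum()), 3)
            maps.append(one_hot(self.labels_by_key[key], self.taxonomy))
        return Tensor(np.stack(maps))


def _subject(sid, labels, kind, taxonomy, seed):
    rng = np.random.default_rng(seed)
    chans = rng.normal(size=(2, *labels.shape)).astype(np.float32)
    avail = np.array([True, kind == "lesion"])
    return Subject(sid, MultiModalImage(chans, avail), labels, kind,
                   "lesion" if kind == "lesion" else "control")


class TestSegLoss:
    def _batch(self, taxonomy):
        rng = np.random.default_rng(7)
        y_l = rng.choice(taxonomy.all_classes, size=(8, 8))
        y_c = rng.choice([0, *taxonomy.tissue_classes], size=(8, 8))
        lesion = _subject("l0", decompose_labels(y_l, taxonomy)[1], "lesion",
                          taxonomy, 1)
        control = _subject("c0", y_c, "tissue", taxonomy, 2)
        return Batch(lesion=[lesion], control=[control]), y_l, y_c

    def _oracle(self, batch, y_l, y_c, taxonomy):
        keys = {}
        keys[round(float(batch.lesion[0].image.channels.sum()), 3)] = y_l
        keys[round(float(batch.control[0].image.channels.sum()), 3)] = y_c
        return _OracleModel(keys, taxonomy)

    def test_perfect_oracle_gives_zero_total(self, taxonomy,
                                             training_weights):
        batch, y_l, y_c = self._batch(taxonomy)
        model = self._oracle(batch, y_l, y_c, taxonomy)
        rep = seg_loss(batch, model, training_weights, mode="no_da",
                       epoch=100, consistency_warmup=50)
        assert rep.total == pytest.approx(0.0, abs=1e-9)
        assert set(rep.components) == {"lesion", "consistency",
                                       "tissue_control"}

    def test_consistency_skipped_during_warmup(self, taxonomy,
                                               training_weights):
        batch, y_l, y_c = self._batch(taxonomy)
        model = self._oracle(batch, y_l, y_c, taxonomy)
        rep = seg_loss(batch, model, training_weights, mode="no_da",
                       epoch=0, consistency_warmup=50)
        assert "consistency" not in rep.components
        rep50 = seg_loss(batch, model, training_weights, mode="no_da",
                         epoch=50, consistency_warmup=50)
        assert "consistency" in rep50.components

    def test_components_sum_to_total(self, taxonomy, training_weights):
        batch, y_l, y_c = self._batch(taxonomy)
        # imperfect model: oracle for the wrong maps
        model = self._oracle(batch, np.roll(y_l, 1), np.roll(y_c, 1),
                             taxonomy)
        rep = seg_loss(batch, model, training_weights, mode="no_da",
                       epoch=100, consistency_warmup=0)
        assert rep.total == pytest.approx(sum(rep.components.values()))
        assert rep.total == pytest.approx(float(rep.total_tensor.data))

    def test_pseudo_mode_averages_the_tissue_terms(self, taxonomy,
                                                   training_weights):
        batch, y_l, y_c = self._batch(taxonomy)
        rng = np.random.default_rng(8)
        y_p = rng.choice([0, *taxonomy.tissue_classes], size=(8, 8))
        pseudo = _subject("p0", y_p, "tissue", taxonomy, 3)
        batch.pseudo = [pseudo]
        keys = {round(float(batch.lesion[0].image.channels.sum()), 3): y_l,
                round(float(batch.control[0].image.channels.sum()), 3): y_c,
                round(float(pseudo.image.channels.sum()), 3): np.roll(y_p, 1)}
        model = _OracleModel(keys, taxonomy)
        rep = seg_loss(batch, model, training_weights, mode="pseudo",
                       epoch=0, consistency_warmup=50)
        # control matches perfectly, pseudo is wrong: the tissue term is the
        # average of the two formulations
        assert rep.components["tissue_control"] == 0.0
        pseudo_term = float(tissue_loss(one_hot(np.roll(y_p, 1), taxonomy),
                                        y_p, training_weights))
        assert rep.components["tissue_pseudo"] == pytest.approx(
            0.5 * pseudo_term, rel=1e-6)

    def test_missing_group_raises(self, taxonomy, training_weights):
        batch, y_l, y_c = self._batch(taxonomy)
        model = self._oracle(batch, y_l, y_c, taxonomy)
        with pytest.raises(ValueError):
            seg_loss(Batch(lesion=batch.lesion), model, training_weights,
                     mode="no_da")
        with pytest.raises(ValueError):
            seg_loss(batch, model, training_weights, mode="pseudo")


class TestTotalLoss:
    def _seg(self, value=0.5):
        rep = LossReport(components={"lesion": value})
        rep.total_tensor = Tensor(np.array(value))
        return rep

    def test_lambda_zero_keeps_seg_total(self):
        out = total_loss(self._seg(0.5), Tensor(np.array(0.9)), 0.0)
        assert out.total == pytest.approx(0.5)

    def test_weighted_da_term_added(self):
        out = total_loss(self._seg(0.5), Tensor(np.array(0.2)), 1.0)
        assert out.total == pytest.approx(0.7)
        assert out.components["da"] == pytest.approx(0.2)

    def test_monotone_in_da_term(self):
        totals = [total_loss(self._seg(0.5), Tensor(np.array(d)), 0.3).total
                  for d in (0.0, 0.5, 1.0)]
        assert totals == sorted(totals)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(self._seg(), Tensor(np.array(0.1)), -0.1)
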