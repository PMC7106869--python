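"""Training phases: pretraining losses decrease, splits are deterministic,
the joint loop respects the composite-objective bookkeeping, checkpoints
resume bit-exactly, and evaluation reports are sound."""

import numpy as np
import pytest

from echosketch import losses as L
from echosketch import metrics as M
from echosketch import phantom as ph
from echosketch import training as T
from echosketch.networks import DecoderSpec, build_decoder_generator


@pytest.fixture(scope="module")
def seg_pairs(tmp_path_factory):
    out = tmp_path_factory.mktemp("seg")
    manifest = ph.generate_pretrain_segmentation_set(
        20, seed=3, out_dir=out, boundary_class=True
    )
    return T.load_segmentation_pairs(manifest)


@pytest.fixture(scope="module")
def tiny_split(small_dataset):
    return T.few_shot_split(small_dataset, shots=2, seed=9)


class TestPretrainU2S:
    def test_cross_entropy_decreases(self, seg_pairs):
        cfg = T.TrainConfig(phase="pretrain_u2s", steps=200, base_channels=8, seed=1)
        state, log = T.pretrain_u2s_parent(seg_pairs, cfg)
        ce = log.values("ce")
        assert np.mean(ce[-20:]) < np.mean(ce[:20])
        assert state.provenance == "parent"

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            T.TrainConfig(steps=0)

    def test_step0_loss_deterministic(self, seg_pairs):
        cfg = T.TrainConfig(phase="pretrain_u2s", steps=2, base_channels=8, seed=7)
        _, log_a = T.pretrain_u2s_parent(seg_pairs, cfg)
        _, log_b = T.pretrain_u2s_parent(seg_pairs, cfg)
        assert log_a.values("ce")[0] == log_b.values("ce")[0]

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            T.pretrain_u2s_parent([], T.TrainConfig(steps=1))


class TestPretrainS2U:
    @pytest.fixture(scope="class")
    def frames(self):
        return [
            ph.generate_paired_sample(ph.PhantomParams(seed=500 + i)).ultrasound
            for i in range(30)
        ]

    def test_generated_mean_moves_toward_data(self, frames):
        cfg = T.TrainConfig(phase="pretrain_s2u", steps=300, base_channels=8, seed=2)
        state, log = T.pretrain_s2u_parent(frames, cfg)
        # rebuild generator at step 0 and at the end; compare mean to data
        dec0, _ = build_decoder_generator(
            DecoderSpec(latent_channels=64, latent_size=4, base_channels=16), seed=2
        )
        dec1, _ = build_decoder_generator(
            DecoderSpec(latent_channels=64, latent_size=4, base_channels=16), seed=2
        )
        dec1.load_state_dict(state.arrays, strict=True)
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 64, 4, 4))
        dec0.eval(), dec1.eval()
        data_mean = np.mean([f.mean() for f in frames])
        gap0 = abs(dec0(z).mean() - data_mean)
        gap1 = abs(dec1(z).mean() - data_mean)
        assert gap1 < gap0
        assert state.provenance == "parent"

    def test_both_losses_logged_every_step(self, small_dataset):
        frames = [u for u, _ in small_dataset]
        cfg = T.TrainConfig(phase="pretrain_s2u", steps=10, base_channels=8, seed=3)
        _, log = T.pretrain_s2u_parent(frames, cfg)
        assert len(log.rows) == 2 * 10
        assert len(log.values("d_loss")) == 10 and len(log.values("g_loss")) == 10

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            T.pretrain_s2u_parent([], T.TrainConfig(steps=1))


class TestFewShotSplit:
    def test_paper_protocol_ten_train_fortyfive_val(self):
        rows = list(range(55))
        split = T.few_shot_split(rows, shots=10, seed=1)
        assert len(split.train_ids) == 10 and len(split.val_ids) == 45

    def test_one_shot(self):
        split = T.few_shot_split(list(range(55)), shots=1, seed=1)
        assert len(split.train_ids) == 1

    def test_disjoint_and_deterministic(self):
        a = T.few_shot_split(list(range(20)), shots=5, seed=4)
        b = T.few_shot_split(list(range(20)), shots=5, seed=4)
        assert a == b
        assert not set(a.train_ids) & set(a.val_ids)

    def test_shots_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            T.few_shot_split(list(range(5)), shots=6, seed=0)


class TestJointTransfer:
    @pytest.fixture(scope="class")
    def trainer(self, small_dataset):
        cfg = T.TrainConfig(steps=5, base_channels=8, seed=11)
        return T.JointTrainer(small_dataset[:2], cfg)

    def test_loss_report_bookkeeping(self, trainer):
        ls, lu, tot = trainer.step()
        ls.validate()
        lu.validate(trainer.weights)
        assert tot == pytest.approx(ls.total + lu.total, abs=1e-12)

    def test_decoder_initialised_bit_exact_from_parent(self, small_dataset):
        frames = [u for u, _ in small_dataset]
        s2u, _ = T.pretrain_s2u_parent(
            frames, T.TrainConfig(phase="pretrain_s2u", steps=5, base_channels=8, seed=2)
        )
        cfg = T.TrainConfig(steps=2, base_channels=8, seed=5)
        tr = T.JointTrainer(small_dataset[:1], cfg, s2u_parent=s2u)
        got = tr.g_u.decoder.state_dict()
        assert all(np.array_equal(s2u.arrays[k], got[k]) for k in s2u.arrays)
        assert tr.g_u_decoder_provenance == "parent"

    def test_step0_losses_deterministic_across_runs(self, small_dataset):
        cfg = T.TrainConfig(steps=1, base_channels=8, seed=13)
        a = T.JointTrainer(small_dataset[:2], cfg).step()
        b = T.JointTrainer(small_dataset[:2], cfg).step()
        assert a[2] == b[2]

    def test_resume_from_snapshot_is_bit_exact(self, small_dataset):
        cfg = T.TrainConfig(steps=10, base_channels=8, seed=17)
        tr = T.JointTrainer(small_dataset[:2], cfg)
        for _ in range(3):
            tr.step()
        snap = tr.state()
        follow = [tr.step()[2] for _ in range(2)]
        tr2 = T.JointTrainer(small_dataset[:2], cfg)
        tr2.load_state(snap)
        replay = [tr2.step()[2] for _ in range(2)]
        assert follow == replay

    def test_nan_aborts_with_last_good_weights(self, small_dataset):
        cfg = T.TrainConfig(steps=4, base_channels=8, seed=19)
        split = T.FewShotSplit(train_ids=(0, 1), val_ids=())

        poisoned = [small_dataset[0], (small_dataset[1][0] * np.nan, small_dataset[1][1])]
        result = T.transfer_learn_joint(None, None, split, poisoned, cfg)
        assert result.aborted
        for name in ("g_s", "g_u_encoder", "d_s"):
            arrays = getattr(result, name).arrays
            assert all(np.isfinite(v).all() for v in arrays.values())

    def test_empty_split_rejected(self, small_dataset):
        cfg = T.TrainConfig(steps=1, base_channels=8, seed=0)
        with pytest.raises(ValueError):
            T.transfer_learn_joint(
                None, None, T.FewShotSplit((), (1,)), small_dataset, cfg
            )


class TestEvaluateCheckpoint:
    class _IdentitySketchStub:
        """Pretends to translate by returning the stored ground truth."""

        training = False

        def __init__(self, lookup):
            self.lookup = lookup

        def eval(self):
            return self

        def train(self, mode=True):
            return self

        def __call__(self, x):
            key = x.tobytes()
            return self.lookup[key][None, None]

    def test_perfect_stubs_score_perfectly(self, small_dataset):
        pairs = small_dataset[:3]
        u2s = {u[None, None].tobytes(): s for u, s in pairs}
        s2u = {s[None, None].tobytes(): u for u, s in pairs}
        rep = T.evaluate_checkpoint(
            self._IdentitySketchStub(u2s), self._IdentitySketchStub(s2u), pairs
        )
        agg = rep.aggregate
        assert agg["dice"] == 1.0 and agg["iou"] == 1.0 and agg["voe"] == 0.0
        assert agg["ssim"] == pytest.approx(1.0)
        assert agg["psnr"] == float("inf")

    def test_report_has_row_per_pair(self, small_dataset):
        pairs = small_dataset[:4]
        u2s = {u[None, None].tobytes(): s for u, s in pairs}
        s2u = {s[None, None].tobytes(): u for u, s in pairs}
        rep = T.evaluate_checkpoint(
            self._IdentitySketchStub(u2s), self._IdentitySketchStub(s2u), pairs
        )
        assert len(rep.rows) == 4
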