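"""Shape contracts, causality, and decoding behaviour of the network."""

import numpy as np
import pytest

from ocsrkit.model import ModelConfig, OCSRModel
from ocsrkit.nn.autodiff import Tensor

VOCAB = 20
START, END = 17, 18


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ModelConfig.tiny(vocab_size=VOCAB, image_size=64, max_len=16)
    return OCSRModel(cfg, seed=0).eval()


@pytest.fixture(scope="module")
def images():
    return (np.random.default_rng(0).random((2, 64, 64, 3)) < 0.1).astype(np.float32)


class TestConfig:
    def test_full_scale_feature_sequence_geometry(self):
        cfg = ModelConfig(vocab_size=79)
        assert cfg.backbone_out_len == 49        # (224 / 32)^2
        assert cfg.backbone_out_dim == 1536      # 192 * 2^3

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=79, image_size=100)

    def test_d_model_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=79, d_model=250, n_heads_transformer=8)

    def test_json_round_trip(self):
        cfg = ModelConfig.tiny(vocab_size=30)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestBackbone:
    def test_sequence_length_49_for_224_input(self):
        cfg = ModelConfig.tiny(vocab_size=VOCAB, image_size=224, window_size=7)
        model = OCSRModel(cfg, seed=0).eval()
        img = (np.random.default_rng(1).random((1, 224, 224, 3)) < 0.1)
        s_b = model.backbone_forward(img.astype(np.float32))
        assert s_b.shape == (1, 49, cfg.backbone_out_dim)

    def test_channel_doubling_per_merge(self, tiny_model, images):
        s_b = tiny_model.backbone_forward(images)
        assert s_b.shape[-1] == 48 * 8

    def test_identical_images_identical_rows(self, tiny_model, images):
        pair = np.stack([images[0], images[0]])
        s_b = tiny_model.backbone_forward(pair).data
        assert np.allclose(s_b[0], s_b[1], atol=1e-5)

    def test_distinct_inputs_distinct_features(self, tiny_model):
        zeros = np.zeros((1, 64, 64, 3), np.float32)
        ones = np.ones((1, 64, 64, 3), np.float32)
        a = tiny_model.backbone_forward(zeros).data
        b = tiny_model.backbone_forward(ones).data
        assert not np.allclose(a, b)

    def test_wrong_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(np.zeros((1, 32, 32, 3), np.float32))


class TestEncoder:
    def test_length_preserved(self, tiny_model, images):
        s_b = tiny_model.backbone_forward(images)
        s_e = tiny_model.project_and_encode(s_b)
        assert s_e.shape[:2] == s_b.shape[:2]
        assert s_e.shape[-1] == tiny_model.config.d_model

    def test_permutation_equivariance_with_matched_positions(self, tiny_model, images):
        """Permuting inputs and the positional table permutes the output."""
        s_b = tiny_model.backbone_forward(images[:1])
        length = s_b.shape[1]
        perm = np.random.default_rng(3).permutation(length)
        enc = tiny_model.encoder
        base_positions = enc.positions.copy()
        try:
            s_e = tiny_model.project_and_encode(s_b).data
            enc.positions = base_positions[perm]
            s_b_perm = Tensor(s_b.data[:, perm, :])
            s_e_perm = tiny_model.project_and_encode(s_b_perm).data
        finally:
            enc.positions = base_positions
        assert np.allclose(s_e_perm, s_e[:, perm, :], atol=1e-4)

    def test_eval_mode_deterministic(self, tiny_model, images):
        s_b = tiny_model.backbone_forward(images)
        a = tiny_model.project_and_encode(s_b).data
        b = tiny_model.project_and_encode(s_b).data
        assert np.array_equal(a, b)


class TestDecoder:
    @pytest.mark.parametrize("n_layers", [1, 2])
    def test_causality_future_token_invariance(self, images, n_layers):
        cfg = ModelConfig.tiny(vocab_size=VOCAB, image_size=64, max_len=16,
                               n_decoder_layers=n_layers)
        model = OCSRModel(cfg, seed=0).eval()
        s_e = model.project_and_encode(model.backbone_forward(images[:1]))
        a = model.decode_logits(np.array([[START, 1, 2, 3]]), s_e).data
        b = model.decode_logits(np.array([[START, 1, 2, 9]]), s_e).data
        assert np.allclose(a[:, :3], b[:, :3], atol=1e-5)
        assert not np.allclose(a[:, 3], b[:, 3])

    def test_softmax_rows_normalized(self, tiny_model, images):
        s_e = tiny_model.project_and_encode(tiny_model.backbone_forward(images))
        logits = tiny_model.decode_logits(np.array([[START, 1, 2]] * 2), s_e)
        probs = Tensor(logits.data).softmax(-1).data
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_cross_attention_sensitivity(self, tiny_model, images):
        """Zeroing the encoder memory must change the logits."""
        s_e = tiny_model.project_and_encode(tiny_model.backbone_forward(images[:1]))
        ids = np.array([[START, 1, 2]])
        with_memory = tiny_model.decode_logits(ids, s_e).data
        no_memory = tiny_model.decode_logits(ids, Tensor(np.zeros_like(s_e.data))).data
        assert not np.allclose(with_memory, no_memory)

    def test_pad_before_end_marker_rejected(self, tiny_model, images):
        s_e = tiny_model.project_and_encode(tiny_model.backbone_forward(images[:1]))
        pad = 19
        bad = np.array([[START, 1, pad, 2]])
        with pytest.raises(ValueError, match="pad"):
            tiny_model.decode_logits(bad, s_e, pad_id=pad, end_id=END)
        # pad after the end marker is ordinary right-padding and is accepted
        ok = np.array([[START, 1, END, pad]])
        tiny_model.decode_logits(ok, s_e, pad_id=pad, end_id=END)

    def test_overlong_prefix_rejected(self, tiny_model, images):
        s_e = tiny_model.project_and_encode(tiny_model.backbone_forward(images[:1]))
        with pytest.raises(ValueError):
            tiny_model.decode_logits(np.zeros((1, 17), np.int64), s_e)


class TestGreedyDecode:
    def test_stops_at_end_token_and_respects_cap(self, tiny_model, images):
        seqs = tiny_model.greedy_decode(images, START, END, max_len=10)
        assert len(seqs) == 2
        for s in seqs:
            assert len(s) <= 9  # cap minus the start marker
            assert END not in s

    def test_deterministic_in_eval_mode(self, tiny_model, images):
        a = tiny_model.greedy_decode(images, START, END, max_len=8)
        b = tiny_model.greedy_decode(images, START, END, max_len=8)
        assert a == b


class TestPersistence:
    def test_parameter_count_snapshot(self):
        model = OCSRModel(ModelConfig.tiny(vocab_size=30, image_size=64), seed=0)
        assert model.num_parameters() == 4_263_434

    def test_save_load_preserves_outputs(self, tmp_path, tiny_model, images):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        again = OCSRModel.load(path).eval()
        a = tiny_model.backbone_forward(images).data
        b = again.backbone_forward(images).data
        assert np.array_equal(a, b)

    def test_same_seed_same_init(self):
        cfg = ModelConfig.tiny(vocab_size=VOCAB, image_size=64)
        a = OCSRModel(cfg, seed=5)
        b = OCSRModel(cfg, seed=5)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)
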