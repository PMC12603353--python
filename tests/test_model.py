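"""Encoder classifier: gradients, masking, determinism, learnability."""

import math

import numpy as np
import pytest

from phastyle.model import (AdamW, EncoderClassifier, ModelConfig, TrainConfig,
                            backward, cross_entropy, forward, init_params,
                            tiny_config, train)
from phastyle.segmentation import Segment, contiguous_segments
from phastyle.sequence_io import ContigRecord, reverse_complement
from phastyle.tokenization import LCATokenizer
from phastyle.voting import predict_contig


def _tiny_cfg(**kw):
    return ModelConfig(n_layers=2, n_heads=2, hidden_dim=8, ff_dim=16,
                       vocab_size=20, max_len=10, **kw)


def _segment(seq, label=None, cid="c", start=0):
    return Segment(cid, start, start + len(seq), "+", seq, label)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        cfg = _tiny_cfg()
        rng = np.random.default_rng(1)
        params = init_params(cfg, rng, dtype=np.float64)
        for key, p in params.items():
            if "ln" not in key:
                params[key] = rng.normal(0, 0.3, p.shape)
        ids = rng.integers(4, cfg.vocab_size, size=(3, 7))
        mask = np.ones((3, 7), dtype=np.int8)
        mask[0, 5:] = 0
        ids[0, 5:] = 0
        y = np.array([0, 1, 1])

        logits, cache = forward(params, cfg, ids, mask, want_cache=True)
        loss, dlogits = cross_entropy(logits, y)
        grads = backward(params, cfg, cache, dlogits)

        eps = 1e-6
        for key in params:
            p = params[key]
            for idx in [tuple(rng.integers(0, s) for s in p.shape) for _ in range(4)]:
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = cross_entropy(forward(params, cfg, ids, mask), y)
                p[idx] = orig - eps
                lm, _ = cross_entropy(forward(params, cfg, ids, mask), y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, abs=2e-6, rel=1e-4)


@pytest.fixture(scope="module")
def small_model():
    tok = LCATokenizer(k=3, shift=1, max_len=16)
    return EncoderClassifier(
        ModelConfig(n_layers=2, n_heads=2, hidden_dim=16, ff_dim=32,
                    vocab_size=len(tok.vocab), max_len=16),
        tok, seed=0)


class TestForwardContracts:
    def test_probabilities_sum_to_one(self, small_model, rng):
        preds = small_model.predict_segments(
            [_segment("".join(rng.choice(list("ACGT"), 12))) for _ in range(5)])
        for p in preds:
            assert 0.0 <= p.p_virulent <= 1.0
            assert p.p_virulent + p.p_temperate == pytest.approx(1.0, abs=1e-6)

    def test_extra_padding_does_not_change_prediction(self, small_model):
        seq = "ACGTACGTAC"
        enc = small_model.tokenizer.encode(seq)
        short = enc.n_real_tokens + 1  # keep one PAD, then compare with full pad
        probs_a = small_model.forward_ids(enc.ids[None, :short],
                                          enc.attention_mask[None, :short])
        probs_b = small_model.forward_ids(enc.ids[None, :], enc.attention_mask[None, :])
        np.testing.assert_allclose(probs_a, probs_b, atol=1e-6)

    def test_zeroed_classifier_head_gives_half(self, small_model, rng):
        model = EncoderClassifier(small_model.config, small_model.tokenizer, seed=1)
        model.params["cls_W"][:] = 0
        model.params["cls_b"][:] = 0
        preds = model.predict_segments([_segment("ACGTACGTACGT")])
        assert preds[0].p_virulent == pytest.approx(0.5)

    def test_output_order_matches_input_order(self, small_model, rng):
        segments = [_segment("".join(rng.choice(list("ACGT"), 12)), start=17 * i)
                    for i in range(7)]
        batched = small_model.predict_segments(segments, batch_size=3)
        singly = [small_model.predict_segments([s])[0] for s in segments]
        for a, b in zip(batched, singly):
            assert a.p_virulent == pytest.approx(b.p_virulent, abs=1e-5)
            assert a.segment is b.segment

    def test_batch_size_invariance(self, small_model, rng):
        segments = [_segment("".join(rng.choice(list("ACGT"), 12)), start=17 * i)
                    for i in range(9)]
        p1 = small_model.predict_segments(segments, batch_size=1)
        p64 = small_model.predict_segments(segments, batch_size=64)
        np.testing.assert_allclose([p.p_virulent for p in p1],
                                   [p.p_virulent for p in p64], atol=1e-5)

    def test_too_short_segment_flagged_neutral(self, small_model):
        preds = small_model.predict_segments([_segment("AC"), _segment("ACGTACGT")])
        assert preds[0].flagged and preds[0].p_virulent == 0.5
        assert not preds[1].flagged

    def test_out_of_vocab_id_rejected(self, small_model):
        ids = np.full((1, 16), 1000, dtype=np.int32)
        mask = np.ones((1, 16), dtype=np.int8)
        with pytest.raises(ValueError, match="vocabulary"):
            small_model.forward_ids(ids, mask)

    def test_empty_batch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predict_segments([])


def _motif_segments(rng, n_per_class, length=90):
    """Perfectly separable toy data: class motif tiled across the segment."""
    vir, tem = "ACGTTGCAAC", "TTAACCGGTA"
    segments = []
    for i in range(n_per_class):
        for motif, label in ((vir, "virulent"), (tem, "temperate")):
            core = (motif * (length // len(motif) + 1))[:length]
            # jitter: random 5' offset into background
            pad = "".join(rng.choice(list("ACGT"), 10))
            segments.append(_segment(pad + core, label, cid=f"{label}{i}"))
    return segments


class TestTraining:
    def test_separable_data_learned(self, rng):
        segments = _motif_segments(rng, 100)
        tok = LCATokenizer(k=6, shift=3, max_len=36)
        model = EncoderClassifier(tiny_config(len(tok.vocab), max_len=36), tok, seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=4, seed=0)
        result = train(model, segments, [], cfg)
        losses = [t.train_loss for t in result.history]
        assert losses[0] > losses[1] > losses[2]
        preds = model.predict_segments(segments)
        acc = np.mean([(p.p_virulent >= 0.5) == (s.label == "virulent")
                       for p, s in zip(preds, segments)])
        assert acc >= 0.95

    def test_shuffled_labels_stay_at_chance(self, rng):
        segments = _motif_segments(rng, 60)
        labels = [s.label for s in segments]
        rng.shuffle(labels)
        shuffled = [Segment(s.contig_id, s.start, s.end, s.strand, s.seq, lab)
                    for s, lab in zip(segments, labels)]
        val = shuffled[:40]
        tok = LCATokenizer(k=6, shift=3, max_len=36)
        model = EncoderClassifier(tiny_config(len(tok.vocab), max_len=36), tok, seed=0)
        cfg = TrainConfig(learning_rate=1e-4, batch_size=16, epochs=2, seed=0)
        result = train(model, shuffled, val, cfg)
        # no learnable signal: loss sits at ln 2 and validation at chance
        assert result.history[-1].train_loss == pytest.approx(math.log(2), abs=0.05)
        assert abs(result.best_val_balanced_accuracy - 0.5) <= 0.15

    def test_identical_seed_identical_loss_trace(self, rng):
        segments = _motif_segments(rng, 20)
        tok = LCATokenizer(k=6, shift=3, max_len=36)
        traces = []
        for _ in range(2):
            model = EncoderClassifier(tiny_config(len(tok.vocab), max_len=36), tok, seed=3)
            cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=1, seed=3)
            result = train(model, segments, [], cfg)
            traces.append(result.history[0].train_loss)
        assert traces[0] == traces[1]  # bitwise identical

    def test_dropout_training_still_learns_and_inference_deterministic(self, rng):
        segments = _motif_segments(rng, 40)
        tok = LCATokenizer(k=6, shift=3, max_len=36)
        model = EncoderClassifier(
            tiny_config(len(tok.vocab), max_len=36, dropout=0.2), tok, seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=3, seed=0)
        result = train(model, segments, [], cfg)
        assert result.history[-1].train_loss < result.history[0].train_loss
        a = model.predict_segments(segments[:4])
        b = model.predict_segments(segments[:4])  # no dropout at inference
        assert [p.p_virulent for p in a] == [p.p_virulent for p in b]

    def test_single_class_training_rejected(self, rng):
        segments = [s for s in _motif_segments(rng, 5) if s.label == "virulent"]
        tok = LCATokenizer(k=6, shift=3, max_len=36)
        model = EncoderClassifier(tiny_config(len(tok.vocab), max_len=36), tok, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, segments, [], TrainConfig())


class TestPersistence:
    def test_save_load_roundtrip(self, small_model, rng, tmp_path):
        segments = [_segment("".join(rng.choice(list("ACGT"), 12)))]
        before = small_model.predict_segments(segments)[0].p_virulent
        small_model.save(tmp_path / "model")
        loaded = EncoderClassifier.load(tmp_path / "model")
        after = loaded.predict_segments(segments)[0].p_virulent
        assert before == pytest.approx(after, abs=1e-7)
        assert loaded.tokenizer.settings() == small_model.tokenizer.settings()


class TestContigPrediction:
    def test_strand_symmetry_exact(self, small_model, rng):
        seq = "".join(rng.choice(list("ACGT"), 1100))
        rec = ContigRecord("x", seq)
        rc_rec = ContigRecord("x", reverse_complement(seq))
        a = predict_contig(small_model, rec, segment_len=512)
        b = predict_contig(small_model, rc_rec, segment_len=512)
        assert a.p_virulent == b.p_virulent  # exactly equal

    def test_tiling_counts(self, small_model, rng):
        seq = "".join(rng.choice(list("ACGT"), 1024))
        rec = ContigRecord("x", seq)
        both = predict_contig(small_model, rec, segment_len=512, both_strands=True)
        single = predict_contig(small_model, rec, segment_len=512, both_strands=False)
        assert single.n_segments == 2
        assert both.n_segments == 4
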