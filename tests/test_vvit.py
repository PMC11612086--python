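"""Core transformer: sequence splitting, patchify, encoder, heads, voting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sectorvit import nn
from sectorvit.vvit import (ProbabilityTensor, SectorSpec, VvitConfig, VvitModel,
                            encoder_forward, n_patches, patchify, predict_binary,
                            split_sequence, vote)

from .oracles import oracle_encoder

TINY = VvitConfig(patch_dim=4, head_dim=3, n_heads=2, mlp_dim=8, depth=1,
                  embed_dim=6, head_hidden_layers=2)


def make_model(sectors, cfg=TINY, seed=0):
    return VvitModel(sectors, cfg, seed=seed, dtype=np.float64)


class TestSplitSequence:
    def test_direct_split(self):
        out = split_sequence(np.arange(5), [SectorSpec("a", 2), SectorSpec("b", 3)])
        np.testing.assert_array_equal(out["a"], [0, 1])
        np.testing.assert_array_equal(out["b"], [2, 3, 4])

    def test_class_token_sector_is_empty(self):
        out = split_sequence(np.arange(5), [SectorSpec("cls", 0), SectorSpec("b", 5)])
        assert out["cls"].size == 0
        np.testing.assert_array_equal(out["b"], np.arange(5))

    def test_length_mismatch_names_sectors(self):
        with pytest.raises(ValueError, match="sector"):
            split_sequence(np.arange(4), [SectorSpec("a", 2), SectorSpec("b", 3)])

    @given(st.lists(st.integers(min_value=0, max_value=7), min_size=1, max_size=6),
           st.integers(0, 2 ** 31 - 1))
    def test_roundtrip(self, lengths, seed):
        specs = [SectorSpec(f"s{i}", a) for i, a in enumerate(lengths)]
        x = np.random.default_rng(seed).normal(size=sum(lengths))
        parts = split_sequence(x, specs)
        np.testing.assert_array_equal(
            np.concatenate([parts[s.name] for s in specs]), x)


class TestPatchify:
    @pytest.mark.parametrize("length,patch,expected", [
        (3, 32, 1),       # demographics: one zero-padded patch
        (16384, 32, 512),  # flattened 128x128 image
        (0, 32, 0),       # class-token sector
    ])
    def test_patch_counts(self, length, patch, expected):
        assert n_patches(length, patch) == expected

    def test_zero_padding(self):
        p = patchify(np.ones((2, 3)), 4)
        assert p.shape == (2, 1, 4)
        np.testing.assert_array_equal(p[:, 0, 3], 0.0)

    def test_token_counts_through_model(self):
        # 1 patch + class token = 2 tokens; length-0 sector = class token only
        m = make_model([SectorSpec("cls", 0), SectorSpec("demo", 3)])
        assert m.params["demo.pos"].shape[0] == 2
        assert m.params["cls.pos"].shape[0] == 1


class TestVote:
    def test_mean_of_two(self):
        np.testing.assert_allclose(vote([np.array([0.2, 0.8]), np.array([0.6, 0.4])]),
                                   [0.4, 0.6])

    def test_idempotent_on_identical(self):
        p = np.array([0.3, 0.7])
        np.testing.assert_allclose(vote([p] * 5), p)

    def test_matches_bruteforce_mean(self, rng):
        vs = [rng.dirichlet(np.ones(2)) for _ in range(8)]
        np.testing.assert_allclose(vote(vs), sum(vs) / 8, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vote([])

    def test_tie_break_positive(self):
        assert predict_binary(np.array([[0.5, 0.5]]))[0] == 1


class TestHeadsAndProbs:
    def test_zero_parameters_give_uniform_probs(self):
        m = make_model([SectorSpec("a", 3)])
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        # layer norm gains zeroed too -> all activations zero -> logits zero
        pt = m.forward({"a": np.ones((2, 3))})
        np.testing.assert_allclose(pt.per_sector["a"], 0.5, atol=1e-12)

    def test_softmax_closed_form(self):
        p = nn.softmax(np.array([np.log(3.0), 0.0]))
        np.testing.assert_allclose(p, [0.75, 0.25], atol=1e-12)

    def test_probs_normalized_and_positive(self, rng):
        m = make_model([SectorSpec("a", 5), SectorSpec("b", 0)])
        pt = m.forward({"a": rng.normal(size=(4, 5)), "b": np.zeros((4, 0))})
        for probs in list(pt.per_sector.values()) + [pt.voted]:
            assert (probs > 0).all()
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEncoder:
    def test_single_token_attention_is_identity_weight(self):
        # with one token the softmax over a 1x1 score is exactly 1
        m = make_model([SectorSpec("cls", 0)], seed=3)
        tokens, _ = m._sector_tokens("cls", np.zeros((1, 0)))
        out = encoder_forward(tokens, m.params, "cls.", m.config)
        ref = oracle_encoder(tokens[0], m.params, "cls.", m.config)
        np.testing.assert_allclose(out[0], ref, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = VvitConfig(patch_dim=3, head_dim=1 + seed % 3, n_heads=1 + seed % 2,
                         mlp_dim=5, depth=1 + seed % 2, embed_dim=4,
                         head_hidden_layers=1)
        m = VvitModel([SectorSpec("s", 7)], cfg, seed=seed, dtype=np.float64)
        tokens = rng.normal(size=(1, 4, cfg.embed_dim))
        out = encoder_forward(tokens, m.params, "s.", cfg)
        ref = oracle_encoder(tokens[0], m.params, "s.", cfg)
        np.testing.assert_allclose(out[0], ref, atol=1e-6)

    def test_class_output_equivariant_to_token_permutation(self, rng):
        """Permuting non-class tokens (self-attention is set-equivariant)
        leaves the class-token output unchanged."""
        m = make_model([SectorSpec("s", 8)], seed=5)
        tokens, _ = m._sector_tokens("s", rng.normal(size=(1, 8)))
        out = encoder_forward(tokens, m.params, "s.", m.config)[0, 0]
        perm = np.array([0, 2, 1])  # keep class token first
        out_p = encoder_forward(tokens[:, perm], m.params, "s.", m.config)[0, 0]
        np.testing.assert_allclose(out, out_p, atol=1e-10)

    def test_forward_deterministic(self, rng):
        m = make_model([SectorSpec("a", 5)])
        x = {"a": rng.normal(size=(3, 5))}
        p1 = m.forward(x).voted
        p2 = m.forward(x).voted
        np.testing.assert_array_equal(p1, p2)


class TestGradients:
    @pytest.mark.parametrize("loss_mode", ["voted", "per_sector_sum"])
    def test_finite_difference_gradient_check(self, loss_mode, rng):
        cfg = VvitConfig(patch_dim=4, head_dim=4, n_heads=2, mlp_dim=8, depth=1,
                         embed_dim=8, head_hidden_layers=4)
        sectors = [SectorSpec("cls", 0), SectorSpec("a", 3), SectorSpec("b", 5)]
        m = VvitModel(sectors, cfg, seed=1, dtype=np.float64)
        batch = {"cls": np.zeros((4, 0)), "a": rng.normal(size=(4, 3)),
                 "b": rng.normal(size=(4, 5))}
        y = np.array([0.0, 1.0, 1.0, 0.0])
        _, grads, _ = m.loss_and_grads(batch, y, loss_mode=loss_mode)
        h = 1e-6
        check_rng = np.random.default_rng(7)
        for key, p in m.params.items():
            g = np.asarray(grads.get(key))
            flat = p.reshape(-1)
            for idx in check_rng.choice(p.size, size=min(4, p.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _, _ = m.loss_and_grads(batch, y, loss_mode=loss_mode)
                flat[idx] = orig - h
                lm, _, _ = m.loss_and_grads(batch, y, loss_mode=loss_mode)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                ga = g.reshape(-1)[idx]
                assert abs(fd - ga) <= 1e-4 * max(1.0, abs(fd), abs(ga)), \
                    f"{key}[{idx}]: fd={fd} analytic={ga}"


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        m = make_model([SectorSpec("a", 5), SectorSpec("cls", 0)])
        path = tmp_path / "ckpt.npz"
        m.save(path)
        m2 = VvitModel.load(path)
        x = {"a": rng.normal(size=(2, 5)), "cls": np.zeros((2, 0))}
        np.testing.assert_array_equal(m.forward(x).voted, m2.forward(x).voted)
        assert [s.name for s in m2.sectors] == ["a", "cls"]

    def test_inference_validates_input_lengths(self, rng):
        m = make_model([SectorSpec("a", 5)])
        with pytest.raises(ValueError, match="expected length"):
            m.forward({"a": rng.normal(size=(2, 4))})

    def test_full_sector_layout_produces_eight_normalized_vectors(self, rng):
        """The full eight-sector layout: every sector emits a normalized
        probability vector and the voted output is their mean."""
        lengths = {"class_token": 0, "demographics": 3, "comorbidity": 3,
                   "habit": 2, "surgical": 6, "radiomic": 32,
                   "tumor": 64, "kidney_tumor": 64}  # reduced image lengths
        sectors = [SectorSpec(k, v) for k, v in lengths.items()]
        m = make_model(sectors)
        batch = {k: rng.normal(size=(2, v)) for k, v in lengths.items()}
        pt = m.forward(batch)
        assert len(pt.per_sector) == 8
        np.testing.assert_allclose(pt.voted.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(
            pt.voted, np.mean(list(pt.per_sector.values()), axis=0), atol=1e-12)
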