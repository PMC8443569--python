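"""Network components against independent brute-force oracles."""

import numpy as np
import pytest

from peppi.exceptions import ConfigurationError, InvalidInputError
from peppi.featurization import FeatureProviders, SequenceRecord, build_profile
from peppi.network import (
    AttentionWeights,
    ModelParams,
    PairSample,
    ResidueHeadWeights,
    attend,
    attention_pool,
    binary_head,
    channel_embed,
    conv_features,
    forward,
    init_params,
    masked_max_pool,
    residue_scores,
)

# ---------------------------------------------------------------------------
# oracles


def naive_conv1d(X, W, b):
    """Sliding-window dot-product convolution with 'same' zero padding."""
    L, C_in = X.shape
    C_out, k, _ = W.shape
    pad = k // 2
    Xp = np.vstack([np.zeros((pad, C_in)), X, np.zeros((pad, C_in))])
    out = np.zeros((L, C_out))
    for i in range(L):
        for o in range(C_out):
            acc = b[o]
            for j in range(k):
                acc += float(Xp[i + j] @ W[o, j])
            out[i, o] = acc
    return out


def naive_attention(U, Wq, Wk, Wv, mask):
    """Double-loop scaled dot-product attention over unmasked keys."""
    N = U.shape[0]
    dk = Wq.shape[0]
    q = np.array([Wq @ U[i] for i in range(N)])
    k = np.array([Wk @ U[i] for i in range(N)])
    v = np.array([Wv @ U[i] for i in range(N)])
    G = np.zeros((N, dk))
    for i in range(N):
        logits = np.array(
            [q[i] @ k[j] / np.sqrt(dk) if mask[j] else -np.inf for j in range(N)]
        )
        w = np.exp(logits - logits[mask == 1].max())
        w = w / w.sum()
        for j in range(N):
            G[i] += w[j] * v[j]
    return G


# ---------------------------------------------------------------------------


class TestChannelEmbed:
    def test_all_padding_rows_are_zero(self, peptide_profile, micro_params):
        U = channel_embed(peptide_profile, micro_params, "peptide")
        assert np.all(U[peptide_profile.mask == 0] == 0.0)

    def test_masked_positions_do_not_affect_output(self, peptide_profile, micro_params):
        import copy

        other = copy.deepcopy(peptide_profile)
        # profiles keep padded rows zero by contract; bypass it to prove masking
        other.aa_codes = other.aa_codes.copy()
        other.aa_codes[other.mask == 0] = 5
        a = channel_embed(peptide_profile, micro_params, "peptide")
        b = channel_embed(other, micro_params, "peptide")
        assert np.array_equal(a, b)

    def test_hand_set_tables_reproduce_code_pattern(self, micro_arch, peptide_profile):
        params = init_params(micro_arch, seed=0)
        d = micro_arch.embed_dim
        table = np.zeros_like(params.arrays["pep_emb_aa"])
        table[:, 0] = np.arange(table.shape[0])  # embedding = the code itself
        params.arrays["pep_emb_aa"] = table
        params.arrays["pep_num_W"][:] = 0.0
        params.arrays["pep_num_b"][:] = 0.0
        U = channel_embed(peptide_profile, params, "peptide")
        assert np.array_equal(U[:, 0], peptide_profile.aa_codes.astype(float))

    def test_role_mismatch_rejected(self, peptide_profile, micro_params):
        with pytest.raises(InvalidInputError):
            channel_embed(peptide_profile, micro_params, "protein")


class TestConvFeatures:
    def test_zero_input_zero_output_with_zero_biases(self, micro_arch):
        params = init_params(micro_arch, seed=1)  # biases init to zero
        U = np.zeros((10, micro_arch.channel_dim))
        H = conv_features(U, params, "peptide")
        assert np.all(H == 0.0)

    def test_matches_naive_sliding_window_oracle(self, micro_params, micro_arch, rng):
        U = rng.normal(size=(12, micro_arch.channel_dim))
        H = conv_features(U, micro_params, "peptide")
        X = U
        for i in (1, 2, 3):
            W = micro_params.arrays[f"pep_conv{i}_W"]
            b = micro_params.arrays[f"pep_conv{i}_b"]
            X = np.maximum(naive_conv1d(X, W, b), 0.0)
        np.testing.assert_allclose(H, X, atol=1e-6)

    def test_nonnegative_after_final_relu(self, micro_params, micro_arch, rng):
        U = rng.normal(size=(9, micro_arch.channel_dim))
        assert conv_features(U, micro_params, "protein" if False else "peptide").min() >= 0.0

    def test_too_short_input_rejected(self, micro_params, micro_arch):
        U = np.zeros((2, micro_arch.channel_dim))
        with pytest.raises(InvalidInputError):
            conv_features(U, micro_params, "peptide")


class TestMaskedMaxPool:
    def test_single_row_identity(self, rng):
        H = rng.normal(size=(1, 5))
        assert np.array_equal(masked_max_pool(H, np.array([1])), H[0])

    def test_padding_rows_ignored(self, rng):
        H = rng.normal(size=(6, 4))
        mask = np.array([1, 1, 1, 0, 0, 0])
        H2 = H.copy()
        H2[3:] = 1e9
        assert np.array_equal(masked_max_pool(H, mask), masked_max_pool(H2, mask))

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            L, C = int(rng.integers(2, 10)), int(rng.integers(1, 6))
            H = rng.normal(size=(L, C))
            mask = (rng.random(L) < 0.7).astype(int)
            if mask.sum() == 0:
                mask[0] = 1
            expected = np.array([max(H[i, c] for i in range(L) if mask[i]) for c in range(C)])
            np.testing.assert_allclose(masked_max_pool(H, mask), expected)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            masked_max_pool(rng.normal(size=(3, 2)), np.zeros(3, dtype=int))


class TestAttend:
    def test_single_token_returns_its_value_vector(self, rng):
        d, dk = 4, 3
        w = AttentionWeights(*(rng.normal(size=(dk, d)) for _ in range(3)))
        U = rng.normal(size=(1, d))
        np.testing.assert_allclose(attend(U, w), (U @ w.W_v.T), atol=1e-12)

    def test_zero_query_projection_gives_uniform_mean(self, rng):
        d, dk, N = 4, 3, 6
        w = AttentionWeights(
            np.zeros((dk, d)), rng.normal(size=(dk, d)), rng.normal(size=(dk, d))
        )
        U = rng.normal(size=(N, d))
        G = attend(U, w)
        v = U @ w.W_v.T
        for i in range(N):
            np.testing.assert_allclose(G[i], v.mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_double_loop_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        N, d, dk = 5, 4, 3
        U = rng.normal(size=(N, d))
        w = AttentionWeights(*(rng.normal(size=(dk, d)) for _ in range(3)))
        mask = (rng.random(N) < 0.8).astype(int)
        if mask.sum() == 0:
            mask[0] = 1
        G = attend(U, w, mask)
        expected = naive_attention(U, w.W_q, w.W_k, w.W_v, mask)
        np.testing.assert_allclose(G, expected, atol=1e-6)

    def test_all_masked_rejected(self, rng):
        w = AttentionWeights(*(rng.normal(size=(2, 3)) for _ in range(3)))
        with pytest.raises(InvalidInputError):
            attend(rng.normal(size=(3, 3)), w, np.zeros(3, dtype=int))


class TestAttentionPool:
    def test_single_unmasked_row(self, rng):
        G = rng.normal(size=(4, 3))
        mask = np.array([0, 1, 0, 0])
        np.testing.assert_allclose(attention_pool(G, mask), G[1])

    def test_identical_rows(self):
        G = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        np.testing.assert_allclose(attention_pool(G, np.ones(5, dtype=int)), [1, 2, 3])

    def test_matches_masked_mean_oracle(self, rng):
        G = rng.normal(size=(7, 4))
        mask = np.array([1, 0, 1, 1, 0, 1, 1])
        expected = G[mask == 1].mean(axis=0)
        np.testing.assert_allclose(attention_pool(G, mask), expected, atol=1e-12)


class TestBinaryHead:
    def _zeroed(self, micro_arch):
        params = init_params(micro_arch, seed=0)
        for k in ("fc1_W", "fc1_b", "fc2_W", "fc2_b", "fc3_W", "fc3_b"):
            params.arrays[k][:] = 0.0
        return params

    def test_zero_weights_give_half(self, micro_arch):
        params = self._zeroed(micro_arch)
        C, dk = micro_arch.conv_filters[-1], micro_arch.attention_dim
        p = binary_head(np.ones(C), np.ones(C), np.ones(dk), np.ones(dk), params)
        assert p == pytest.approx(0.5)

    def test_eval_mode_deterministic(self, micro_params, micro_arch, rng):
        C, dk = micro_arch.conv_filters[-1], micro_arch.attention_dim
        args = (rng.normal(size=C), rng.normal(size=C), rng.normal(size=dk), rng.normal(size=dk))
        assert binary_head(*args, micro_params) == binary_head(*args, micro_params)

    def test_hand_computed_composition(self):
        """1-unit layers: sigma(w3*relu(w2*relu(w1*x+b1)+b2)+b3)."""
        from peppi.network import ArchitectureConfig

        arch = ArchitectureConfig(
            embed_dim=1, conv_filters=(1, 1, 1), conv_kernels=(1, 1, 1),
            attention_dim=1, fc_sizes=(1, 1), dropout=0.0,
        )
        params = init_params(arch, seed=0)
        params.arrays["fc1_W"][:] = 0.5
        params.arrays["fc1_b"][:] = 0.1
        params.arrays["fc2_W"][:] = -2.0
        params.arrays["fc2_b"][:] = 1.0
        params.arrays["fc3_W"][:] = 3.0
        params.arrays["fc3_b"][:] = -0.2
        x = np.array([0.3, -0.4, 0.2, 0.1])  # z = concat of 4 one-dim inputs
        h1 = max(0.0, 0.5 * x.sum() + 0.1)
        h2 = max(0.0, -2.0 * h1 + 1.0)
        expected = 1.0 / (1.0 + np.exp(-(3.0 * h2 - 0.2)))
        got = binary_head(x[:1], x[1:2], x[2:3], x[3:4], params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_dim_mismatch_rejected(self, micro_params):
        with pytest.raises(ConfigurationError):
            binary_head(np.ones(2), np.ones(2), np.ones(2), np.ones(2), micro_params)


class TestResidueScores:
    def test_zero_weights_give_half_everywhere(self, rng):
        H = rng.normal(size=(8, 5))
        w = ResidueHeadWeights(np.zeros(5), 0.0)
        np.testing.assert_allclose(residue_scores(H, w), 0.5)

    def test_aligned_hot_position_scores_highest(self):
        H = np.zeros((6, 3))
        H[2] = [5.0, 0, 0]
        w = ResidueHeadWeights(np.array([1.0, 0, 0]), 0.0)
        s = residue_scores(H, w)
        assert s.argmax() == 2 and s[2] > s.max(initial=0, where=np.arange(6) != 2)

    def test_matches_scalar_product_oracle(self, rng):
        H = rng.normal(size=(7, 4))
        w = ResidueHeadWeights(rng.normal(size=4), 0.3)
        expected = np.array([1 / (1 + np.exp(-(w.W_pep @ h + w.c))) for h in H])
        np.testing.assert_allclose(residue_scores(H, w), expected, atol=1e-6)


class TestForward:
    def test_eval_mode_bit_stable(self, peptide_profile, protein_profile, micro_params):
        s = PairSample(peptide_profile, protein_profile, 1)
        p1, r1 = forward(s, micro_params)
        p2, r2 = forward(s, micro_params)
        assert p1 == p2 and np.array_equal(r1, r2)

    def test_outputs_strictly_in_unit_interval(self, peptide_profile, protein_profile, micro_params):
        p, r = forward(PairSample(peptide_profile, protein_profile, 0), micro_params)
        assert 0.0 < p < 1.0
        assert np.all((r > 0.0) & (r < 1.0))

    def test_invariant_to_trailing_padding(self, peptide_record, protein_record, micro_params):
        prov = FeatureProviders(seed=0)
        s50 = PairSample(
            build_profile(peptide_record, prov, pad_len=50),
            build_profile(protein_record, prov, pad_len=80),
            1,
        )
        s64 = PairSample(
            build_profile(peptide_record, prov, pad_len=64),
            build_profile(protein_record, prov, pad_len=96),
            1,
        )
        p1, r1 = forward(s50, micro_params)
        p2, r2 = forward(s64, micro_params)
        n = s50.peptide.true_length
        assert p1 == pytest.approx(p2, abs=1e-9)
        np.testing.assert_allclose(r1[:n], r2[:n], atol=1e-9)

    def test_composition_matches_component_oracles(self, micro_params, micro_arch):
        """The full forward equals the chained single-sample components."""
        prov = FeatureProviders(seed=1)
        pep = build_profile(SequenceRecord("p", "peptide", "ACDEFGHW"), prov, pad_len=8)
        pro = build_profile(
            SequenceRecord("q", "protein", "ACDEFGHIKLMNPQRSTVWY" * 3), prov, pad_len=60
        )
        sample = PairSample(pep, pro, 1)
        p, r = forward(sample, micro_params)

        U_pep = channel_embed(pep, micro_params, "peptide")
        U_pro = channel_embed(pro, micro_params, "protein")
        H_pep = conv_features(U_pep, micro_params, "peptide")
        H_pro = conv_features(U_pro, micro_params, "protein")
        pep_cnn = masked_max_pool(H_pep, pep.mask)
        pro_cnn = masked_max_pool(H_pro, pro.mask)
        G_pep = attend(U_pep, micro_params.attention_weights("peptide"), pep.mask)
        G_pro = attend(U_pro, micro_params.attention_weights("protein"), pro.mask)
        pep_att = attention_pool(G_pep, pep.mask)
        pro_att = attention_pool(G_pro, pro.mask)
        expected_p = binary_head(pep_cnn, pro_cnn, pep_att, pro_att, micro_params)
        expected_r = residue_scores(H_pep, micro_params.residue_head())
        assert p == pytest.approx(expected_p, abs=1e-9)
        np.testing.assert_allclose(r, expected_r, atol=1e-9)

    def test_attention_rows_sum_to_one_over_unmasked(self, micro_params, rng):
        from peppi.network import _attention_forward

        U = rng.normal(size=(2, 9, micro_params.arch.channel_dim))
        mask = np.ones((2, 9), dtype=int)
        mask[0, 6:] = 0
        G, cache = _attention_forward(U, micro_params, "pep", mask)
        A = cache["A"]
        np.testing.assert_allclose(A.sum(axis=2), 1.0, atol=1e-9)
        # no weight on masked keys
        assert np.all(A[0, :, 6:] == 0.0)


class TestModelParams:
    def test_parameter_count_deterministic_in_config(self, micro_arch):
        a = init_params(micro_arch, seed=0)
        b = init_params(micro_arch, seed=99)
        assert a.n_parameters() == b.n_parameters()

    def test_embedding_row_zero_frozen(self, micro_params):
        for name, arr in micro_params.arrays.items():
            if "_emb_" in name:
                assert np.all(arr[0] == 0.0)
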