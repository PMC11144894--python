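"""Soft-mask encoder: masks, masked updates, readout and gating."""

import numpy as np
import pytest

from masmddi import autodiff as ad
from masmddi.chem_io import MolecularGraph, normalize_features, parse_smiles
from masmddi.encoder import (
    EncoderConfig,
    compute_soft_mask,
    encode_drug,
    init_encoder_params,
    init_node_states,
    masmg_layer,
    readout,
)


def _random_graph(rng, n, d_in=55, p_edge=0.4):
    """Synthetic molecular-graph container with random features/topology."""
    feats = rng.normal(size=(n, d_in))
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p_edge]
    return MolecularGraph(feats, edges, "synthetic")


def _delete_nodes(graph, removed):
    keep = [i for i in range(graph.n) if i not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    edges = [(remap[u], remap[v]) for u, v in graph.edges
             if u in remap and v in remap]
    return MolecularGraph(graph.node_features[keep], edges, graph.smiles)


def _encode_values(graph, params, config, clamp=None):
    with ad.no_grad():
        per_layer, state = encode_drug(graph, params, config, clamp=clamp)
    return np.stack([t.value for t in per_layer]), state


@pytest.fixture()
def small_setup(rng):
    config = EncoderConfig(input_dim=55, n_layers=3, hidden_dim=8)
    params = init_encoder_params(config, rng)
    return config, params


def test_zero_parameters_give_mask_half_everywhere(small_setup, rng):
    """With all weights and biases zero the mask logit is 0, so m = 0.5."""
    config, params = small_setup
    for p in params.values():
        p.value = np.zeros_like(p.value)
    g = _random_graph(rng, 6)
    h0, m0 = init_node_states(g, params)
    m = compute_soft_mask(h0, m0, ad.constant(g.adjacency()), params, 0)
    assert np.allclose(m.value, 0.5)


def test_masks_lie_strictly_inside_unit_interval(small_setup, rng):
    config, params = small_setup
    for _ in range(10):
        g = _random_graph(rng, int(rng.integers(2, 10)))
        _, state = _encode_values(g, params, config)
        computed = state.masks[:, 1:]
        assert np.all(computed > 0.0) and np.all(computed < 1.0)


def test_soft_mask_matches_hand_computation_on_two_node_path():
    """d = d_m = 1 with hand-set weights: scalar arithmetic oracle."""
    config = EncoderConfig(input_dim=1, n_layers=1, hidden_dim=1, mask_dim=1)
    params = init_encoder_params(config, np.random.default_rng(0))
    values = {
        "input_W": [[1.0]], "input_b": [0.0],
        "enc0_I1_W": [[2.0]], "enc0_I2_W": [[-1.0]],
        "enc0_mask_W1": [[0.5], [0.25]], "enc0_mask_b1": [0.1],
        "enc0_mask_W2": [[1.5]], "enc0_mask_b2": [-0.2],
    }
    for k, v in values.items():
        params[k].value = np.array(v, dtype=float)
    g = MolecularGraph(np.array([[2.0], [3.0]]), [(0, 1)], "synthetic")
    h0, m0 = init_node_states(g, params)
    m = compute_soft_mask(h0, m0, ad.constant(g.adjacency()), params, 0)

    def oracle(h_self, h_nbr):
        pre = np.array([max(2.0 * h_self, 0.0), max(-1.0 * h_nbr, 0.0)])
        hidden = max(pre @ np.array([0.5, 0.25]) + 0.1, 0.0)
        return 1.0 / (1.0 + np.exp(-(1.5 * hidden - 0.2)))

    assert m.value[0, 0] == pytest.approx(oracle(2.0, 3.0), abs=1e-12)
    assert m.value[1, 0] == pytest.approx(oracle(3.0, 2.0), abs=1e-12)


def test_zero_mask_zeroes_the_node_row(small_setup, rng):
    config, params = small_setup
    g = _random_graph(rng, 5)
    h0, _ = init_node_states(g, params)
    m = ad.constant(np.array([[1.0], [0.0], [1.0], [0.5], [1.0]]))
    h1 = masmg_layer(h0, m, ad.constant(g.adjacency()), params, 0)
    assert np.allclose(h1.value[1], 0.0)
    assert np.all(h1.value >= 0.0)  # ReLU output gated by nonnegative mask


def test_isolated_node_update_hand_value():
    """Single node, d=1, W=[1,1]ᵀ, m=1, h=2 → ReLU(1·2 + 0) = 2."""
    config = EncoderConfig(input_dim=1, n_layers=1, hidden_dim=1)
    params = init_encoder_params(config, np.random.default_rng(0))
    params["enc0_W"].value = np.array([[1.0], [1.0]])
    h = ad.constant(np.array([[2.0]]))
    m = ad.constant(np.array([[1.0]]))
    out = masmg_layer(h, m, ad.constant(np.zeros((1, 1))), params, 0)
    assert out.value[0, 0] == pytest.approx(2.0)


def test_readout_is_column_sum():
    h = ad.constant(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
    assert np.array_equal(readout(h).value, [2.0, 4.0])


def test_encoding_invariant_under_node_permutation(small_setup, rng):
    config, params = small_setup
    for _ in range(5):
        g = _random_graph(rng, 8)
        perm = rng.permutation(8)
        inv = np.argsort(perm)  # new index of original node u is inv[u]
        permuted = MolecularGraph(
            g.node_features[perm],
            [(int(inv[u]), int(inv[v])) for u, v in g.edges],
            g.smiles)
        a, _ = _encode_values(g, params, config)
        b, _ = _encode_values(permuted, params, config)
        np.testing.assert_allclose(a, b, atol=1e-6)


def test_clamped_subset_equals_deleted_subgraph(small_setup, rng):
    """Zero masks make nodes invisible: the formal subgraph property."""
    config, params = small_setup
    g = _random_graph(rng, 9)
    removed = {2, 5}
    clamp = {(u, k) for u in removed for k in range(config.n_layers + 1)}
    clamped, _ = _encode_values(g, params, config, clamp=clamp)
    deleted, _ = _encode_values(_delete_nodes(g, removed), params, config)
    np.testing.assert_allclose(clamped, deleted, atol=1e-6)


def test_single_layer_yields_single_vector(small_setup, rng):
    config = EncoderConfig(input_dim=55, n_layers=1, hidden_dim=8)
    params = init_encoder_params(config, rng)
    g = _random_graph(rng, 4)
    per_layer, state = encode_drug(g, params, config)
    assert len(per_layer) == 1
    assert state.masks.shape == (4, 2)


def test_initial_masks_are_ones_and_zero_features_propagate_zero(small_setup, rng):
    config, params = small_setup
    params["input_b"].value = np.zeros_like(params["input_b"].value)
    g = MolecularGraph(np.zeros((4, 55)), [(0, 1), (1, 2)], "synthetic")
    h0, m0 = init_node_states(g, params)
    assert np.allclose(m0.value, 1.0)
    assert np.allclose(h0.value, 0.0)
    seq, _ = _encode_values(g, params, config)
    assert np.allclose(seq, 0.0)  # monotone zero-propagation, zero biases aside


def test_encode_is_bitwise_deterministic(rng):
    config = EncoderConfig(input_dim=55, n_layers=2, hidden_dim=8)
    g = _random_graph(np.random.default_rng(5), 7)
    a = _encode_values(g, init_encoder_params(config, np.random.default_rng(11)), config)[0]
    b = _encode_values(g, init_encoder_params(config, np.random.default_rng(11)), config)[0]
    assert np.array_equal(a, b)


def test_mismatched_feature_width_is_configuration_error(small_setup):
    config, params = small_setup
    g = MolecularGraph(np.zeros((3, 10)), [], "synthetic")
    with pytest.raises(ValueError, match="projection"):
        init_node_states(g, params)
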