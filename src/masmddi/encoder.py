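"""Multi-layer adaptive soft-mask graph encoder.

Each of the K stacked layers computes, per atom ``u``:

* a soft mask ``m_u ∈ (0,1)`` from a sigmoid-terminated two-layer
  perceptron over ReLU(concat(I1(m'·h'_u), Σ_{s∈N(u)} I2(m'_s·h'_s)))
  where primes denote the previous layer;
* the masked update ``h_u ← m_u · ReLU(W·concat(m_u·h'_u, Σ m_s·h'_s))``.

The outer multiplication by ``m_u`` makes the skipping property exact:
a node whose mask is (clamped to) zero contributes nothing, so masking a
node subset to zero at every layer reproduces the encoding of the graph
with that subset deleted.  A SUM readout after every layer yields one
graph-level vector per layer — the drug's substructure sequence, the
unit all downstream attention operates on.

Masks are kept per node and per layer (:class:`MaskState`) so that the
substructures the encoder attends to can be inspected after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_io import MolecularGraph

__all__ = [
    "EncoderConfig",
    "MaskState",
    "SubstructureSequence",
    "init_encoder_params",
    "init_node_states",
    "compute_soft_mask",
    "masmg_layer",
    "readout",
    "encode_drug",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture knobs of the encoder.

    ``n_layers`` (K) controls the depth / number of substructure views;
    ``hidden_dim`` (D) the embedding width; ``mask_dim`` the width of the
    I1/I2 maps feeding the mask perceptron (defaults to D).
    """

    input_dim: int = 55
    n_layers: int = 4
    hidden_dim: int = 128
    mask_dim: int | None = None

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")

    @property
    def d_m(self) -> int:
        return self.mask_dim if self.mask_dim is not None else self.hidden_dim


@dataclass
class MaskState:
    """Per-node, per-layer masks of one encoded graph.

    ``masks`` has shape (n_atoms, K+1); column 0 is the initial mask
    (all ones unless clamped).  ``clamped`` maps a layer index in
    0..K to the set of node indices forced to zero at that layer.
    """

    masks: np.ndarray
    clamped: dict[int, set[int]] = field(default_factory=dict)

    def to_rows(self, graph_id: str) -> list[tuple[str, int, int, float]]:
        """Rows ``(graph_id, node, layer, mask)`` for the TSV mask dump."""
        n, k1 = self.masks.shape
        return [(graph_id, u, k, float(self.masks[u, k]))
                for u in range(n) for k in range(k1)]


@dataclass
class SubstructureSequence:
    """The K per-layer graph-level embeddings of one drug."""

    per_layer: list[np.ndarray]

    @property
    def concatenated(self) -> np.ndarray:
        """Jump concatenation of all layers (export only; the attention
        and scoring stages consume ``per_layer`` directly)."""
        return np.concatenate(self.per_layer)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_params(config: EncoderConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-uniform weights, zero biases; layers are not parameter-shared."""
    d, dm = config.hidden_dim, config.d_m
    params: dict[str, Tensor] = {
        "input_W": ad.parameter(_glorot(rng, config.input_dim, d)),
        "input_b": ad.parameter(np.zeros(d)),
    }
    for k in range(config.n_layers):
        params[f"enc{k}_W"] = ad.parameter(_glorot(rng, 2 * d, d))
        # I1/I2 carry no bias: a per-neighbour bias would survive a zero
        # mask and break the exact node-deletion property of the masks.
        params[f"enc{k}_I1_W"] = ad.parameter(_glorot(rng, d, dm))
        params[f"enc{k}_I2_W"] = ad.parameter(_glorot(rng, d, dm))
        params[f"enc{k}_mask_W1"] = ad.parameter(_glorot(rng, 2 * dm, d))
        params[f"enc{k}_mask_b1"] = ad.parameter(np.zeros(d))
        params[f"enc{k}_mask_W2"] = ad.parameter(_glorot(rng, d, 1))
        params[f"enc{k}_mask_b2"] = ad.parameter(np.zeros(1))
    return params


def _clamp_keep(clamp: set[tuple[int, int]] | None, n: int, layer: int) -> np.ndarray | None:
    """(n,1) 0/1 keep-vector for ``layer``, or None if nothing clamped."""
    if not clamp:
        return None
    zeros = [u for (u, k) in clamp if k == layer]
    if not zeros:
        return None
    keep = np.ones((n, 1))
    keep[zeros, 0] = 0.0
    return keep


def init_node_states(
    graph: MolecularGraph,
    params: dict[str, Tensor],
    clamp: set[tuple[int, int]] | None = None,
) -> tuple[Tensor, Tensor]:
    """Project normalized atom features to D and set initial masks to 1."""
    x = ad.constant(graph.node_features)
    if graph.node_features.shape[1] != params["input_W"].shape[0]:
        raise ValueError(
            f"feature width {graph.node_features.shape[1]} does not match "
            f"input projection {params['input_W'].shape[0]}")
    h0 = ad.linear(x, params["input_W"], params["input_b"])
    m0 = np.ones((graph.n, 1))
    keep = _clamp_keep(clamp, graph.n, 0)
    if keep is not None:
        m0 = m0 * keep
    return h0, ad.constant(m0)


def compute_soft_mask(
    h_prev: Tensor,
    m_prev: Tensor,
    adjacency: Tensor,
    params: dict[str, Tensor],
    layer: int,
) -> Tensor:
    """Soft mask of every node for ``layer`` (shape (n,1), values in (0,1))."""
    mh = ad.mul(m_prev, h_prev)
    self_term = ad.matmul(mh, params[f"enc{layer}_I1_W"])
    nbr = ad.matmul(adjacency, ad.matmul(mh, params[f"enc{layer}_I2_W"]))
    u = ad.relu(ad.concat([self_term, nbr], axis=1))
    hidden = ad.relu(ad.linear(u, params[f"enc{layer}_mask_W1"], params[f"enc{layer}_mask_b1"]))
    logits = ad.linear(hidden, params[f"enc{layer}_mask_W2"], params[f"enc{layer}_mask_b2"])
    return ad.sigmoid(logits)


def masmg_layer(
    h_prev: Tensor,
    m_k: Tensor,
    adjacency: Tensor,
    params: dict[str, Tensor],
    layer: int,
) -> Tensor:
    """Masked aggregation/update; rows with zero mask come out exactly zero."""
    mh = ad.mul(m_k, h_prev)
    agg = ad.concat([mh, ad.matmul(adjacency, mh)], axis=1)
    return ad.mul(m_k, ad.relu(ad.matmul(agg, _lookup_w(params, layer))))


def _lookup_w(params: dict[str, Tensor], layer: int) -> Tensor:
    return params[f"enc{layer}_W"]


def readout(h_k: Tensor) -> Tensor:
    """SUM readout over nodes."""
    return ad.reduce_sum(h_k, axis=0)


def encode_drug(
    graph: MolecularGraph,
    params: dict[str, Tensor],
    config: EncoderConfig,
    clamp: set[tuple[int, int]] | None = None,
) -> tuple[list[Tensor], MaskState]:
    """Run the K-layer encoder on one graph.

    Returns the per-layer readout tensors (each shape (D,)) and the
    recorded :class:`MaskState`.  ``clamp`` is a set of ``(node, layer)``
    pairs whose mask is forced to zero (layer 0 = initial mask), used for
    substructure diagnostics and the gating tests.
    """
    adjacency = ad.constant(graph.adjacency())
    h, m = init_node_states(graph, params, clamp)
    mask_log = np.ones((graph.n, config.n_layers + 1))
    mask_log[:, 0] = m.value[:, 0]
    per_layer: list[Tensor] = []
    for k in range(config.n_layers):
        m = compute_soft_mask(h, m, adjacency, params, k)
        keep = _clamp_keep(clamp, graph.n, k + 1)
        if keep is not None:
            m = ad.mul(m, ad.constant(keep))
        h = masmg_layer(h, m, adjacency, params, k)
        mask_log[:, k + 1] = m.value[:, 0]
        per_layer.append(readout(h))
    clamped: dict[int, set[int]] = {}
    for (u, k) in (clamp or ()):
        clamped.setdefault(k, set()).add(u)
    return per_layer, MaskState(masks=mask_log, clamped=clamped)
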