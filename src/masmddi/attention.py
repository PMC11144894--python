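"""Latent-feature update of the two drugs' substructure sequences.

Given the per-layer embeddings ``h_x^1..h_x^K`` and ``h_y^1..h_y^K`` of
a drug pair, both sequences are passed through ReLU affine maps to
attention vectors, every layer pair (i, j) is scored by a further ReLU
affine map of the *sum* of the two attention vectors, and each drug's
per-layer attention is the sigmoid of the mean over the other drug's
layer index.  The update rescales each embedding channelwise:

    ĥ^i = 0.5·h^i + h^i ⊙ A_h[i]          with A_h ∈ (0,1)

so for nonnegative embeddings every channel is rescaled into
[0.5·h, 1.5·h], and a flat attention of 0.5 leaves the sequence exactly
unchanged.

By default the pairwise score is a D-vector per layer pair (attention
resolved over both the layer ("spatial") and channel dimensions); a
scalar-per-pair variant is available via ``channel_attention=False``,
in which case the score map has output width 1 and broadcasts across
channels in the update.

All operations accept an optional leading batch dimension: sequences of
shape (K, D) or (B, K, D).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "init_attention_params",
    "attention_vector",
    "pairwise_attention",
    "marginal_attention",
    "update_latent",
    "latent_update",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_attention_params(
    hidden_dim: int,
    rng: np.random.Generator,
    channel_attention: bool = True,
) -> dict[str, Tensor]:
    d = hidden_dim
    d_out = d if channel_attention else 1
    return {
        "attn_Whx": ad.parameter(_glorot(rng, d, d)),
        "attn_bhx": ad.parameter(np.zeros(d)),
        "attn_Why": ad.parameter(_glorot(rng, d, d)),
        "attn_bhy": ad.parameter(np.zeros(d)),
        "attn_Wa": ad.parameter(_glorot(rng, d, d_out)),
        "attn_ba": ad.parameter(np.zeros(d_out)),
    }


def attention_vector(h: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """ReLU affine map of every layer embedding, shape-preserving."""
    return ad.relu(ad.linear(h, w, b))


def pairwise_attention(ha_x: Tensor, ha_y: Tensor, w_a: Tensor, b_a: Tensor) -> Tensor:
    """Score every layer pair: A[..., i, j, :] = ReLU(W_a(ha_x^i + ha_y^j) + b).

    Symmetric in the two attention vectors of a pair (their sum enters
    the map), with shape (..., K, K, D) — or (..., K, K, 1) for the
    scalar variant.
    """
    kx = ha_x.shape[-2]
    ky = ha_y.shape[-2]
    d = ha_x.shape[-1]
    lead = ha_x.shape[:-2]
    x = ad.reshape(ha_x, (*lead, kx, 1, d))
    y = ad.reshape(ha_y, (*lead, 1, ky, d))
    return ad.relu(ad.linear(ad.add(x, y), w_a, b_a))


def marginal_attention(a: Tensor) -> tuple[Tensor, Tensor]:
    """Per-drug attention by averaging over the other drug's layers.

    Drug x's attention at layer i averages A over j (the y index), and
    vice versa; a sigmoid maps the scores into (0, 1).
    """
    a_hx = ad.sigmoid(ad.reduce_mean(a, axis=-2))
    a_hy = ad.sigmoid(ad.reduce_mean(a, axis=-3))
    return a_hx, a_hy


def update_latent(h: Tensor, a_h: Tensor) -> Tensor:
    """ĥ^i = 0.5·h^i + h^i ⊙ A_h[i] (elementwise, broadcasting channels)."""
    return ad.add(ad.mul(ad.constant(0.5), h), ad.mul(h, a_h))


def latent_update(
    h_x: Tensor,
    h_y: Tensor,
    params: dict[str, Tensor],
    enabled: bool = True,
) -> tuple[Tensor, Tensor]:
    """Full Eqs-(4)-(10) update of a drug pair's substructure sequences.

    With ``enabled=False`` (the "no attention module" ablation) both
    sequences pass through unchanged.
    """
    if not enabled:
        return h_x, h_y
    ha_x = attention_vector(h_x, params["attn_Whx"], params["attn_bhx"])
    ha_y = attention_vector(h_y, params["attn_Why"], params["attn_bhy"])
    a = pairwise_attention(ha_x, ha_y, params["attn_Wa"], params["attn_ba"])
    a_hx, a_hy = marginal_attention(a)
    return update_latent(h_x, a_hx), update_latent(h_y, a_hy)
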