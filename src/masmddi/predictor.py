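"""Co-attention scoring of a drug pair and the interaction probability.

Every pair of substructure views (layer i of drug x, layer j of drug y)
receives an unnormalized co-attention weight

    γ_ij = zᵀ tanh(W_x ĥ_x^i + W_y ĥ_y^j)

(tanh rather than softmax so that non-interacting substructure pairs can
carry negative weight), and the triple's probability is the sigmoid of
the γ-weighted sum of bilinear forms through the relation matrix M_R:

    p = sigmoid( Σ_i Σ_j γ_ij · (ĥ_x^i)ᵀ M_R ĥ_y^j )

One learnable D×D matrix M_R exists per interaction type.  Scoring is
deliberately order-sensitive — interaction records describe how drug x
affects drug y — so score(x, y, R) need not equal score(y, x, R); a
symmetrized prediction (mean of both orders) is offered at the model
level for users who want order invariance.

Operations accept sequences shaped (K, D) or batched (B, K, D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PairScore",
    "init_coattention_params",
    "init_relation_matrices",
    "coattention_scores",
    "interaction_probability",
    "classify",
    "score_triple",
    "LOGIT_CLAMP",
]

# logits are clamped to +-30 before the sigmoid purely for numerical
# safety; |logit| = 30 corresponds to p within 1e-13 of {0, 1}
LOGIT_CLAMP = 30.0


@dataclass
class PairScore:
    """Score of one DDI triple: the K×K co-attention weights, the
    interaction probability and the thresholded label."""

    gamma: np.ndarray
    probability: float
    label: int


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_coattention_params(
    hidden_dim: int,
    rng: np.random.Generator,
    coattn_dim: int | None = None,
) -> dict[str, Tensor]:
    d = hidden_dim
    dp = coattn_dim if coattn_dim is not None else d
    return {
        "co_Wx": ad.parameter(_glorot(rng, d, dp)),
        "co_Wy": ad.parameter(_glorot(rng, d, dp)),
        "co_z": ad.parameter(_glorot(rng, dp, 1)),
    }


def init_relation_matrices(
    n_relations: int,
    hidden_dim: int,
    rng: np.random.Generator,
) -> Tensor:
    """Stack of per-relation bilinear matrices, shape (R, D, D)."""
    d = hidden_dim
    mats = np.stack([_glorot(rng, d, d) for _ in range(n_relations)])
    return ad.parameter(mats)


def coattention_scores(
    h_x: Tensor,
    h_y: Tensor,
    params: dict[str, Tensor],
) -> Tensor:
    """γ over all layer pairs, shape (..., K, K); no normalization."""
    px = ad.linear(h_x, params["co_Wx"])
    py = ad.linear(h_y, params["co_Wy"])
    kx, ky = h_x.shape[-2], h_y.shape[-2]
    dp = px.shape[-1]
    lead = h_x.shape[:-2]
    t = ad.tanh(ad.add(ad.reshape(px, (*lead, kx, 1, dp)),
                       ad.reshape(py, (*lead, 1, ky, dp))))
    return ad.reshape(ad.linear(t, params["co_z"]), (*lead, kx, ky))


def _swap_last_two(x: Tensor) -> Tensor:
    axes = list(range(len(x.shape)))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return ad.transpose(x, tuple(axes))


def interaction_probability(
    h_x: Tensor,
    h_y: Tensor,
    gamma: Tensor,
    m_r: Tensor,
) -> Tensor:
    """p = sigmoid(Σ_ij γ_ij ĥ_x^i ᵀ M_R ĥ_y^j), shape (...,).

    ``m_r`` is one (D, D) matrix, or a (B, D, D) stack when scoring a
    batch of triples with per-triple relations.
    """
    bilinear = ad.matmul(ad.matmul(h_x, m_r), _swap_last_two(h_y))  # (..., K, K)
    logit = ad.reduce_sum(ad.mul(gamma, bilinear), axis=(-2, -1))
    return ad.sigmoid(ad.clip(logit, -LOGIT_CLAMP, LOGIT_CLAMP))


def classify(p: float | np.ndarray, threshold: float = 0.5) -> int | np.ndarray:
    """1 iff the probability strictly exceeds the threshold."""
    labels = (np.asarray(p) > threshold).astype(int)
    return int(labels) if labels.ndim == 0 else labels


def score_triple(model, triple) -> PairScore:
    """Full forward pass for one triple against a model's parameters.

    ``model`` is a :class:`~masmddi.model.DDIModel` (duck-typed: needs
    ``_forward`` and a relation vocabulary check).
    """
    gamma, p = model.forward_pair(triple.drug_x, triple.drug_y, triple.relation)
    return PairScore(gamma=gamma, probability=float(p),
                     label=classify(float(p), model.config.threshold))
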