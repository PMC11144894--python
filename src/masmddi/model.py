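"""The DDI prediction model and its fitted results.

:class:`DDIModel` is constructed from data — a list of positive DDI
triples plus a drug→SMILES map — together with a
:class:`~masmddi.trainer.TrainConfig`.  ``fit()`` runs the negative-
sampled training loop (Adam, exponentially decayed learning rate,
paired binary cross-entropy) and returns a :class:`DDIResults` holding
the selected parameters (best validation AUROC), the per-epoch history
and evaluation helpers, in the spirit of the Model/Results split of
statsmodels.

The forward pass composes the package's stages: soft-mask encoder →
(optional) spatial/channel attention update → co-attention weights →
per-relation bilinear score → sigmoid.  All drugs of a batch are
encoded once and their substructure sequences gathered per triple, so
the cost per optimization step is one encoder run per *distinct* drug.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .attention import init_attention_params, latent_update
from .chem_io import (
    AtomFeatureSchema,
    DDITriple,
    MolecularGraph,
    default_schema,
    normalize_features,
    parse_smiles,
)
from .encoder import EncoderConfig, MaskState, encode_drug, init_encoder_params
from .predictor import (
    classify,
    coattention_scores,
    init_coattention_params,
    init_relation_matrices,
    interaction_probability,
)
from .trainer import (
    MetricReport,
    TrainConfig,
    evaluate,
    lr_at_epoch,
    sample_negatives,
)

__all__ = ["DDIModel", "DDIResults", "load_results"]


class RelationVocabularyError(KeyError):
    pass


def _triple_key(t: DDITriple) -> tuple[str, str, int]:
    return (t.drug_x, t.drug_y, t.relation)


class _Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, Tensor], weight_decay: float):
        self.params = params
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.value
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.value = p.value - lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class DDIModel:
    """Drug-drug interaction predictor over molecular graphs.

    Parameters
    ----------
    triples
        Positive DDI triples (drug_x, drug_y, relation).
    drug_smiles
        Mapping from every referenced drug id to its SMILES string.
    config
        Architecture and optimization settings.
    n_relations
        Size of the relation vocabulary; inferred from the triples when
        omitted.  Relations must be dense integers 0..n_relations-1.
    known_positives
        Optional superset of true triples used to filter sampled
        negatives (defaults to the training triples themselves).
    """

    def __init__(
        self,
        triples: list[DDITriple],
        drug_smiles: dict[str, str],
        config: TrainConfig | None = None,
        n_relations: int | None = None,
        schema: AtomFeatureSchema | None = None,
        known_positives: set[tuple[str, str, int]] | None = None,
    ):
        self.config = config or TrainConfig()
        self.triples = list(triples)
        self.schema = schema or default_schema()
        missing = sorted({d for t in triples for d in (t.drug_x, t.drug_y)
                          if d not in drug_smiles})
        if missing:
            raise ValueError(f"no SMILES for drugs: {missing[:5]}...")
        self.drug_smiles = dict(drug_smiles)
        self.n_relations = (n_relations if n_relations is not None
                            else 1 + max((t.relation for t in triples), default=0))
        self.known_positives = set(known_positives) if known_positives else \
            {_triple_key(t) for t in triples}
        self.known_positives |= {_triple_key(t) for t in triples}
        self.graphs: dict[str, MolecularGraph] = {
            d: normalize_features(parse_smiles(s, self.schema))
            for d, s in self.drug_smiles.items()
        }
        self.encoder_config = EncoderConfig(
            input_dim=self.schema.total_width,
            n_layers=self.config.n_layers,
            hidden_dim=self.config.hidden_dim,
            mask_dim=self.config.mask_dim,
        )
        self.params: dict[str, Tensor] | None = None

    # ------------------------------------------------------------------
    # parameters and forward pass

    def init_params(self, seed: int | None = None) -> dict[str, Tensor]:
        """(Re)initialize all trainable parameters, seed-controlled."""
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        params = init_encoder_params(self.encoder_config, rng)
        params.update(init_attention_params(
            self.config.hidden_dim, rng,
            channel_attention=self.config.channel_attention))
        params.update(init_coattention_params(
            self.config.hidden_dim, rng, coattn_dim=self.config.coattn_dim))
        params["relations"] = init_relation_matrices(
            self.n_relations, self.config.hidden_dim, rng)
        # small-init the scoring head: near-zero initial logits avoid the
        # saturated mask-collapse fixed point (see TrainConfig docstring)
        params["co_z"].value *= self.config.head_init_scale
        params["relations"].value *= self.config.head_init_scale
        self.params = params
        return params

    def _require_params(self) -> dict[str, Tensor]:
        if self.params is None:
            self.init_params()
        return self.params

    def _check_relations(self, triples: list[DDITriple]) -> None:
        bad = [t.relation for t in triples
               if not 0 <= t.relation < self.n_relations]
        if bad:
            raise RelationVocabularyError(
                f"relation ids {sorted(set(bad))} outside vocabulary "
                f"0..{self.n_relations - 1}")

    def encode(self, drug: str, clamp=None) -> tuple[list[Tensor], MaskState]:
        """Substructure sequence and mask state of one drug."""
        return encode_drug(self.graphs[drug], self._require_params(),
                           self.encoder_config, clamp=clamp)

    def _encode_batch(
        self,
        drugs: list[str],
        dropout_rng: np.random.Generator | None = None,
        dropout_rate: float = 0.0,
    ) -> dict[str, Tensor]:
        """Encode each distinct drug once; returns (K, D) tensors.

        Dropout (when active) zeroes whole channels of the substructure
        embeddings with inverted scaling, before the attention module.
        """
        params = self._require_params()
        out: dict[str, Tensor] = {}
        for d in dict.fromkeys(drugs):  # preserves order, dedupes
            per_layer, _ = encode_drug(self.graphs[d], params, self.encoder_config)
            seq = ad.stack(per_layer, axis=0)
            if dropout_rng is not None and dropout_rate > 0.0:
                keep = (dropout_rng.random(seq.shape) >= dropout_rate)
                seq = ad.mul(seq, ad.constant(keep / (1.0 - dropout_rate)))
            out[d] = seq
        return out

    def _forward(
        self,
        triples: list[DDITriple],
        encodings: dict[str, Tensor] | None = None,
        dropout_rng: np.random.Generator | None = None,
        dropout_rate: float = 0.0,
    ) -> tuple[Tensor, Tensor]:
        """Batched forward pass; returns (gamma (B,K,K), p (B,))."""
        self._check_relations(triples)
        params = self._require_params()
        if encodings is None:
            drugs = [d for t in triples for d in (t.drug_x, t.drug_y)]
            encodings = self._encode_batch(drugs, dropout_rng, dropout_rate)
        h_x = ad.stack([encodings[t.drug_x] for t in triples], axis=0)
        h_y = ad.stack([encodings[t.drug_y] for t in triples], axis=0)
        h_x, h_y = latent_update(h_x, h_y, params,
                                 enabled=self.config.attention_module)
        gamma = coattention_scores(h_x, h_y, params)
        rel_idx = np.array([t.relation for t in triples], dtype=np.intp)
        m_r = ad.gather(params["relations"], rel_idx)
        p = interaction_probability(h_x, h_y, gamma, m_r)
        return gamma, p

    def forward_pair(self, drug_x: str, drug_y: str, relation: int):
        """Unbatched forward pass of one pair; returns (gamma, p) arrays."""
        t = DDITriple(drug_x, drug_y, relation)
        with ad.no_grad():
            gamma, p = self._forward([t])
        return gamma.value[0], p.value[0]

    def predict(self, triples: list[DDITriple],
                params: dict[str, Tensor] | None = None) -> np.ndarray:
        """Interaction probabilities, optionally symmetrized over order."""
        if params is not None:
            saved, self.params = self.params, params
        try:
            with ad.no_grad():
                p = self._forward(triples)[1].value
                if self.config.symmetrize:
                    flipped = [DDITriple(t.drug_y, t.drug_x, t.relation)
                               for t in triples]
                    p = 0.5 * (p + self._forward(flipped)[1].value)
        finally:
            if params is not None:
                self.params = saved
        return p

    # ------------------------------------------------------------------
    # training

    def _loss(self, pos: list[DDITriple], neg: list[DDITriple],
              dropout_rng=None, dropout_rate=0.0) -> Tensor:
        """Paired BCE, −mean(log p_pos + log(1−p_neg)), as a tape tensor."""
        batch = pos + neg
        _, p = self._forward(batch, dropout_rng=dropout_rng,
                             dropout_rate=dropout_rate)
        eps = 1e-7
        p = ad.clip(p, eps, 1.0 - eps)
        n = len(pos)
        p_pos = ad.reshape(p, (len(batch),))
        logs = ad.log(p_pos)
        log1m = ad.log(ad.add(ad.constant(1.0), ad.mul(ad.constant(-1.0), p)))
        pos_term = ad.reduce_sum(ad.mul(logs, ad.constant(
            np.concatenate([np.ones(n), np.zeros(n)]))))
        neg_term = ad.reduce_sum(ad.mul(log1m, ad.constant(
            np.concatenate([np.zeros(n), np.ones(n)]))))
        total = ad.add(pos_term, neg_term)
        return ad.mul(ad.constant(-1.0 / n), total)

    def fit(
        self,
        train: list[DDITriple] | None = None,
        val: list[DDITriple] | None = None,
        mode: str = "transductive",
        fixed_negatives: list[DDITriple] | None = None,
        verbose: bool = False,
    ) -> "DDIResults":
        """Train and return the fitted results.

        ``train``/``val`` default to all construction triples with no
        validation (last epoch selected).  With validation, the epoch
        with the best validation AUROC is selected.  ``mode`` only
        resolves the default dropout rate (0.2 for ``"inductive"``).

        By default one fresh negative is sampled per positive per epoch;
        ``fixed_negatives`` (aligned with ``train``) freezes them
        instead, turning the run into plain optimization of a finite
        balanced set — the right setup for overfitting sanity checks.
        """
        cfg = self.config
        train = list(train) if train is not None else list(self.triples)
        self._check_relations(train)
        dropout = cfg.dropout if cfg.dropout is not None else \
            (0.2 if mode == "inductive" else 0.0)
        pool = sorted({d for t in self.triples for d in (t.drug_x, t.drug_y)})

        ss = np.random.SeedSequence(cfg.seed)
        derived = [int(s.generate_state(1)[0] % (2**31))
                   for s in ss.spawn(3 + cfg.max_restarts)]
        epoch_seed, val_seed, drop_seed = derived[:3]
        init_seeds = [cfg.seed] + derived[3:]

        val_neg = None
        if val:
            # fixed once per run so metrics are comparable across epochs
            val_neg = sample_negatives(val, pool, self.known_positives,
                                       np.random.default_rng(val_seed))

        # a collapsed run sits at the trivial p=0.5 plateau (loss 2 ln 2);
        # restart from a re-derived init when training never left it
        collapse_loss = 0.95 * 2.0 * np.log(2.0)
        for attempt, init_seed in enumerate(init_seeds):
            params = self.init_params(init_seed)
            optimizer = _Adam(params, cfg.weight_decay)
            drop_rng = np.random.default_rng([drop_seed, attempt])
            history: list[dict] = []
            best_auroc, best_epoch, best_state = -np.inf, -1, None
            for epoch in range(cfg.epochs):
                rng = np.random.default_rng([epoch_seed, epoch])
                order = rng.permutation(len(train))
                lr = lr_at_epoch(epoch, cfg.base_lr, cfg.lr_decay)
                losses = []
                for start in range(0, len(train), cfg.batch_size):
                    idx = order[start:start + cfg.batch_size]
                    pos = [train[i] for i in idx]
                    if fixed_negatives is not None:
                        neg = [fixed_negatives[i] for i in idx]
                    else:
                        neg = sample_negatives(pos, pool, self.known_positives, rng)
                    optimizer.zero_grad()
                    loss = self._loss(pos, neg, dropout_rng=drop_rng,
                                      dropout_rate=dropout)
                    if not np.isfinite(loss.value):
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}; diverged "
                            f"(lr={lr:.2e}, batch starting at {start})")
                    ad.backward(loss)
                    optimizer.step(lr)
                    losses.append(float(loss.value))
                row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr}
                if val:
                    report = self.evaluate_triples(val, val_neg)
                    row.update({"val_acc": report.acc, "val_auroc": report.auroc,
                                "val_auprc": report.auprc, "val_f1": report.f1})
                    if report.auroc > best_auroc:
                        best_auroc, best_epoch = report.auroc, epoch
                        best_state = {k: p.value.copy() for k, p in params.items()}
                history.append(row)
                if verbose:
                    print("  ".join(
                        f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                        for k, v in row.items()))
            if history[-1]["loss"] <= collapse_loss:
                break  # training escaped the trivial plateau
        if best_state is not None:
            for k, p in params.items():
                p.value = best_state[k]
        else:
            best_epoch = cfg.epochs - 1
        return DDIResults(model=self, params=params,
                          history=pd.DataFrame(history), best_epoch=best_epoch,
                          n_restarts=attempt)

    def evaluate_triples(self, positives: list[DDITriple],
                         negatives: list[DDITriple]) -> MetricReport:
        """Metrics on a positive set against pre-sampled negatives."""
        probs = self.predict(positives + negatives)
        labels = np.concatenate([np.ones(len(positives), dtype=int),
                                 np.zeros(len(negatives), dtype=int)])
        return evaluate(probs, labels, self.config.threshold)


@dataclass
class DDIResults:
    """Fitted model state: selected parameters, history and evaluators."""

    model: DDIModel
    params: dict[str, Tensor]
    history: pd.DataFrame
    best_epoch: int
    n_restarts: int = 0

    def predict(self, triples: list[DDITriple]) -> np.ndarray:
        return self.model.predict(triples, params=self.params)

    def classify(self, triples: list[DDITriple]) -> np.ndarray:
        return classify(self.predict(triples), self.model.config.threshold)

    def evaluate(self, positives: list[DDITriple],
                 negatives: list[DDITriple]) -> MetricReport:
        return self.model.evaluate_triples(positives, negatives)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "DDI soft-mask co-attention model",
            "=" * 48,
            f"drugs: {len(self.model.drug_smiles)}    "
            f"relations: {self.model.n_relations}    "
            f"training triples: {len(self.model.triples)}",
            f"encoder: K={cfg.n_layers} layers, D={cfg.hidden_dim}, "
            f"attention={'on' if cfg.attention_module else 'off'}",
            f"optimizer: Adam lr={cfg.base_lr:g}*{cfg.lr_decay:g}^t, "
            f"weight decay={cfg.weight_decay:g}, batch={cfg.batch_size}",
            f"epochs run: {len(self.history)}    selected epoch: {self.best_epoch}"
            + (f"    restarts: {self.n_restarts}" if self.n_restarts else ""),
        ]
        if "val_auroc" in self.history:
            row = self.history.iloc[self.best_epoch]
            lines.append(
                f"validation at selection: ACC={row['val_acc']:.4f} "
                f"AUROC={row['val_auroc']:.4f} AUPRC={row['val_auprc']:.4f} "
                f"F1={row['val_f1']:.4f}")
        lines.append(f"final training loss: {self.history['loss'].iloc[-1]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Single-file checkpoint: named arrays + JSON config manifest."""
        manifest = {
            "format_version": 1,
            "config": asdict(self.model.config),
            "n_relations": self.model.n_relations,
            "input_dim": self.model.encoder_config.input_dim,
            "best_epoch": int(self.best_epoch),
            "n_restarts": int(self.n_restarts),
            "history_columns": list(self.history.columns),
        }
        arrays = {f"param/{k}": p.value for k, p in self.params.items()}
        arrays["history"] = self.history.to_numpy(dtype=float)
        np.savez(path, manifest=np.array(json.dumps(manifest)), **arrays)


def load_results(path, triples: list[DDITriple],
                 drug_smiles: dict[str, str]) -> DDIResults:
    """Rebuild a :class:`DDIResults` from a checkpoint plus its data."""
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(str(archive["manifest"]))
        cfg = TrainConfig(**manifest["config"])
        model = DDIModel(triples, drug_smiles, config=cfg,
                         n_relations=manifest["n_relations"])
        params = model.init_params()
        for k in params:
            params[k].value = archive[f"param/{k}"].copy()
        history = pd.DataFrame(archive["history"],
                               columns=manifest["history_columns"])
    return DDIResults(model=model, params=params, history=history,
                      best_epoch=manifest["best_epoch"],
                      n_restarts=manifest.get("n_restarts", 0))
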