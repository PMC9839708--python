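"""GRU sequence autoencoder with attention for spectrogram embeddings.

A spectrogram tensor ``[2, F, T]`` is read as a sequence of T frames (each the
2F-long concatenation of both channels' frequency columns).  A GRU encoder
consumes the sequence; its final hidden state is mapped by an affine head to a
D-dimensional embedding (default D = 128).  A GRU decoder, initialized from
the embedding, reconstructs the frame sequence step by step: each step receives
the previous frame (the true frame under teacher forcing during training, its
own previous output at inference) plus a dot-product attention context over
the encoder's per-step outputs.  Training minimizes frame-wise mean squared
error with Adam; reconstruction quality is monitored as the cosine similarity
between each validation tensor and its reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .spectro import SpectrogramTensor

__all__ = ["AEConfig", "TrainHistory", "TemporalAutoencoder",
           "train_autoencoder", "validate_reconstruction", "cosine_similarity"]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class AEConfig:
    embedding_dim: int = 128
    gru_hidden: int = 128
    gru_layers: int = 1
    attention: str = "dot"  # {"dot", "additive"}
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 128
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    teacher_forcing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ModelError("embedding_dim must be >= 1")
        if self.epochs < 0:
            raise ModelError("epochs must be >= 0")
        if self.attention not in ("dot", "additive"):
            raise ModelError(f"unknown attention form {self.attention!r}")
        if self.gru_layers != 1:
            raise ModelError("only single-layer GRUs are supported")


@dataclass
class TrainHistory:
    """Per-epoch training MSE and validation cosine similarity."""

    train_mse: list[float] = field(default_factory=list)
    val_cosine: list[float] = field(default_factory=list)
    best_epoch: int = -1


class _GRUCell:
    """Standard gated recurrent unit: update/reset gates + candidate state."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden: int, prefix: str):
        k = 1.0 / np.sqrt(hidden)

        def p(shape):
            return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)

        self.W = p((in_dim, 3 * hidden))   # input weights for z, r, n
        self.U = p((hidden, 3 * hidden))   # recurrent weights
        self.b = p((3 * hidden,))
        self.hidden = hidden
        self.prefix = prefix

    def params(self) -> dict[str, Tensor]:
        return {f"{self.prefix}_W": self.W, f"{self.prefix}_U": self.U, f"{self.prefix}_b": self.b}

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        gx = ad.add(ad.matmul(x, self.W), self.b)
        gh = ad.matmul(h, self.U)
        # split the 3H-wide pre-activations into z, r, n blocks
        def blk(t, i):
            sub = Tensor(t.value[:, i * H:(i + 1) * H], parents=(t,),
                         backward_fn=None)
            def bwd(g, t=t, i=i):
                if t.requires_grad:
                    full = np.zeros_like(t.value)
                    full[:, i * H:(i + 1) * H] = g
                    t._accumulate(full)
            sub.backward_fn = bwd if sub.requires_grad else None
            return sub
        z = ad.sigmoid(ad.add(blk(gx, 0), blk(gh, 0)))
        r = ad.sigmoid(ad.add(blk(gx, 1), blk(gh, 1)))
        n = ad.tanh(ad.add(blk(gx, 2), ad.mul(r, blk(gh, 2))))
        return ad.add(ad.mul(z, h), ad.mul(ad.one_minus(z), n))


class TemporalAutoencoder:
    """Encoder-decoder over spectrogram frame sequences.

    ``frame_dim`` must equal 2F of the tensors the model is applied to.
    """

    def __init__(self, frame_dim: int, config: AEConfig):
        self.config = config
        self.frame_dim = frame_dim
        rng = np.random.default_rng(config.seed)
        H, D = config.gru_hidden, config.embedding_dim
        k = 1.0 / np.sqrt(H)
        self.encoder = _GRUCell(rng, frame_dim, H, "enc")
        self.decoder = _GRUCell(rng, frame_dim, H, "dec")
        self.W_emb = Tensor(rng.uniform(-k, k, (H, D)), requires_grad=True)
        self.b_emb = Tensor(np.zeros(D), requires_grad=True)
        self.W_dec0 = Tensor(rng.uniform(-1 / np.sqrt(D), 1 / np.sqrt(D), (D, H)), requires_grad=True)
        self.b_dec0 = Tensor(np.zeros(H), requires_grad=True)
        self.W_out = Tensor(rng.uniform(-k, k, (2 * H, frame_dim)), requires_grad=True)
        self.b_out = Tensor(np.zeros(frame_dim), requires_grad=True)
        if config.attention == "additive":
            self.W_att_q = Tensor(rng.uniform(-k, k, (H, H)), requires_grad=True)
            self.W_att_k = Tensor(rng.uniform(-k, k, (H, H)), requires_grad=True)
            self.v_att = Tensor(rng.uniform(-k, k, (H, 1)), requires_grad=True)

    # ---------------------------------------------------------------- params
    def parameters(self) -> dict[str, Tensor]:
        out = {**self.encoder.params(), **self.decoder.params(),
               "W_emb": self.W_emb, "b_emb": self.b_emb,
               "W_dec0": self.W_dec0, "b_dec0": self.b_dec0,
               "W_out": self.W_out, "b_out": self.b_out}
        if self.config.attention == "additive":
            out.update(W_att_q=self.W_att_q, W_att_k=self.W_att_k, v_att=self.v_att)
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v.value = np.array(weights[k], dtype=np.float64)

    # --------------------------------------------------------------- forward
    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[2] != self.frame_dim:
            raise ModelError(
                f"frame dimension {X.shape[2]} does not match the model's {self.frame_dim} "
                "(spectrogram F differs from the one the model was built for)"
            )
        return X

    def _encode_graph(self, X: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        B, T, _ = X.shape
        h = Tensor(np.zeros((B, self.config.gru_hidden)))
        outs = []
        for t in range(T):
            h = self.encoder.step(Tensor(X[:, t, :]), h)
            outs.append(h)
        emb = ad.add(ad.matmul(h, self.W_emb), self.b_emb)
        return emb, outs

    def _attend(self, enc_stack: Tensor, h: Tensor) -> tuple[Tensor, np.ndarray]:
        if self.config.attention == "dot":
            return ad.attention(enc_stack, h)
        # additive (Bahdanau-style): scores_t = v' tanh(Wq h + Wk e_t)
        q = ad.matmul(h, self.W_att_q)                       # (B, H)
        B, T, H = enc_stack.value.shape
        flat = Tensor(enc_stack.value.reshape(B * T, H), parents=(enc_stack,))
        flat.backward_fn = ((lambda g: enc_stack._accumulate(g.reshape(B, T, H)))
                            if flat.requires_grad else None)
        keys = ad.matmul(flat, self.W_att_k)
        keys3 = Tensor(keys.value.reshape(B, T, H), parents=(keys,))
        keys3.backward_fn = ((lambda g: keys._accumulate(g.reshape(B * T, H)))
                             if keys3.requires_grad else None)
        scores = ad.matvec_last(_tanh_keys(keys3, q), self.v_att)
        return ad.softmax_context(enc_stack, scores)

    def forward_batch(self, X: np.ndarray, teacher_forcing: bool = True
                      ) -> tuple[Tensor, list[Tensor], np.ndarray, Tensor]:
        """Run encode + decode on a batch (B, T, 2F).

        Returns (embedding node, per-step output nodes, attention weights
        (T, B, T_enc), total squared-error node).
        """
        X = self._check(X)
        B, T, _ = X.shape
        emb, enc_outs = self._encode_graph(X)
        enc_stack = ad.stack(enc_outs, axis=1)  # (B, T, H)
        h = ad.tanh(ad.add(ad.matmul(emb, self.W_dec0), self.b_dec0))
        prev = np.zeros((B, self.frame_dim))
        outputs, weights = [], []
        loss = None
        for t in range(T):
            h = self.decoder.step(Tensor(prev), h)
            ctx, w = self._attend(enc_stack, h)
            out = ad.add(ad.matmul(ad.concat([h, ctx], axis=1), self.W_out), self.b_out)
            outputs.append(out)
            weights.append(w)
            step_loss = ad.sse(out, X[:, t, :])
            loss = step_loss if loss is None else ad.add(loss, step_loss)
            prev = X[:, t, :] if teacher_forcing else out.value
        mse = ad.scale(loss, 1.0 / X.size)
        return emb, outputs, np.stack(weights), mse

    # ------------------------------------------------------------- inference
    def encode_batch(self, X: np.ndarray) -> np.ndarray:
        """Deterministic embeddings (B, D) for a batch of frame sequences."""
        X = self._check(X)
        emb, _ = self._encode_graph(X)
        return emb.value

    def reconstruct_batch(self, X: np.ndarray) -> np.ndarray:
        """Free-running reconstruction (B, T, 2F)."""
        X = self._check(X)
        _, outputs, _, _ = self.forward_batch(X, teacher_forcing=False)
        return np.stack([o.value for o in outputs], axis=1)


def _tanh_keys(keys3: Tensor, q: Tensor) -> Tensor:
    """tanh(q[:, None, :] + keys) as a graph node (additive-attention helper)."""
    out_val = np.tanh(q.value[:, None, :] + keys3.value)

    def bwd(g):
        d = g * (1.0 - out_val**2)
        if keys3.requires_grad:
            keys3._accumulate(d)
        if q.requires_grad:
            q._accumulate(d.sum(axis=1))

    t = Tensor(out_val, parents=(keys3, q), backward_fn=bwd)
    if not t.requires_grad:
        t.backward_fn = None
    return t


# ------------------------------------------------------------------ training

def encode(tensor: SpectrogramTensor, model: TemporalAutoencoder) -> np.ndarray:
    """Embed one spectrogram tensor; returns a length-D vector."""
    return model.encode_batch(tensor.frames()[None])[0]


def forward(tensor: SpectrogramTensor, model: TemporalAutoencoder
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Embedding, reconstruction reassembled to [2, F, T], attention weights."""
    X = tensor.frames()[None]
    emb, outputs, weights, _ = model.forward_batch(X, teacher_forcing=False)
    frames = np.stack([o.value[0] for o in outputs])  # (T, 2F)
    F = tensor.n_freqs
    recon = np.stack([frames[:, :F].T, frames[:, F:].T])
    return emb.value[0], recon, weights[:, 0, :]


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """cos(x, y) on flattened arrays; zero-norm inputs contribute 0 by convention."""
    x, y = np.ravel(x), np.ravel(y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def _as_batch(tensors: list[SpectrogramTensor]) -> np.ndarray:
    X = np.stack([t.frames() for t in tensors])
    if not np.isfinite(X).all():
        raise ModelError("non-finite values in input tensors")
    return X


def validate_reconstruction(model: TemporalAutoencoder,
                            tensors: list[SpectrogramTensor],
                            batch_size: int = 256) -> float:
    """Mean cosine similarity between tensors and their free-running reconstructions."""
    if not tensors:
        raise ModelError("empty validation set")
    X = _as_batch(tensors)
    sims = []
    for i in range(0, len(X), batch_size):
        batch = X[i:i + batch_size]
        recon = model.reconstruct_batch(batch)
        sims.extend(cosine_similarity(x, r) for x, r in zip(batch, recon))
    return float(np.mean(sims))


def train_autoencoder(train_tensors: list[SpectrogramTensor],
                      val_tensors: list[SpectrogramTensor],
                      config: AEConfig) -> tuple[TemporalAutoencoder, TrainHistory]:
    """Train on unlabeled tensors; restore the best validation-cosine epoch.

    The interface deliberately accepts spectrogram tensors only — no labels
    can reach the unsupervised stage.
    """
    if not train_tensors:
        raise ModelError("empty training set")
    X = _as_batch(train_tensors)
    frame_dim = X.shape[2]
    model = TemporalAutoencoder(frame_dim, config)
    history = TrainHistory()
    if config.epochs == 0:
        return model, history
    opt = ad.Adam(list(model.parameters().values()), lr=config.learning_rate,
                  beta1=config.adam_beta1, beta2=config.adam_beta2, eps=config.adam_eps)
    rng = np.random.default_rng([config.seed, 0x5EED])
    best_cos, best_weights = -np.inf, model.get_weights()
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_sse, n_vals = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = X[order[i:i + config.batch_size]]
            opt.zero_grad()
            _, _, _, mse = model.forward_batch(batch, teacher_forcing=config.teacher_forcing)
            if not np.isfinite(mse.value):
                raise ModelError(f"non-finite training loss at epoch {epoch}")
            mse.backward()
            opt.step()
            epoch_sse += float(mse.value) * batch.size
            n_vals += batch.size
        history.train_mse.append(epoch_sse / n_vals)
        val_cos = validate_reconstruction(model, val_tensors) if val_tensors else np.nan
        history.val_cosine.append(float(val_cos))
        if val_tensors and val_cos > best_cos:
            best_cos, best_weights = val_cos, model.get_weights()
            history.best_epoch = epoch
    if val_tensors:
        model.set_weights(best_weights)
    else:
        history.best_epoch = config.epochs - 1
    return model, history
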