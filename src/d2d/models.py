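"""Encoder–decoder Transformer conditional sequence models.

A source domain sequence B is encoded by a Transformer encoder; a causal
Transformer decoder then defines next-symbol conditionals
P(a_i | B, a_1..a_{i-1}) over the token vocabulary, giving a tractable
conditional likelihood log P(A|B) = Σ_i log P(a_i | B, a_<i).

Two named presets mirror the sizes used throughout:

* ``shallow`` — 2 layers, 1 attention head, d_model 55, d_ff 2048
* ``large``   — 3 layers, 1 attention head, d_model 105, d_ff 2048

The architecture is the original post-norm translation Transformer with fixed
sinusoidal positional encodings, so the parameter count is independent of the
alignment lengths Nin and Nout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor
from .alphabet import Tokenizer

_NEG = -1e9  # additive attention mask value


@dataclass
class ModelConfig:
    n_layers: int = 2
    n_heads: int = 1
    d_model: int = 55
    d_ff: int = 2048
    dropout: float = 0.1
    max_len: int = 1024
    dtype: str = "float32"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )


PRESETS = {
    "shallow": ModelConfig(n_layers=2, n_heads=1, d_model=55, d_ff=2048),
    "large": ModelConfig(n_layers=3, n_heads=1, d_model=105, d_ff=2048),
}


def preset_config(name: str, **overrides) -> ModelConfig:
    cfg = asdict(PRESETS[name])
    cfg.update(overrides)
    return ModelConfig(**cfg)


def sinusoidal_encoding(L: int, d: int, dtype) -> np.ndarray:
    pos = np.arange(L)[:, None].astype(np.float64)
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(dtype)


class TransformerModel:
    """Conditional sequence model P(a_i | B, a_1..a_{i-1}).

    Teacher-forced calls take the SOS-prefixed decoder input and return one
    normalized log-distribution over all 24 tokens per decoder position
    (Nout residue positions plus the EOS slot).
    """

    def __init__(self, config: ModelConfig, tokenizer: Tokenizer, seed: int = 0):
        self.config = config
        self.tokenizer = tokenizer
        self.seed = seed
        self.dtype = np.dtype(config.dtype)
        self._params: dict[str, Parameter] = {}
        self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------ init
    def _param(self, name, shape, rng, scale=None):
        if scale is None:  # Glorot uniform
            fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
            scale = np.sqrt(6.0 / (fan_in + fan_out))
        data = rng.uniform(-scale, scale, size=shape).astype(self.dtype)
        p = Parameter(data)
        self._params[name] = p
        return p

    def _zeros(self, name, shape):
        p = Parameter(np.zeros(shape, dtype=self.dtype))
        self._params[name] = p
        return p

    def _ones(self, name, shape):
        p = Parameter(np.ones(shape, dtype=self.dtype))
        self._params[name] = p
        return p

    def _init_params(self, rng):
        c = self.config
        V = self.tokenizer.total_tokens
        d = c.d_model
        self._param("embed", (V, d), rng, scale=np.sqrt(3.0 / d))
        for side, n_attn in (("enc", 1), ("dec", 2)):
            for layer in range(c.n_layers):
                pre = f"{side}{layer}"
                for a in range(n_attn):
                    for w in ("q", "k", "v", "o"):
                        self._param(f"{pre}.attn{a}.W{w}", (d, d), rng)
                        self._zeros(f"{pre}.attn{a}.b{w}", (d,))
                    self._ones(f"{pre}.ln{a}.g", (d,))
                    self._zeros(f"{pre}.ln{a}.b", (d,))
                self._param(f"{pre}.ff.W1", (d, c.d_ff), rng)
                self._zeros(f"{pre}.ff.b1", (c.d_ff,))
                self._param(f"{pre}.ff.W2", (c.d_ff, d), rng)
                self._zeros(f"{pre}.ff.b2", (d,))
                self._ones(f"{pre}.lnff.g", (d,))
                self._zeros(f"{pre}.lnff.b", (d,))
        self._param("out.W", (d, V), rng)
        self._zeros("out.b", (V,))

    def parameters(self) -> list[Parameter]:
        return list(self._params.values())

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # ------------------------------------------------------------- building
    def _embed(self, tokens: np.ndarray) -> Tensor:
        c = self.config
        x = ad.embedding(self._params["embed"], tokens) * np.sqrt(float(c.d_model))
        pe = sinusoidal_encoding(tokens.shape[-1], c.d_model, self.dtype)
        return x + pe

    def _attention(self, pre: str, x: Tensor, mem: Tensor, mask, rng):
        c = self.config
        h, dh = c.n_heads, c.d_model // c.n_heads

        def proj(inp, w):
            B, L = inp.shape[0], inp.shape[1]
            y = inp @ self._params[f"{pre}.W{w}"] + self._params[f"{pre}.b{w}"]
            return y.reshape(B, L, h, dh).swapaxes(1, 2)  # (B, h, L, dh)

        q, k, v = proj(x, "q"), proj(mem, "k"), proj(mem, "v")
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        if mask is not None:
            scores = scores + mask
        attn = ad.softmax(scores, axis=-1)
        attn = ad.dropout(attn, c.dropout, rng)
        ctx = attn @ v  # (B, h, Lq, dh)
        B, Lq = x.shape[0], x.shape[1]
        ctx = ctx.swapaxes(1, 2).reshape(B, Lq, c.d_model)
        return ctx @ self._params[f"{pre}.Wo"] + self._params[f"{pre}.bo"]

    def _ffn(self, pre: str, x: Tensor, rng):
        c = self.config
        hdn = (x @ self._params[f"{pre}.W1"] + self._params[f"{pre}.b1"]).relu()
        hdn = ad.dropout(hdn, c.dropout, rng)
        return hdn @ self._params[f"{pre}.W2"] + self._params[f"{pre}.b2"]

    def _ln(self, pre: str, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self._params[f"{pre}.g"], self._params[f"{pre}.b"])

    def encode_source(self, src_tokens: np.ndarray, rng=None) -> Tensor:
        """Encoder memory for a batch of source sequences, (B, Nin, d_model)."""
        c = self.config
        x = ad.dropout(self._embed(src_tokens), c.dropout, rng)
        for layer in range(c.n_layers):
            pre = f"enc{layer}"
            a = self._attention(f"{pre}.attn0", x, x, None, rng)
            x = self._ln(f"{pre}.ln0", x + ad.dropout(a, c.dropout, rng))
            f = self._ffn(f"{pre}.ff", x, rng)
            x = self._ln(f"{pre}.lnff", x + ad.dropout(f, c.dropout, rng))
        return x

    def decode(self, mem: Tensor, dec_input: Tensor, rng=None) -> Tensor:
        """Causal decoder over pre-embedded input; returns (B, L, V) log-probs."""
        c = self.config
        L = dec_input.shape[1]
        causal = np.triu(np.full((L, L), _NEG, dtype=self.dtype), k=1)
        x = ad.dropout(dec_input, c.dropout, rng)
        for layer in range(c.n_layers):
            pre = f"dec{layer}"
            a = self._attention(f"{pre}.attn0", x, x, causal, rng)
            x = self._ln(f"{pre}.ln0", x + ad.dropout(a, c.dropout, rng))
            a = self._attention(f"{pre}.attn1", x, mem, None, rng)
            x = self._ln(f"{pre}.ln1", x + ad.dropout(a, c.dropout, rng))
            f = self._ffn(f"{pre}.ff", x, rng)
            x = self._ln(f"{pre}.lnff", x + ad.dropout(f, c.dropout, rng))
        logits = x @ self._params["out.W"] + self._params["out.b"]
        return ad.log_softmax(logits, axis=-1)

    def relaxed_decoder_input(self, probs: Tensor) -> Tensor:
        """Decoder input embeddings for relaxed (probability-vector) samples.

        ``probs`` has shape (B, Nout, 21); the returned input is SOS-prefixed
        and drops the last sampled position (shape (B, Nout, d_model) after
        prefixing/truncation), so output row i is conditioned on sampled
        symbols < i.  Embeddings are mixed linearly, keeping the pathway
        differentiable through the sample.
        """
        c = self.config
        B, Nout = probs.shape[0], probs.shape[1]
        E_res = self._params["embed"][: self.tokenizer.n_residues, :]
        mixed = probs @ E_res                                       # (B, Nout, d)
        sos = np.zeros((B, 1, self.tokenizer.total_tokens), dtype=self.dtype)
        sos[:, 0, self.tokenizer.sos_id] = 1.0
        sos_emb = Tensor(sos) @ self._params["embed"]               # (B, 1, d)
        emb = ad.concat([sos_emb, mixed[:, : Nout - 1, :]], axis=1)
        emb = emb * np.sqrt(float(c.d_model))
        pe = sinusoidal_encoding(Nout, c.d_model, self.dtype)
        return emb + pe

    def forward(self, src_tokens: np.ndarray, tgt_in_tokens: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """Teacher-forced log-probabilities, shape (B, len(tgt_in), 24).

        Row i is the model's next-symbol log-distribution given the source
        and decoder input positions ≤ i (causal masking).  ``rng`` enables
        dropout; omit it for deterministic inference.
        """
        mem = self.encode_source(src_tokens, rng)
        return self.decode(mem, self._embed(tgt_in_tokens), rng)

    # ------------------------------------------------------------ inference
    def next_logprobs(self, src_tokens: np.ndarray,
                      prefix_tokens: np.ndarray) -> np.ndarray:
        """Normalized next-symbol log-distributions for an SOS-prefixed prefix."""
        src_tokens = np.atleast_2d(src_tokens)
        prefix_tokens = np.atleast_2d(prefix_tokens)
        if prefix_tokens[0, 0] != self.tokenizer.sos_id:
            raise ValueError("target prefix must start with the SOS token")
        if src_tokens.max() >= self.tokenizer.total_tokens or src_tokens.min() < 0:
            raise ValueError("source tokens out of vocabulary")
        with ad.no_grad():
            return self.forward(src_tokens, prefix_tokens).data

    def conditional_logprobs(self, src_tokens: np.ndarray,
                             tgt_tokens: np.ndarray) -> np.ndarray:
        """log P(a | B, a_<i) over the 21 residue symbols, shape (B, Nout, 21).

        Teacher-forced on the true target; the EOS position is dropped and the
        rows are *not* renormalized over residues (mass on specials stays with
        the model).
        """
        src_tokens = np.atleast_2d(src_tokens)
        tgt_tokens = np.atleast_2d(tgt_tokens)
        sos = np.full((tgt_tokens.shape[0], 1), self.tokenizer.sos_id, dtype=np.int64)
        tgt_in = np.concatenate([sos, tgt_tokens], axis=1)
        with ad.no_grad():
            lp = self.forward(src_tokens, tgt_in).data
        return lp[:, :-1, : self.tokenizer.n_residues]

    # ----------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "seed": self.seed,
                "tokenizer_hash": self.tokenizer.hash(), "kind": "transformer"}
        arrays = {k: p.data for k, p in self._params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path, tokenizer: Tokenizer) -> "TransformerModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["tokenizer_hash"] != tokenizer.hash():
                raise ValueError("checkpoint tokenizer hash mismatch; refusing to load")
            model = cls(ModelConfig(**meta["config"]), tokenizer, seed=meta["seed"])
            for k, p in model._params.items():
                p.data = z[k].astype(model.dtype)
        return model


def build_model(config: ModelConfig | str, tok: Tokenizer,
                seed: int = 0, **overrides) -> TransformerModel:
    """Build a Transformer from a :class:`ModelConfig` or a preset name."""
    if isinstance(config, str):
        config = preset_config(config, **overrides)
    return TransformerModel(config, tok, seed=seed)


class UniformBaseline:
    """Uninformed reference model: probability 1/21 on every residue.

    Useful as the floor for perplexity (PP = 21) and the sanity bound any
    trained model must beat.
    """

    def __init__(self, tokenizer: Tokenizer):
        self.tokenizer = tokenizer

    def conditional_logprobs(self, src_tokens, tgt_tokens):
        tgt_tokens = np.atleast_2d(tgt_tokens)
        B, Nout = tgt_tokens.shape
        n = self.tokenizer.n_residues
        return np.full((B, Nout, n), -np.log(n))
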