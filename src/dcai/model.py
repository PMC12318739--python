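"""The dual cross-attention integration (DCAI) network.

Two modality branches are encoded independently and fused by two
cross-attention modules running in opposite directions:

* structured branch — the 9x4 rating matrix S is embedded row-wise by two
  stacked linear maps with a ReLU, ``S_emb = ReLU((S W1 + b1) W2 + b2)``
  (W1: 4x32, W2: 32x256), giving 9 tokens of width 256, then encoded by a
  six-block transformer encoder;
* image branch — the 32^3 cube is split into 32 axial slices; one shared
  convolution with a full-slice 32x32 kernel and 256 channels turns each
  slice into a token (equivalently, a linear map on the flattened slice),
  then a second six-block transformer encoder.

Cross-attention is single-head scaled dot-product with learned Q/K/V
projections and scale 1/sqrt(d), d = 256.  ``S_CA`` uses image queries over
structured keys/values and ``C_CA`` structured queries over image
keys/values (the subscripts follow the key/value modality, not the query).
Each attended sequence is layer-normalized per token, average-pooled over
tokens to a 256-vector, and the two pooled vectors are concatenated
(structured first) into V in R^512, classified by a single linear layer into
benign (index 0) / malignant (index 1) logits with a cross-entropy loss.

Ablation switches: ``structured_only`` / ``image_only`` drop the other
branch and classify the single pooled vector; ``no_transformer`` replaces
both encoders with the identity; ``no_cross_attention`` pools the encoder
outputs directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, cross_entropy_with_logits, no_grad, softmax
from .nn import (AdamW, Dropout, LayerNorm, Linear, Module, Parameter,
                 TransformerEncoder, _uniform_fan_in)

N_STRUCT_TOKENS = 9
N_IMAGE_TOKENS = 32
SLICE_PIXELS = 32 * 32

ABLATIONS = ("full", "structured_only", "image_only", "no_transformer",
             "no_cross_attention")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the full network: 256-wide tokens, six encoder
    blocks per branch.  Block internals (8 heads, 4x feed-forward, GELU,
    dropout 0.1, pre-norm, learned positional embeddings) are this
    implementation's choices and are all switchable.
    """

    n_transformer_blocks: int = 6
    model_dim: int = 256
    n_heads: int = 8
    ffn_dim: int | None = None  # defaults to 4 * model_dim
    dropout: float = 0.1
    ablation: str = "full"
    positional: bool = True
    struct_hidden: int = 32  # width of the first structured embedding layer
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"choose from {ABLATIONS}")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.model_dim


class StructuredEmbedder(Module):
    """Row-wise two-layer embedding of the rating matrix: (B,9,4) -> (B,9,D)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(4, cfg.struct_hidden, rng)
        self.lin2 = Linear(cfg.struct_hidden, cfg.model_dim, rng)

    def forward(self, s: Tensor) -> Tensor:
        if s.shape[-2:] != (N_STRUCT_TOKENS, 4):
            raise ValueError(f"expected (..., 9, 4) ratings, got {s.shape}")
        return self.lin2(self.lin1(s)).relu()


class VolumeEmbedder(Module):
    """Slice-wise patch embedding of the cube: (B,32,32,32) -> (B,32,D).

    One shared full-slice kernel (32x32, stride 32, no padding) with D output
    channels — realized as a linear map on each flattened slice, which is the
    exact same computation.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(SLICE_PIXELS, cfg.model_dim, rng)

    def forward(self, c: Tensor) -> Tensor:
        if c.shape[-3:] != (32, 32, 32):
            raise ValueError(f"expected (..., 32, 32, 32) cube, got {c.shape}")
        b = c.shape[0]
        return self.proj(c.reshape(b, N_IMAGE_TOKENS, SLICE_PIXELS))


class CrossAttention(Module):
    """Single-head cross-attention: queries from one modality, keys/values
    from the other.  Scale is 1/sqrt(model_dim); no output projection, no
    bias, no residual (layer norm + pooling follow downstream)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.wq = Parameter(_uniform_fan_in(rng, dim, (dim, dim)))
        self.wk = Parameter(_uniform_fan_in(rng, dim, (dim, dim)))
        self.wv = Parameter(_uniform_fan_in(rng, dim, (dim, dim)))
        self.scale = 1.0 / np.sqrt(dim)

    def forward(self, query_seq: Tensor, kv_seq: Tensor) -> Tensor:
        if query_seq.shape[-1] != kv_seq.shape[-1]:
            raise ValueError(
                f"feature dims differ: {query_seq.shape} vs {kv_seq.shape}")
        q = query_seq @ self.wq
        k = kv_seq @ self.wk
        v = kv_seq @ self.wv
        att = softmax((q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2))
                      * self.scale)
        return att @ v

    def attention_weights(self, query_seq: Tensor, kv_seq: Tensor) -> np.ndarray:
        """Softmax attention matrix (for inspection/tests)."""
        with no_grad():
            q = query_seq @ self.wq
            k = kv_seq @ self.wk
            att = softmax(
                (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2))
                * self.scale)
        return att.data


class PoolNorm(Module):
    """Per-token layer norm followed by average pooling over tokens."""

    def __init__(self, dim: int):
        super().__init__()
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-2] == 0:
            raise ValueError("cannot pool an empty token sequence")
        return self.norm(x).mean(axis=-2)


class DCAIModel(Module):
    """Full network; ``forward`` maps a batch of samples to logits.

    Inputs: ``s`` — (B, 9, 4) rating matrices already scaled to [0, 1];
    ``c`` — (B, 32, 32, 32) cubes in [0, 1].
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        dim = cfg.model_dim
        use_struct = cfg.ablation != "image_only"
        use_image = cfg.ablation != "structured_only"

        if use_struct:
            self.struct_embed = StructuredEmbedder(cfg, rng)
            if cfg.positional:
                self.struct_pos = Parameter(
                    0.02 * rng.standard_normal((N_STRUCT_TOKENS, dim)))
            if cfg.ablation != "no_transformer":
                self.struct_encoder = TransformerEncoder(
                    dim, cfg.n_transformer_blocks, cfg.n_heads, cfg.ffn_dim,
                    cfg.dropout, rng)
        if use_image:
            self.volume_embed = VolumeEmbedder(cfg, rng)
            if cfg.positional:
                self.image_pos = Parameter(
                    0.02 * rng.standard_normal((N_IMAGE_TOKENS, dim)))
            if cfg.ablation != "no_transformer":
                self.image_encoder = TransformerEncoder(
                    dim, cfg.n_transformer_blocks, cfg.n_heads, cfg.ffn_dim,
                    cfg.dropout, rng)
        if use_struct and use_image and cfg.ablation != "no_cross_attention":
            # S_CA: image queries over structured keys/values; C_CA: the reverse.
            self.cross_s = CrossAttention(dim, rng)
            self.cross_c = CrossAttention(dim, rng)
        if use_struct:
            self.pool_s = PoolNorm(dim)
        if use_image:
            self.pool_c = PoolNorm(dim)
        n_final = (int(use_struct) + int(use_image)) * dim
        self.classifier = Linear(n_final, 2, rng)

    # -- branch pieces -------------------------------------------------------
    def _encode_structured(self, s: Tensor) -> Tensor:
        x = self.struct_embed(s)
        if self.config.positional:
            x = x + self.struct_pos
        if self.config.ablation == "no_transformer":
            return x
        return self.struct_encoder(x)

    def _encode_image(self, c: Tensor) -> Tensor:
        x = self.volume_embed(c)
        if self.config.positional:
            x = x + self.image_pos
        if self.config.ablation == "no_transformer":
            return x
        return self.image_encoder(x)

    def forward(self, s: Tensor | np.ndarray | None,
                c: Tensor | np.ndarray | None) -> Tensor:
        cfg = self.config
        if s is not None and not isinstance(s, Tensor):
            s = Tensor(s)
        if c is not None and not isinstance(c, Tensor):
            c = Tensor(c)
        if cfg.ablation == "structured_only":
            return self.classifier(self.pool_s(self._encode_structured(s)))
        if cfg.ablation == "image_only":
            return self.classifier(self.pool_c(self._encode_image(c)))
        s_enc = self._encode_structured(s)
        c_enc = self._encode_image(c)
        if cfg.ablation == "no_cross_attention":
            s_final = self.pool_s(s_enc)
            c_final = self.pool_c(c_enc)
        else:
            s_ca = self.cross_s(c_enc, s_enc)  # 32 tokens, structured content
            c_ca = self.cross_c(s_enc, c_enc)  # 9 tokens, image content
            s_final = self.pool_s(s_ca)
            c_final = self.pool_c(c_ca)
        v = concat([s_final, c_final], axis=-1)
        return self.classifier(v)

    def loss(self, s, c, labels: np.ndarray) -> Tensor:
        return cross_entropy_with_logits(self.forward(s, c), labels)

    def predict_proba(self, s, c) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(s, c)
                return softmax(logits).data
        finally:
            self.train(was_training)

    def predict(self, s, c) -> np.ndarray:
        return self.predict_proba(s, c).argmax(axis=-1)


# ---------------------------------------------------------------------------
# checkpoints: weights file + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: DCAIModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path,
                    expected_config: ModelConfig | None = None) -> DCAIModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    cfg = ModelConfig(**json.loads(sidecar.read_text()))
    if expected_config is not None and asdict(cfg) != asdict(expected_config):
        raise ValueError("checkpoint config does not match the expected config")
    model = DCAIModel(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
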