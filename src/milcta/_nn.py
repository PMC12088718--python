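"""Neural-network layers, backbones and optimizer for the MIL classifier.

Built on the in-package autodiff engine.  The network mirrors the framework's
stages: a shared convolutional encoder applied per slice, additive sinusoidal
positional encoding of the in-bag index, one pre-norm multi-head
self-attention block across the 36 instances, gated attention pooling to a
bag embedding, and a small dense classifier head.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat_last, conv2d_3x3, global_max, layer_norm, maxpool2x2, softmax


class Parameter(Tensor):
    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.decay = decay  # whether L2 regularization applies


class Module:
    """Base class: parameter discovery and state (de)serialization."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            p.data = a.astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(_he_init(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv3x3(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        self.w = Parameter(_he_init(rng, (c_out, c_in, 3, 3), c_in * 9))
        self.b = Parameter(np.zeros(c_out), decay=False)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_3x3(x, self.w, self.b, stride=self.stride)

    def freeze(self) -> None:
        self.w.requires_grad = False
        self.b.requires_grad = False


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim), decay=False)
        self.beta = Parameter(np.zeros(dim), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class SmallCNN(Module):
    """Four stride-2 conv/relu blocks → global pooling → embedding.

    Global pooling concatenates average and maximum responses: the max
    channel keeps small localized structures (a single plaque blob) visible
    in the slice embedding instead of being diluted by averaging.
    """

    def __init__(self, embed_dim: int, rng: np.random.Generator, channels=(8, 16, 32, 64)):
        self.convs = [
            Conv3x3(c_in, c_out, rng, stride=2)
            for c_in, c_out in zip((1,) + tuple(channels[:-1]), channels)
        ]
        self.proj = Dense(2 * channels[-1], embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        B, C = x.data.shape[:2]
        flat = x.reshape(B, C, x.data.shape[2] * x.data.shape[3])
        pooled = concat_last(flat.mean(axis=2), global_max(flat))
        return self.proj(pooled)


#: VGG16 convolutional layout; 'M' marks a max-pooling layer.  Layer indices
#: for freezing count sequentially and include pooling layers.
_VGG16_LAYOUT = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M")


class VGG16Style(Module):
    """VGG16-shaped encoder (optionally width-scaled) with layer freezing.

    ``frozen_layers`` counts sequential layers including pooling; the
    parameters of convolutions at frozen indices are excluded from gradient
    updates.  External pretrained weights can be loaded via
    :meth:`load_state_arrays`.
    """

    def __init__(self, embed_dim: int, rng: np.random.Generator, frozen_layers: int = 15, width_scale: float = 1.0):
        self.layout: list = []
        c_in = 1
        self.convs = []
        for i, item in enumerate(_VGG16_LAYOUT):
            if item == "M":
                self.layout.append("M")
            else:
                c_out = max(4, int(round(item * width_scale)))
                conv = Conv3x3(c_in, c_out, rng)
                if i < frozen_layers:
                    conv.freeze()
                self.convs.append(conv)
                self.layout.append(conv)
                c_in = c_out
        self.frozen_layers = frozen_layers
        self.proj = Dense(c_in, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for item in self.layout:
            if item == "M":
                x = maxpool2x2(x)
            else:
                x = item(x).relu()
        return self.proj(x.mean(axis=(2, 3)))


def sinusoidal_positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Standard transformer sin/cos encoding of instance position."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(np.float32)


class MultiHeadSelfAttention(Module):
    """One pre-norm multi-head self-attention block with residual connection."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"embed_dim {dim} must be divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.dim = dim
        self.norm = LayerNorm(dim)
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)
        # zero-init the output projection: the block starts as the identity
        # and learns to mix context, which stabilizes small-data training
        self.wo.w.data[:] = 0.0

    def __call__(self, x: Tensor, branch_mask: np.ndarray | None = None) -> Tensor:
        """Apply the block; ``branch_mask`` (B,) gates the context branch.

        During training the context branch is dropped stochastically per bag
        (stochastic depth).  Without the shortcut through mixed context the
        bag prediction must be recoverable from instance-local features,
        which keeps the pooling attention anchored to the evidence-carrying
        instances instead of off-loading them into every other instance.
        """
        B, N, D = x.data.shape
        h, dh = self.n_heads, self.dim // self.n_heads
        xn = self.norm(x)

        def split(t: Tensor) -> Tensor:  # (B,N,D) -> (B,h,N,dh)
            return t.reshape(B, N, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(xn)), split(self.wk(xn)), split(self.wv(xn))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        out = self.wo(ctx)
        if branch_mask is not None:
            out = out * Tensor(branch_mask[:, None, None].astype(x.data.dtype))
        return x + out


class GatedAttentionPool(Module):
    """Gated attention pooling: score_i = w·(tanh(V h_i) ⊙ σ(U h_i))."""

    def __init__(self, dim: int, attn_dim: int, rng: np.random.Generator, gated: bool = True):
        self.gated = gated
        self.v = Dense(dim, attn_dim, rng)
        self.u = Dense(dim, attn_dim, rng)
        self.w = Dense(attn_dim, 1, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (bag embedding (B,D), attention weights (B,N))."""
        gate = self.v(x).tanh()
        if self.gated:
            gate = gate * self.u(x).sigmoid()
        scores = self.w(gate)  # (B,N,1)
        attn = softmax(scores.transpose(0, 2, 1), axis=-1)  # (B,1,N)
        pooled = (attn @ x).reshape(x.data.shape[0], x.data.shape[2])
        return pooled, attn.reshape(x.data.shape[0], x.data.shape[1])


class MILNet(Module):
    """Bag-of-slices classifier producing a bag logit and attention scores."""

    def __init__(
        self,
        backbone: str,
        input_size: tuple[int, int],
        bag_size: int,
        embed_dim: int,
        n_heads: int,
        attn_dim: int,
        dropout: float,
        positional_encoding: str,
        rng: np.random.Generator,
        frozen_layers: int = 0,
        small_cnn_channels=(8, 16, 32, 64),
        vgg_width_scale: float = 1.0,
        gated_pool: bool = True,
        context_dropout: float = 0.5,
    ):
        if backbone == "small_cnn":
            self.encoder: Module = SmallCNN(embed_dim, rng, channels=small_cnn_channels)
        elif backbone == "vgg16_style":
            self.encoder = VGG16Style(embed_dim, rng, frozen_layers=frozen_layers, width_scale=vgg_width_scale)
        else:
            raise ValueError(f"unknown backbone {backbone!r}")
        self.bag_size = bag_size
        self.input_size = tuple(input_size)
        self.dropout = dropout
        if positional_encoding not in ("sinusoidal", "none"):
            raise ValueError("positional_encoding must be 'sinusoidal' or 'none'")
        self.pe = (
            sinusoidal_positional_encoding(bag_size, embed_dim) if positional_encoding == "sinusoidal" else None
        )
        self.context_dropout = context_dropout
        self.mha = MultiHeadSelfAttention(embed_dim, n_heads, rng)
        self.pool = GatedAttentionPool(embed_dim, attn_dim, rng, gated=gated_pool)
        self.head1 = Dense(embed_dim, 64, rng)
        self.head2 = Dense(64, 1, rng)

    def embed(self, x: Tensor) -> Tensor:
        """Shared encoder applied independently per slice: (B,N,H,W)→(B,N,D)."""
        B, N, H, W = x.data.shape
        flat = x.reshape(B * N, 1, H, W)
        feats = self.encoder(flat)
        return feats.reshape(B, N, feats.data.shape[-1])

    def forward(self, x_bags: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Return (logits (B,), attention (B,N)) for a stack of bags."""
        x = Tensor(np.asarray(x_bags))
        feats = self.embed(x)
        if self.pe is not None:
            feats = feats + Tensor(self.pe[None, : feats.data.shape[1], :])
        branch_mask = None
        if train and self.context_dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            branch_mask = (rng.random(x.data.shape[0]) >= self.context_dropout).astype(np.float64)
        ctx = self.mha(feats, branch_mask=branch_mask)
        pooled, attn = self.pool(ctx)
        hidden = self.head1(pooled).relu()
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(hidden.data.shape) < keep).astype(hidden.data.dtype) / keep
            hidden = hidden * Tensor(mask)
        logits = self.head2(hidden).reshape(x.data.shape[0])
        return logits, attn


def bce_with_logits(logits: Tensor, targets: np.ndarray, sample_weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable (optionally weighted) binary cross-entropy."""
    y = np.asarray(targets, dtype=logits.data.dtype)
    pos = logits.relu()
    absz = pos + (-logits).relu()
    loss = pos - logits * Tensor(y) + ((-absz).exp() + 1.0).log()
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=logits.data.dtype)
        return (loss * Tensor(w)).sum() * (1.0 / max(float(w.sum()), 1e-12))
    return loss.mean()


class Adam:
    """ADAM optimizer with L2 regularization added to the gradient (2·λ·w)."""

    def __init__(self, params: list[Parameter], lr: float, l2: float = 0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.l2 = l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2 > 0 and getattr(p, "decay", False):
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
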