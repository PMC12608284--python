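"""The DIFNet architecture.

Multiscale temporal convolution (three parallel kernel lengths acting as
coarse band-selective filters, each followed by a depthwise spatial
convolution that collapses the electrode axis), a Transformer encoder for
global sequence dependencies, a dilated-causal TCN for local temporal
refinement, and a demographic fusion stage that condenses normalized
age/sex/education into one learned scalar F multiplying the spatiotemporal
feature map before the softmax classification head.

Module order is configurable so ablation variants (baseline, +T1, +T2,
+T2+T1, +T1+T2) differ only in which blocks are present and their sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    SpatialConv,
    Tensor,
    concat,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MultiscaleConfig",
    "TransformerConfig",
    "TCNConfig",
    "FusionConfig",
    "DifnetConfig",
    "scaled_dot_attention",
    "multi_head_attention",
    "MultiHeadAttention",
    "MultiscaleBlock",
    "TransformerEncoder",
    "TCNBlock",
    "TCN",
    "FusionHead",
    "DIFNet",
    "build_difnet",
    "receptive_field",
    "normalize_demographics",
    "INDICATOR_COLUMNS",
    "VARIANT_CODES",
    "MODULE_ORDERS",
]

#: Fusion variant codes -> demographic table columns, in fixed order.
INDICATOR_COLUMNS = {"A": "age", "S": "sex", "Y": "education_years"}
VARIANT_CODES = ("N", "A", "S", "Y", "AS", "AY", "SY", "ASY")
MODULE_ORDERS = ("baseline", "T1", "T2", "T2T1", "T1T2")


# --------------------------------------------------------------------------
# configuration records
# --------------------------------------------------------------------------

@dataclass
class MultiscaleConfig:
    kernel_sizes: tuple[int, ...] = (250, 125, 62)
    temporal_filters: int = 16          # F1, filters per parallel branch
    n_channels: int = 16                # N_C electrodes
    depth_multiplier: int = 2
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5

    @property
    def out_channels(self) -> int:
        return len(self.kernel_sizes) * self.temporal_filters * self.depth_multiplier

    def out_length(self, n_samples: int) -> int:
        return (n_samples // self.pool1) // self.pool2


@dataclass
class TransformerConfig:
    n_layers: int = 2
    n_heads: int = 6
    head_dim: int = 16
    ffn_ratio: int = 4
    dropout: float = 0.5
    positional_encoding: bool = False
    adapt_width: bool = True  # re-derive heads when the incoming width differs

    @property
    def model_dim(self) -> int:
        return self.n_heads * self.head_dim


@dataclass
class TCNConfig:
    n_blocks: int = 2          # L
    filters: int = 32
    kernel: int = 4            # K_T (TCN-local; distinct from multiscale kernels)
    dropout: float = 0.3

    def dilations(self) -> list[int]:
        return [2**i for i in range(self.n_blocks)]


@dataclass
class FusionConfig:
    indicators: str = "N"      # one of VARIANT_CODES
    conv_width: int = 3
    conv_filters: int = 8

    def __post_init__(self):
        if self.indicators not in VARIANT_CODES:
            raise ValueError(
                f"unknown fusion code {self.indicators!r}; choose from {VARIANT_CODES}"
            )

    @property
    def columns(self) -> list[str]:
        return [INDICATOR_COLUMNS[c] for c in self.indicators if c != "N"]

    @property
    def n_active(self) -> int:
        return len(self.columns)


@dataclass
class DifnetConfig:
    multiscale: MultiscaleConfig = field(default_factory=MultiscaleConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    tcn: TCNConfig = field(default_factory=TCNConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    module_order: str = "T1T2"
    n_classes: int = 2
    n_samples: int = 1000      # epoch length the head is sized for

    def __post_init__(self):
        if self.module_order not in MODULE_ORDERS:
            raise ValueError(
                f"unknown module order {self.module_order!r}; choose from {MODULE_ORDERS}"
            )

    def variant_name(self) -> str:
        return f"DIFNet-{self.fusion.indicators}"


# --------------------------------------------------------------------------
# attention
# --------------------------------------------------------------------------

def scaled_dot_attention(q, k, v):
    """Scaled dot-product attention.

    ``softmax(Q K^T / sqrt(d_k)) V`` over the last two axes; accepts numpy
    arrays (returns an array) or Tensors (returns a Tensor, differentiable).
    Leading batch axes broadcast.
    """
    as_array = not isinstance(q, Tensor)
    qt, kt, vt = (x if isinstance(x, Tensor) else Tensor(x) for x in (q, k, v))
    if qt.shape[-2] == 0 or kt.shape[-2] == 0:
        raise ValueError("attention requires non-empty query and key matrices")
    if qt.shape[-1] != kt.shape[-1]:
        raise ValueError("query and key dimensions differ")
    if kt.shape[-2] != vt.shape[-2]:
        raise ValueError("key and value row counts differ")
    d_k = qt.shape[-1]
    scores = (qt @ kt.transpose(*range(kt.ndim - 2), kt.ndim - 1, kt.ndim - 2)
              ) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    out = weights @ vt
    return out.data if as_array else out


def attention_weights(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """The softmax weight matrix of scaled dot-product attention."""
    d_k = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def multi_head_attention(x, wq, wk, wv, wo, n_heads: int):
    """Functional multi-head attention on a (n, d_model) sequence.

    Projections are (d_model, d_model); the sequence is split into
    ``n_heads`` subspaces, attended in parallel, concatenated and projected
    back.  Contains no positional term, so it is permutation-equivariant.
    """
    as_array = not isinstance(x, Tensor)
    xt = x if isinstance(x, Tensor) else Tensor(x)
    n, d = xt.shape[-2], xt.shape[-1]
    if d % n_heads:
        raise ValueError(f"model dim {d} not divisible by {n_heads} heads")
    wq, wk, wv, wo = (w if isinstance(w, Tensor) else Tensor(w)
                      for w in (wq, wk, wv, wo))
    dh = d // n_heads

    def split(t):  # (..., n, d) -> (..., H, n, dh)
        lead = t.shape[:-2]
        t = t.reshape(*lead, n, n_heads, dh)
        axes = tuple(range(len(lead))) + (t.ndim - 3 + 1, t.ndim - 3, t.ndim - 1)
        return t.transpose(*axes)

    q, k, v = split(xt @ wq), split(xt @ wk), split(xt @ wv)
    heads = scaled_dot_attention(q, k, v)       # (..., H, n, dh)
    lead = heads.shape[:-3]
    axes = tuple(range(len(lead))) + (heads.ndim - 2, heads.ndim - 3, heads.ndim - 1)
    merged = heads.transpose(*axes).reshape(*lead, n, d)
    out = merged @ wo
    return out.data if as_array else out


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"model dim {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        scale = np.sqrt(1.0 / d_model)
        self.wq, self.wk, self.wv, self.wo = (
            Tensor(rng.uniform(-scale, scale, size=(d_model, d_model)),
                   requires_grad=True)
            for _ in range(4)
        )

    def __call__(self, x: Tensor) -> Tensor:
        return multi_head_attention(x, self.wq, self.wk, self.wv, self.wo,
                                    self.n_heads)


# --------------------------------------------------------------------------
# multiscale convolutional block
# --------------------------------------------------------------------------

class MultiscaleBlock(Module):
    """Three parallel temporal-kernel branches over (B, 1, C, T).

    Each branch: temporal convolution (1 x K_i, same padding, F1 filters)
    -> depthwise spatial convolution collapsing the C electrodes (multiplier
    M) -> batch normalization -> ELU -> average pool (1, pool1) -> dropout.
    Branch outputs concatenate on the channel axis and are pooled again by
    (1, pool2), yielding (B, 3*F1*M, T // pool1 // pool2).

    The ELU before pooling is essential, not cosmetic: average-pooling a
    raw (signed) filter response cancels oscillatory energy, so band *power*
    would be invisible downstream; rectifying first turns the pool into a
    band-energy detector, the standard depthwise-separable EEG front-end
    design.
    """

    def __init__(self, cfg: MultiscaleConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.temporal = [
            Conv1d(1, cfg.temporal_filters, k, rng, padding="same", bias=False)
            for k in cfg.kernel_sizes
        ]
        self.spatial = [
            SpatialConv(cfg.temporal_filters, cfg.n_channels,
                        cfg.depth_multiplier, rng)
            for _ in cfg.kernel_sizes
        ]
        self.norm = [BatchNorm1d(cfg.temporal_filters * cfg.depth_multiplier)
                     for _ in cfg.kernel_sizes]
        self.drop = [Dropout(cfg.dropout) for _ in cfg.kernel_sizes]

    def __call__(self, x: Tensor) -> Tensor:
        b, one, c, t = x.shape
        if one != 1:
            raise ValueError("expected input (batch, 1, channels, samples)")
        if max(self.cfg.kernel_sizes) > t:
            raise ValueError(
                f"kernel {max(self.cfg.kernel_sizes)} exceeds epoch length {t}"
            )
        flat = x.reshape(b * c, 1, t)
        branches = []
        for conv, spatial, norm, drop in zip(self.temporal, self.spatial,
                                             self.norm, self.drop):
            h = conv(flat)                                   # (B*C, F1, T)
            h = h.reshape(b, c, self.cfg.temporal_filters, t)
            h = h.transpose(0, 2, 1, 3)                      # (B, F1, C, T)
            h = spatial(h)                                   # (B, F1*M, T)
            h = norm(h).elu()
            h = h.avg_pool1d(self.cfg.pool1)
            branches.append(drop(h))
        out = concat(branches, axis=1)
        return out.avg_pool1d(self.cfg.pool2)


# --------------------------------------------------------------------------
# transformer encoder
# --------------------------------------------------------------------------

def sinusoidal_encoding(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return enc


class _EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ff2(self.ff1(x).elu())))
        return x


class TransformerEncoder(Module):
    """N identical layers of multi-head self-attention + position-wise FFN,
    each wrapped in residual + layer normalization; shape preserving on
    (B, n, d_model)."""

    def __init__(self, cfg: TransformerConfig, d_model: int,
                 rng: np.random.Generator):
        super().__init__()
        n_heads = cfg.n_heads
        if d_model != cfg.model_dim:
            if not cfg.adapt_width:
                raise ValueError(
                    f"transformer boundary mismatch: incoming width {d_model} "
                    f"!= configured model dim {cfg.model_dim}"
                )
            n_heads = max(h for h in range(1, cfg.n_heads + 1) if d_model % h == 0)
            logger.info("transformer adapted to width %d with %d heads",
                        d_model, n_heads)
        self.d_model = d_model
        self.n_heads = n_heads
        self.positional = cfg.positional_encoding
        self.layers = [
            _EncoderLayer(d_model, n_heads, cfg.ffn_ratio * d_model,
                          cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_model:
            raise ValueError(
                f"transformer boundary mismatch: got width {x.shape[-1]}, "
                f"expected {self.d_model}"
            )
        if self.positional:
            x = x + Tensor(sinusoidal_encoding(x.shape[-2], self.d_model))
        for layer in self.layers:
            x = layer(x)
        return x


# --------------------------------------------------------------------------
# temporal convolutional network
# --------------------------------------------------------------------------

def receptive_field(n_blocks: int, kernel: int) -> int:
    """Receptive field of a TCN with ``n_blocks`` residual blocks (two
    dilated causal convolutions each, dilation doubling per block):
    1 + 2*(K-1)*(2^L - 1) samples."""
    if n_blocks < 1 or kernel < 1:
        raise ValueError("n_blocks and kernel must be positive")
    return 1 + 2 * (kernel - 1) * (2**n_blocks - 1)


class TCNBlock(Module):
    """One residual block: two dilated causal convolutions, each followed by
    batch normalization, ELU and dropout; 1x1 projection on the skip path
    when channel counts differ."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(c_in, c_out, kernel, rng, dilation=dilation,
                            padding="causal")
        self.bn1 = BatchNorm1d(c_out)
        self.conv2 = Conv1d(c_out, c_out, kernel, rng, dilation=dilation,
                            padding="causal")
        self.bn2 = BatchNorm1d(c_out)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)
        self.projection = (Conv1d(c_in, c_out, 1, rng, padding="same", bias=False)
                           if c_in != c_out else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop1(self.bn1(self.conv1(x)).elu())
        h = self.drop2(self.bn2(self.conv2(h)).elu())
        skip = self.projection(x) if self.projection is not None else x
        return h + skip


class TCN(Module):
    def __init__(self, cfg: TCNConfig, c_in: int, rng: np.random.Generator,
                 seq_len: int | None = None):
        super().__init__()
        self.cfg = cfg
        if seq_len is not None and receptive_field(cfg.n_blocks, cfg.kernel) > seq_len:
            warnings.warn(
                f"TCN receptive field {receptive_field(cfg.n_blocks, cfg.kernel)} "
                f"exceeds sequence length {seq_len}", stacklevel=2
            )
        self.blocks = []
        for i, d in enumerate(cfg.dilations()):
            self.blocks.append(
                TCNBlock(c_in if i == 0 else cfg.filters, cfg.filters,
                         cfg.kernel, d, cfg.dropout, rng)
            )

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


# --------------------------------------------------------------------------
# demographic normalization and fusion
# --------------------------------------------------------------------------

def normalize_demographics(table: pd.DataFrame, columns: list[str],
                           stats: dict[str, tuple[float, float]] | None = None,
                           ) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Min-max normalize the active indicator columns to [0, 1].

    When ``stats`` is None the min/max are fitted on ``table`` (do this on
    the training partition only); otherwise the supplied frozen stats are
    applied and out-of-range values are clipped with a warning, so held-out
    subjects can never leak into the fit.
    """
    if not columns:
        return np.zeros((len(table), 0)), {}
    fitted = stats is None
    if fitted:
        stats = {}
        for col in columns:
            lo, hi = float(table[col].min()), float(table[col].max())
            if hi == lo:
                raise ValueError(f"indicator {col!r} is degenerate (min == max)")
            stats[col] = (lo, hi)
    out = np.empty((len(table), len(columns)))
    for j, col in enumerate(columns):
        lo, hi = stats[col]
        vals = (table[col].to_numpy(dtype=np.float64) - lo) / (hi - lo)
        if not fitted and ((vals < 0) | (vals > 1)).any():
            warnings.warn(
                f"indicator {col!r} outside the fitted [min, max]; clipping",
                stacklevel=2,
            )
        out[:, j] = np.clip(vals, 0.0, 1.0)
    return out, stats


class FusionHead(Module):
    """Condense a (B, d) indicator vector into one scalar F per example.

    The vector is tiled across the sequence axis to (B, d, n), convolved
    (width ``conv_width``, same padding), globally average-pooled and mapped
    by a dense layer through a sigmoid scaled to (0, 2), so F is bounded and
    centered on 1 (identity-like) at initialization.  The dense weights get
    a unit-normal spread rather than a near-zero start: an exactly-identity
    start leaves the demographic pathway without gradient until the EEG
    branch has already fit the training data, which starves fusion of any
    chance to contribute.
    """

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.n_active == 0:
            raise ValueError("fusion head requires at least one active indicator")
        self.cfg = cfg
        self.conv = Conv1d(cfg.n_active, cfg.conv_filters, cfg.conv_width, rng,
                           padding="same")
        self.dense = Linear(cfg.conv_filters, 1, rng)
        self.dense.weight.data[...] = rng.normal(size=self.dense.weight.shape)

    def scalar(self, demo: Tensor, n: int) -> Tensor:
        b, d = demo.shape
        tiled = demo.reshape(b, d, 1) * Tensor(np.ones((1, 1, n)))
        h = self.conv(tiled).elu()
        pooled = h.mean(axis=-1)          # global average pool -> (B, filters)
        return self.dense(pooled).sigmoid() * 2.0   # (B, 1) in (0, 2)

    def __call__(self, features: Tensor, demo: Tensor) -> Tensor:
        f = self.scalar(demo, features.shape[-1])
        return features * f.reshape(f.shape[0], 1, 1)


# --------------------------------------------------------------------------
# the assembled network
# --------------------------------------------------------------------------

class DIFNet(Module):
    """Multiscale conv -> (T1/T2 per ``module_order``) -> demographic fusion
    -> flatten -> dense softmax head."""

    def __init__(self, cfg: DifnetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ms = cfg.multiscale
        self.multiscale = MultiscaleBlock(ms, rng)
        width = ms.out_channels
        seq_len = ms.out_length(cfg.n_samples)
        self.block_sequence: list[str] = ["multiscale"]
        self.transformer = None
        self.tcn = None
        order = cfg.module_order
        stages = {"baseline": [], "T1": ["T1"], "T2": ["T2"],
                  "T2T1": ["T2", "T1"], "T1T2": ["T1", "T2"]}[order]
        for stage in stages:
            if stage == "T1":
                if not cfg.transformer.adapt_width and width != cfg.transformer.model_dim:
                    raise ValueError(
                        f"boundary multiscale->transformer: width {width} != "
                        f"model dim {cfg.transformer.model_dim}"
                    )
                self.transformer = TransformerEncoder(cfg.transformer, width, rng)
                self.block_sequence.append("transformer")
            else:
                self.tcn = TCN(cfg.tcn, width, rng, seq_len=seq_len)
                width = cfg.tcn.filters
                self.block_sequence.append("tcn")
        self.fusion = (FusionHead(cfg.fusion, rng)
                       if cfg.fusion.indicators != "N" else None)
        if self.fusion is not None:
            self.block_sequence.append("fusion")
        self.head = Linear(width * seq_len, cfg.n_classes, rng)
        self.block_sequence.append("dense_softmax")
        self._head_in = width * seq_len
        self._stages = stages

    def forward(self, x, demo=None) -> Tensor:
        """Logits for a batch.

        ``x``: (B, 1, C, T) array or Tensor; ``demo``: (B, d) normalized
        indicators (required iff the fusion code is not N).
        """
        xt = x if isinstance(x, Tensor) else Tensor(x)
        h = self.multiscale(xt)            # (B, ch, n)
        for stage in self._stages:
            if stage == "T1":
                h = self.transformer(h.transpose(0, 2, 1)).transpose(0, 2, 1)
            else:
                h = self.tcn(h)
        if self.fusion is not None:
            if demo is None:
                raise ValueError(
                    f"variant {self.cfg.variant_name()} requires demographics"
                )
            dt = demo if isinstance(demo, Tensor) else Tensor(demo)
            h = self.fusion(h, dt)
        b = h.shape[0]
        return self.head(h.reshape(b, self._head_in))

    __call__ = forward

    def predict_proba(self, x, demo=None) -> np.ndarray:
        self.eval()
        return self.forward(x, demo).softmax(axis=-1).data

    def fingerprint(self) -> dict:
        return {
            "variant": self.cfg.variant_name(),
            "module_order": self.cfg.module_order,
            "blocks": list(self.block_sequence),
            "n_parameters": self.n_parameters(),
            "head_input": self._head_in,
            "config": {
                "multiscale": asdict(self.cfg.multiscale),
                "transformer": asdict(self.cfg.transformer),
                "tcn": asdict(self.cfg.tcn),
                "fusion": asdict(self.cfg.fusion),
            },
        }


def build_difnet(cfg: DifnetConfig, seed: int = 0) -> DIFNet:
    """Construct a seeded DIFNet; weight init and dropout both derive from
    ``seed``, so two models built with the same seed are identical."""
    seq = np.random.SeedSequence(seed)
    init_seq, drop_seq = seq.spawn(2)
    model = DIFNet(cfg, np.random.default_rng(init_seq))
    model.seed_dropout(np.random.default_rng(drop_seq))
    return model


def config_to_yaml(cfg: DifnetConfig, path) -> None:
    """Write a DifnetConfig as YAML (field names mirror the dataclasses)."""
    import yaml

    payload = {
        "multiscale": asdict(cfg.multiscale),
        "transformer": asdict(cfg.transformer),
        "tcn": asdict(cfg.tcn),
        "fusion": asdict(cfg.fusion),
        "module_order": cfg.module_order,
        "n_classes": cfg.n_classes,
        "n_samples": cfg.n_samples,
    }
    payload["multiscale"]["kernel_sizes"] = list(cfg.multiscale.kernel_sizes)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> DifnetConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ms = raw.get("multiscale", {})
    if "kernel_sizes" in ms:
        ms["kernel_sizes"] = tuple(ms["kernel_sizes"])
    return DifnetConfig(
        multiscale=MultiscaleConfig(**ms),
        transformer=TransformerConfig(**raw.get("transformer", {})),
        tcn=TCNConfig(**raw.get("tcn", {})),
        fusion=FusionConfig(**raw.get("fusion", {})),
        module_order=raw.get("module_order", "T1T2"),
        n_classes=raw.get("n_classes", 2),
        n_samples=raw.get("n_samples", 1000),
    )


def save_checkpoint(model: DIFNet, path) -> None:
    """Weights + normalization statistics as npz, with the architecture
    fingerprint in a JSON sidecar for ablation bookkeeping."""
    import json
    from pathlib import Path

    path = Path(path)
    state = model.state()
    np.savez_compressed(path, **{f"arr_{i}": a for i, a in enumerate(state)})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(model.fingerprint(), fh, indent=2)


def load_checkpoint(model: DIFNet, path) -> DIFNet:
    from pathlib import Path

    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as npz:
        state = [npz[f"arr_{i}"] for i in range(len(npz.files))]
    model.load_state(state)
    return model


def compact_config(indicators: str = "N", module_order: str = "T1T2",
                   n_channels: int = 16, n_samples: int = 1000) -> DifnetConfig:
    """Desk-scale configuration: the same topology with two temporal filters
    per branch, a single-layer encoder and an 8-filter TCN, so a
    cross-validated run finishes in CPU-minutes.  The full-size architecture
    is the dataclass default.
    """
    return DifnetConfig(
        multiscale=MultiscaleConfig(kernel_sizes=(62, 31, 15),
                                    temporal_filters=2,
                                    n_channels=n_channels,
                                    dropout=0.25),
        transformer=TransformerConfig(n_layers=1, n_heads=2, head_dim=6,
                                      dropout=0.25),
        tcn=TCNConfig(filters=8, dropout=0.15),
        fusion=FusionConfig(indicators=indicators),
        module_order=module_order,
        n_samples=n_samples,
    )
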