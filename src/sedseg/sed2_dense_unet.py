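"""Stage-2 tumor-extraction network: a fully convolutional DenseNet
("dense U-Net") built from dense blocks (DB), transition-down (TD) and
transition-up (TU) modules.

Channel bookkeeping, which the whole architecture hangs on:

* an encoder dense block concatenates its input with every layer's new
  features, so ``m`` input channels and ``n`` layers at growth rate ``k``
  yield ``m + n*k`` output channels;
* a transition down preserves channels and halves the spatial dims
  (1x1 conv + 2x2 max pool);
* a transition up upsamples *only the new features* of the preceding
  dense block by a stride-2 transposed convolution, so its width is
  ``n*k``;
* a decoder dense block emits only its new features (``n*k``) to keep
  the upsampling path from ballooning.

With a 48-channel initial convolution, growth rate 16, encoder blocks of
(4, 5, 7, 10, 12) layers and a 15-layer bottleneck, the encoder ledger is
112 / 192 / 304 / 464 / 656 and the bottleneck concatenation reaches
656 + 15*16 = 896 channels.  (The published per-layer table prints 880
for that cell, which is inconsistent with its own ledger; 896 is the
arithmetically forced value and the one this builder produces.)
"""

from __future__ import annotations

from dataclasses import dataclass

from .netgraph import LayerGraph, propagate_shapes
from .nn import GraphModel

__all__ = [
    "Sed2Config",
    "Sed2BuildError",
    "dense_block_channels",
    "transition_down_shape",
    "transition_up_channels",
    "build_sed2",
    "build_sed2_model",
]


class Sed2BuildError(ValueError):
    """The built graph's channel ledger disagrees with the configuration."""


@dataclass
class Sed2Config:
    growth_rate: int = 16
    encoder_block_layers: tuple = (4, 5, 7, 10, 12)
    bottleneck_layers: int = 15
    decoder_block_layers: tuple = (12, 10, 7, 5, 4)
    initial_conv_channels: int = 48
    input_size: tuple = (256, 256, 1)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if len(self.encoder_block_layers) != len(self.decoder_block_layers):
            raise ValueError("encoder and decoder must have the same number of blocks")
        h, w, _ = self.input_size
        factor = 2 ** len(self.encoder_block_layers)
        if h % factor or w % factor:
            raise ValueError(f"input spatial dims {h}x{w} must be divisible by {factor}")

    @property
    def n_stages(self) -> int:
        return len(self.encoder_block_layers)


# -- channel arithmetic, usable standalone ----------------------------------

def dense_block_channels(m: int, n_layers: int, growth_rate: int,
                         mode: str = "concat_with_input") -> int:
    """Output width of a dense block with ``m`` input channels."""
    if m <= 0 or growth_rate <= 0 or n_layers < 0:
        raise ValueError("channel counts and growth rate must be positive")
    if mode == "concat_with_input":
        return m + n_layers * growth_rate
    if mode == "new_features_only":
        if n_layers == 0:
            raise ValueError("a 0-layer dense block has no new features to emit")
        return n_layers * growth_rate
    raise ValueError(f"unknown dense-block mode {mode!r}")


def transition_down_shape(channels: int, size: tuple) -> tuple:
    """(channels, size) after a transition down: channels kept, dims halved."""
    h, w = size
    if h % 2 or w % 2:
        raise ValueError(f"transition down needs even spatial dims, got {size}")
    return channels, (h // 2, w // 2)


def transition_up_channels(n_layers: int, growth_rate: int) -> int:
    """Width of a transition up: only the preceding block's new features."""
    return n_layers * growth_rate


# -- graph builder ----------------------------------------------------------

def build_sed2(config: Sed2Config | None = None) -> LayerGraph:
    """Build the Stage-2 dense U-Net graph and self-check its ledger."""
    cfg = config or Sed2Config()
    k = cfg.growth_rate
    n_stages = cfg.n_stages

    g = LayerGraph()
    g.add("input", "input")
    g.add("init_conv", "conv", ["input"], out_channels=cfg.initial_conv_channels)

    # expected encoder ledger, recomputed independently of the graph engine
    expected = {}
    m = cfg.initial_conv_channels
    prev = "init_conv"
    for i, n in enumerate(cfg.encoder_block_layers, start=1):
        g.add(f"db_{i}", "dense_block", [prev],
              n_layers=n, growth_rate=k, mode="concat_with_input")
        m = dense_block_channels(m, n, k)
        expected[f"db_{i}"] = m
        g.add(f"td_{i}", "transition_down", [f"db_{i}"])
        expected[f"td_{i}"] = m
        prev = f"td_{i}"

    bott = f"db_{n_stages + 1}"
    g.add(bott, "dense_block", [prev],
          n_layers=cfg.bottleneck_layers, growth_rate=k, mode="concat_with_input")
    expected[bott] = dense_block_channels(m, cfg.bottleneck_layers, k)

    prev_block = bott
    prev_block_layers = cfg.bottleneck_layers
    for j, n in enumerate(cfg.decoder_block_layers, start=1):
        g.add(f"tu_{j}", "transition_up", [prev_block])
        expected[f"tu_{j}"] = transition_up_channels(prev_block_layers, k)
        skip = f"db_{n_stages - j + 1}"
        g.add(f"concat_{j}", "concat", [f"tu_{j}", skip])
        expected[f"concat_{j}"] = expected[f"tu_{j}"] + expected[skip]
        dec = f"db_{n_stages + 1 + j}"
        g.add(dec, "dense_block", [f"concat_{j}"],
              n_layers=n, growth_rate=k, mode="new_features_only")
        expected[dec] = dense_block_channels(expected[f"concat_{j}"], n, k,
                                             "new_features_only")
        prev_block, prev_block_layers = dec, n
    g.add("output", "conv1x1_out", [prev_block], out_channels=1)

    shapes = propagate_shapes(g, cfg.input_size)
    for name, want in expected.items():
        got = shapes.channels(name)
        if got != want:
            raise Sed2BuildError(
                f"channel ledger mismatch at node {name!r}: engine reports {got}, "
                f"configuration implies {want}"
            )
    return g


def build_sed2_model(config: Sed2Config | None = None, seed: int = 0) -> GraphModel:
    """Instantiate the Stage-2 network with He-initialized weights."""
    cfg = config or Sed2Config()
    return GraphModel(build_sed2(cfg), cfg.input_size, seed=seed, dropout=cfg.dropout)
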