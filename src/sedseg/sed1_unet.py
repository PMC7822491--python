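"""Stage-1 liver-localization U-Net.

A classic five-level U-Net: each encoder level applies two 3x3
convolutions (ReLU) and doubles the channel count before 2x2 max pooling;
the decoder mirrors it with 2x2 transposed convolutions and skip
concatenations from the same-resolution encoder level, ending in a 1x1
convolution with a sigmoid that emits a per-pixel liver probability.

At the default configuration (256x256 input, 32 base channels) the
channel ledger is

    encoder   32 / 64 / 128 / 256 / 512
    up+copy   256+256 / 128+128 / 64+64 / 32+32
    decoder   128 / 64 / 32 / 16  ->  1

``build_sed1`` returns the topology as a declarative
:class:`~sedseg.netgraph.LayerGraph`; ``build_sed1_model`` compiles it
into a runnable network.
"""

from __future__ import annotations

from dataclasses import dataclass

from .netgraph import LayerGraph, propagate_shapes
from .nn import GraphModel

__all__ = ["Sed1Config", "Sed1BuildError", "build_sed1", "build_sed1_model"]


class Sed1BuildError(ValueError):
    """The built graph failed its structural self-check."""


@dataclass
class Sed1Config:
    """Configuration of the liver-localization U-Net.

    ``decoder_channels`` defaults to ``(4b, 2b, b, b//2)`` for base
    channels ``b``, which reproduces the published 128/64/32/16 ledger at
    ``base_channels=32``.
    """

    input_size: tuple = (256, 256, 1)
    base_channels: int = 32
    depth: int = 5
    decoder_channels: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.decoder_channels is None:
            b = self.base_channels
            self.decoder_channels = tuple(
                max(b * 2 ** (self.depth - 3 - i), b // 2) if i < self.depth - 2 else b // 2
                for i in range(self.depth - 1)
            )
        if len(self.decoder_channels) != self.depth - 1:
            raise ValueError("decoder_channels must have depth-1 entries")
        h, w, _ = self.input_size
        factor = 2 ** (self.depth - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by {factor}"
            )


def build_sed1(config: Sed1Config | None = None) -> LayerGraph:
    """Build the Stage-1 U-Net graph and verify its skip-connection widths."""
    cfg = config or Sed1Config()
    d = cfg.depth
    enc_ch = [cfg.base_channels * 2 ** i for i in range(d)]

    g = LayerGraph()
    g.add("input", "input")
    prev = "input"
    for i in range(d):
        g.add(f"conv_block_{i + 1}", "conv_block", [prev], out_channels=enc_ch[i])
        prev = f"conv_block_{i + 1}"
        if i < d - 1:
            g.add(f"pool_{i + 1}", "pool", [prev])
            prev = f"pool_{i + 1}"

    expected_concat = []
    for j in range(d - 1):
        # up_1 halves the bottleneck width; later ups keep the decoder width
        up_out = enc_ch[d - 2 - j] if j == 0 else cfg.decoder_channels[j - 1]
        g.add(f"up_{j + 1}", "up", [prev], out_channels=up_out)
        skip = f"conv_block_{d - 1 - j}"
        g.add(f"concat_{j + 1}", "concat", [f"up_{j + 1}", skip])
        expected_concat.append(up_out + enc_ch[d - 2 - j])
        g.add(
            f"conv_block_{d + 1 + j}", "conv_block", [f"concat_{j + 1}"],
            out_channels=cfg.decoder_channels[j],
        )
        prev = f"conv_block_{d + 1 + j}"
    g.add("output", "conv1x1_out", [prev], out_channels=1)

    # structural self-check: every skip must land with the expected width
    shapes = propagate_shapes(g, cfg.input_size)
    actual = [shapes.channels(f"concat_{j + 1}") for j in range(d - 1)]
    if actual != expected_concat:
        raise Sed1BuildError(
            f"skip-connection widths {actual} do not match expected {expected_concat}"
        )
    return g


def build_sed1_model(config: Sed1Config | None = None, seed: int = 0) -> GraphModel:
    """Instantiate the Stage-1 network with He-initialized weights."""
    cfg = config or Sed1Config()
    return GraphModel(build_sed1(cfg), cfg.input_size, seed=seed)
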