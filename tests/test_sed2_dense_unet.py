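"""Stage-2 dense U-Net: channel ledger, DB/TD/TU rules, runnable model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedseg.netgraph import propagate_shapes
from sedseg.sed2_dense_unet import (Sed2BuildError, Sed2Config, build_sed2,
                                    build_sed2_model, dense_block_channels,
                                    transition_down_shape,
                                    transition_up_channels)

# published per-layer ledger at 256x256x1; the bottleneck entry is the
# arithmetically forced 896 (the printed table's 880 is inconsistent with
# its own channel accounting)
SED2_LEDGER = {
    "init_conv": ((256, 256), 48),
    "db_1": ((256, 256), 112),
    "td_1": ((128, 128), 112),
    "db_2": ((128, 128), 192),
    "td_2": ((64, 64), 192),
    "db_3": ((64, 64), 304),
    "td_3": ((32, 32), 304),
    "db_4": ((32, 32), 464),
    "td_4": ((16, 16), 464),
    "db_5": ((16, 16), 656),
    "td_5": ((8, 8), 656),
    "db_6": ((8, 8), 896),
    "tu_1": ((16, 16), 240),
    "concat_1": ((16, 16), 896),
    "db_7": ((16, 16), 192),
    "tu_2": ((32, 32), 192),
    "concat_2": ((32, 32), 656),
    "db_8": ((32, 32), 160),
    "tu_3": ((64, 64), 160),
    "concat_3": ((64, 64), 464),
    "db_9": ((64, 64), 112),
    "tu_4": ((128, 128), 112),
    "concat_4": ((128, 128), 304),
    "db_10": ((128, 128), 80),
    "tu_5": ((256, 256), 80),
    "concat_5": ((256, 256), 192),
    "db_11": ((256, 256), 64),
    "output": ((256, 256), 1),
}


class TestChannelArithmetic:
    @pytest.mark.parametrize(
        "m,n,k,mode,expected",
        [
            (48, 4, 16, "concat_with_input", 112),   # first encoder block
            (112, 5, 16, "concat_with_input", 192),
            (12, 12, 16, "new_features_only", 192),  # first decoder block
            (10, 0, 16, "concat_with_input", 10),    # 0 layers: identity
        ],
    )
    def test_dense_block_channels(self, m, n, k, mode, expected):
        assert dense_block_channels(m, n, k, mode) == expected

    def test_zero_layer_decoder_block_rejected(self):
        with pytest.raises(ValueError):
            dense_block_channels(48, 0, 16, "new_features_only")

    def test_transition_down_preserves_channels_halves_dims(self):
        assert transition_down_shape(112, (256, 256)) == (112, (128, 128))
        assert transition_down_shape(656, (16, 16)) == (656, (8, 8))

    def test_transition_down_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            transition_down_shape(16, (15, 16))

    def test_transition_up_width_is_new_features(self):
        assert transition_up_channels(15, 16) == 240  # bottleneck
        assert transition_up_channels(5, 16) == 80    # last decoder stage

    @settings(max_examples=30, deadline=None)
    @given(m=st.integers(4, 64), n=st.integers(1, 8), k=st.integers(1, 8))
    def test_encoder_recurrence(self, m, n, k):
        assert dense_block_channels(m, n, k) == m + n * k


class TestSed2Graph:
    def test_full_ledger(self):
        shapes = propagate_shapes(build_sed2(), (256, 256, 1))
        for name, (size, ch) in SED2_LEDGER.items():
            assert shapes.size(name) == size, name
            assert shapes.channels(name) == ch, name

    def test_encoder_block_outputs(self):
        shapes = propagate_shapes(build_sed2(), (256, 256, 1))
        enc = [shapes.channels(f"db_{i}") for i in range(1, 6)]
        assert enc == [112, 192, 304, 464, 656]

    def test_decoder_new_feature_outputs(self):
        shapes = propagate_shapes(build_sed2(), (256, 256, 1))
        dec = [shapes.channels(f"db_{i}") for i in range(7, 12)]
        assert dec == [192, 160, 112, 80, 64]

    def test_bottleneck_concat_width(self):
        shapes = propagate_shapes(build_sed2(), (256, 256, 1))
        assert shapes.channels("concat_1") == 240 + 656 == 896

    def test_skips_pair_encoder_and_decoder(self):
        g = build_sed2()
        assert g["concat_1"].inputs == ["tu_1", "db_5"]
        assert g["concat_5"].inputs == ["tu_5", "db_1"]

    def test_every_encoder_block_reaches_output(self):
        import networkx as nx

        g = build_sed2()
        dg = nx.DiGraph()
        for node in g:
            for up in node.inputs:
                dg.add_edge(up, node.name)
        for i in range(1, 6):
            assert nx.has_path(dg, f"db_{i}", "output")

    def test_ledger_mismatch_raises_naming_node(self, monkeypatch):
        import sedseg.sed2_dense_unet as mod

        orig = mod.dense_block_channels

        def corrupted(m, n, k, mode="concat_with_input"):
            out = orig(m, n, k, mode)
            return out - 16 if (n == 15 and mode == "concat_with_input") else out

        monkeypatch.setattr(mod, "dense_block_channels", corrupted)
        with pytest.raises(Sed2BuildError, match="db_6"):
            mod.build_sed2()

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            Sed2Config(input_size=(100, 100, 1))


class TestSed2Model:
    def test_forward_contract(self, tiny_sed2, rng):
        x = rng.random((1, 64, 64, 1), dtype=np.float32)
        out = tiny_sed2.forward(x, train=False)
        assert out.shape == (1, 64, 64, 1)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_scaled_model_matches_symbolic_count(self):
        from sedseg.netgraph import count_parameters

        cfg = Sed2Config(input_size=(64, 64, 1), growth_rate=2,
                         initial_conv_channels=6)
        model = build_sed2_model(cfg, seed=0)
        assert model.n_parameters() == count_parameters(build_sed2(cfg), cfg.input_size)
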