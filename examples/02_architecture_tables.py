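"""Print both cascade architectures as symbolic shape tables.

The per-layer output sizes are derived from the declarative graphs alone
(no weights involved), reproducing the published channel ledgers:
stage 1 encoder 32/64/128/256/512, stage 2 encoder dense blocks
112/192/304/464/656 with a 896-channel bottleneck concatenation.
"""

from sedseg import count_parameters, propagate_shapes
from sedseg.sed1_unet import build_sed1
from sedseg.sed2_dense_unet import build_sed2

for title, graph in (("SED-1 (liver U-Net)", build_sed1()),
                     ("SED-2 (tumor dense U-Net)", build_sed2())):
    shapes = propagate_shapes(graph, (256, 256, 1))
    print(f"\n{title}")
    print(f"{'node':<14} {'output size':<12} channels")
    for entry in shapes:
        print(f"{entry.name:<14} {entry.size[0]}x{entry.size[1]:<9} {entry.channels}")
    print(f"trainable parameters: {count_parameters(graph, (256, 256, 1)):,}")
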