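"""Build the four architectures and compare their parameter budgets.

The squeeze variants get within ~12x of U-Net's size from the fire blocks,
and the attention gates add under 0.1M parameters on top.  All networks map
an HxWx3 image to HxWx2 per-pixel class probabilities.
"""

import numpy as np

from dermseg.architectures import NetworkSpec, build_network, count_parameters
from dermseg.nn import Tensor, no_grad

counts = {}
for arch in ("unet", "attention_unet", "squeeze_unet", "attention_squeeze_unet"):
    model = build_network(NetworkSpec(architecture=arch, height=384, width=512, seed=0))
    counts[arch] = count_parameters(model)
    print(f"{arch:24s} {counts[arch]:>12,d} parameters "
          f"({counts[arch] / 1e6:.2f}M)")

delta = counts["attention_squeeze_unet"] - counts["squeeze_unet"]
print(f"\nattention gates cost {delta:,d} extra parameters "
      f"(~{round(delta / 100_000) * 100_000 // 1000}k)")

model = build_network(NetworkSpec(architecture="attention_squeeze_unet",
                                  height=96, width=128, seed=0))
x = np.random.default_rng(0).random((1, 3, 96, 128), dtype=np.float32)
with no_grad():
    probs = model(Tensor(x)).data
print(f"\nforward pass: input {x.shape} -> output {probs.shape}, "
      f"per-pixel probability sums within {np.abs(probs.sum(1) - 1).max():.1e} of 1")
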