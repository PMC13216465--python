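"""ResNet18 trunk (stem + stages 1-3) used as the frozen feature encoder.

Only the layers needed for the three feature scales are instantiated:
for a 256x256 input the trunk emits 64-channel 64x64, 128-channel 32x32
and 256-channel 16x16 activations. Weights are seeded He-initialized;
the module is frozen after construction and always run in eval mode, so
batch-norm uses its fixed running statistics.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .core import Module, Tensor, no_grad
from .layers import BatchNorm2d, Conv2d, ReLU, Sequential


class BasicBlock(Module):
    def __init__(self, cin, cout, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng), BatchNorm2d(cout)
            )
        else:
            self.down = None

    def forward(self, x):
        identity = x if self.down is None else self.down(x)
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return F.relu(F.add(out, identity))


class ResNet18Trunk(Module):
    def __init__(self, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(3, 64, 7, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.layer1 = Sequential(BasicBlock(64, 64, rng=rng), BasicBlock(64, 64, rng=rng))
        self.layer2 = Sequential(
            BasicBlock(64, 128, stride=2, rng=rng), BasicBlock(128, 128, rng=rng)
        )
        self.layer3 = Sequential(
            BasicBlock(128, 256, stride=2, rng=rng), BasicBlock(256, 256, rng=rng)
        )
        self.eval()
        self.freeze()

    def train(self, mode=True):  # frozen: always eval, running stats fixed
        return super().train(False)

    def forward(self, x):
        """Return the three-scale feature pyramid for a (B,3,H,W) input."""
        with no_grad():
            if not isinstance(x, Tensor):
                x = Tensor(x)
            x = F.relu(self.bn1(self.conv1(x)))
            x = F.max_pool2d(x, 3, 2, 1)
            f1 = self.layer1(x)
            f2 = self.layer2(f1)
            f3 = self.layer3(f2)
        return f1.data, f2.data, f3.data
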