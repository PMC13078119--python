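"""Baseline convolutional fusion blocks (CSP-style) used by the skeleton."""

from __future__ import annotations

from . import nn
from .nn.tensor import concat


class Bottleneck(nn.Module):
    def __init__(self, cin, cout, shortcut=True, e=0.5, k=(3, 3)):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = nn.ConvBN(cin, c_, k[0])
        self.cv2 = nn.ConvBN(c_, cout, k[1])
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP block with three 1x1 projections around a bottleneck chain."""

    def __init__(self, cin, cout, n=2, e=0.5):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = nn.ConvBN(cin, c_, 1)
        self.cv2 = nn.ConvBN(cin, c_, 1)
        self.cv3 = nn.ConvBN(2 * c_, cout, 1)
        self.m = nn.Sequential(*[Bottleneck(c_, c_, e=1.0) for _ in range(n)])

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Split-transform-merge block: split, chain n units, concat everything."""

    def __init__(self, cin, cout, n=1, e=0.5, c3k=False, shortcut=True):
        super().__init__()
        self.c_ = int(cout * e)
        self.cv1 = nn.ConvBN(cin, 2 * self.c_, 1)
        self.cv2 = nn.ConvBN((2 + n) * self.c_, cout, 1)
        units = [C3k(self.c_, self.c_, 2) if c3k
                 else Bottleneck(self.c_, self.c_, shortcut)
                 for _ in range(n)]
        self.m = nn.ModuleList(units)

    def forward(self, x):
        y = self.cv1(x)
        c = self.c_
        ys = [y[:, :c], y[:, c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))
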