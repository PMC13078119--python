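"""Layer/module abstractions over the autodiff core.

`Module` keeps registries of parameters, buffers and submodules, supports
train/eval switching and flat state-dict (de)serialisation with numpy arrays.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Tensor

_rng = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the weight-initialisation stream (checkpoint reproducibility)."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._mods.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._mods.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        """Total learnable element count (buffers excluded)."""
        return sum(p.size for p in self.parameters())

    # -- mode -------------------------------------------------------------
    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._mods.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ------------------------------------------------------------
    def state_dict(self):
        sd = {n: p.data.copy() for n, p in self.named_parameters()}
        sd.update({n: b.copy() for n, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict):
        own_p = dict(self.named_parameters())
        own_b = {}

        def collect(mod, prefix=""):
            for n in mod._buffers:
                own_b[prefix + n] = (mod, n)
            for n, m in mod._mods.items():
                collect(m, prefix + n + ".")

        collect(self)
        missing = (set(own_p) | set(own_b)) - set(sd)
        if missing:
            raise KeyError(f"state_dict missing entries: {sorted(missing)[:5]} ...")
        for n, p in own_p.items():
            if p.data.shape != sd[n].shape:
                raise ValueError(f"shape mismatch for {n}: "
                                 f"{p.data.shape} vs {sd[n].shape}")
            p.data = np.asarray(sd[n], dtype=np.float32).copy()
        for n, (mod, attr) in own_b.items():
            buf = np.asarray(sd[n], dtype=mod._buffers[attr].dtype).copy()
            mod._buffers[attr] = buf
            object.__setattr__(mod, attr, buf)

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Bare convolution (kaiming-uniform init, optional bias)."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, groups=1,
                 bias=True):
        super().__init__()
        kh, kw = (k, k) if np.isscalar(k) else k
        fan_in = cin // groups * kh * kw
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(
            _rng.uniform(-bound, bound, (cout, cin // groups, kh, kw)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias, self.stride,
                          self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        return ops.batch_norm(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class GroupNorm(Module):
    def __init__(self, groups, c, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.groups, self.eps = groups, eps

    def forward(self, x):
        return ops.group_norm(x, self.weight, self.bias, self.groups, self.eps)


_ACTS = {
    "silu": lambda t: t.silu(),
    "relu": lambda t: t.relu(),
    "relu6": lambda t: t.relu6(),
    "sigmoid": lambda t: t.sigmoid(),
    "none": lambda t: t,
}


class ConvBN(Module):
    """Conv + BatchNorm + activation — the standard detector conv block."""

    def __init__(self, cin, cout, k=1, stride=1, groups=1, act="silu",
                 padding=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        if act not in _ACTS:
            raise ValueError(f"unknown activation {act!r}")
        self.act_name = act

    def forward(self, x):
        return _ACTS[self.act_name](self.bn(self.conv(x)))
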