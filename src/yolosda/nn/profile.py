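"""Multiply-accumulate (MAC) accounting for complexity reports.

Convolutions, linear maps and attention matmuls report their MAC counts here
while a :func:`count_macs` context is active. The reporting convention used
throughout the package is 1 MAC = 2 FLOPs; normalisation and activation
arithmetic is excluded, matching how detection frameworks usually print
GFLOPs.
"""

from __future__ import annotations

import contextlib

_active: list | None = None
_count_matmul = False


@contextlib.contextmanager
def count_macs(include_matmul: bool = False):
    """Collect MACs of every profiled op run inside the block.

    Yields a single-element list; ``result[0]`` holds the running MAC total.
    By default only convolution/linear layers are counted — the convention
    under which detector GFLOPs are conventionally printed; pass
    ``include_matmul=True`` to also count attention matmuls.
    """
    global _active, _count_matmul
    prev, prevm = _active, _count_matmul
    _active, _count_matmul = [0], include_matmul
    try:
        yield _active
    finally:
        _active, _count_matmul = prev, prevm


def add(n: int):
    if _active is not None:
        _active[0] += int(n)


def add_matmul(n: int):
    if _active is not None and _count_matmul:
        _active[0] += int(n)


def active() -> bool:
    return _active is not None
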