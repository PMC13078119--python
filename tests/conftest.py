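import numpy as np
import pytest

from yolosda import datakit, network


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_spec():
    """Quarter-width detector at 96 px — fast enough for forward/training."""
    return network.yolo_sda_spec(input_size=96, width_mult=0.25)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Twelve 96-px synthetic scenes, split 7:2:1."""
    root = tmp_path_factory.mktemp("scenes")
    manifest = datakit.write_dataset(str(root), 12, seed=3, size=96,
                                     n_objects=(1, 3))
    return manifest


def loop_conv2d(x, w, b=None, stride=1, padding=0):
    """Brute-force per-output-pixel convolution oracle (numpy loops only)."""
    C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    y = np.zeros((Cout, Ho, Wo))
    for o in range(Cout):
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(Cin):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += w[o, c, di, dj] * \
                                xp[c, i * stride + di, j * stride + dj]
                y[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return y


@pytest.fixture()
def conv_oracle():
    return loop_conv2d
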