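"""Fully-convolutional segmentation architectures.

Three backbones share one contract: an H×W×3 image in, an H×W×2 logit map
out (softmaxed downstream), for any H, W divisible by the backbone stride.

* ``tiny`` — a 4-layer encoder-decoder under 100k parameters, sized for
  CPU training on small synthetic scenes.
* ``vgg16-fcn`` — the 13-conv VGG-16 trunk with a 1×1 score head and a
  single bilinear ×32 decoder.
* ``resnet50-fcn`` — the ResNet-50 trunk (bottleneck blocks, batch norm)
  with the same FCN head.

The deeper trunks accept an optional ``pretrained`` weights path; nothing
in the package ever requires downloaded weights.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    BatchNorm2d,
    Bottleneck,
    Conv2d,
    MaxPool2d,
    ReLU,
    Sequential,
    UpsampleBilinear,
)

__all__ = ["SegmentationModel", "build_model", "BACKBONES"]

BACKBONES = ("tiny", "vgg16-fcn", "resnet50-fcn")


class SegmentationModel:
    """A backbone plus its stride contract and build seed."""

    def __init__(self, net: Sequential, backbone: str, stride: int, seed: int):
        self.net = net
        self.backbone = backbone
        self.stride = stride
        self.seed = seed

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Map an (N, 3, H, W) float batch to (N, 2, H, W) logits."""
        h, w = x.shape[2], x.shape[3]
        if h % self.stride or w % self.stride:
            raise ValueError(
                f"{self.backbone} requires H and W divisible by {self.stride}; "
                f"got {h}×{w}"
            )
        return self.net.forward(x.astype(np.float32), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad.astype(np.float32))

    def parameters(self) -> list[dict]:
        return self.net.parameters()

    def n_parameters(self) -> int:
        return int(sum(p["value"].size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p["value"] for i, p in enumerate(self.parameters())}
        # batch-norm running statistics live outside parameters()
        for i, layer in enumerate(_walk(self.net)):
            if isinstance(layer, BatchNorm2d):
                state[f"bn_{i}_mean"] = layer.running_mean
                state[f"bn_{i}_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p["value"][...] = state[f"param_{i}"]
        for i, layer in enumerate(_walk(self.net)):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"bn_{i}_mean"]
                layer.running_var[...] = state[f"bn_{i}_var"]


def _walk(layer):
    yield layer
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            yield from _walk(sub)
    for attr in ("main", "project", "relu"):
        sub = getattr(layer, attr, None)
        if sub is not None and hasattr(sub, "forward"):
            yield from _walk(sub)


def _tiny(rng) -> tuple[Sequential, int]:
    net = Sequential(
        Conv2d(3, 16, 3, rng=rng),
        ReLU(),
        Conv2d(16, 32, 3, stride=2, rng=rng),
        ReLU(),
        Conv2d(32, 32, 3, rng=rng),
        ReLU(),
        UpsampleBilinear(2),
        Conv2d(32, 2, 1, pad=0, rng=rng),
    )
    return net, 2


def _vgg16_fcn(rng) -> tuple[Sequential, int]:
    cfg = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P", 512, 512, 512, "P", 512, 512, 512, "P"]
    layers, cin = [], 3
    for item in cfg:
        if item == "P":
            layers.append(MaxPool2d(2))
        else:
            layers += [Conv2d(cin, item, 3, rng=rng), ReLU()]
            cin = item
    layers += [Conv2d(cin, 2, 1, pad=0, rng=rng), UpsampleBilinear(32)]
    return Sequential(*layers), 32


def _resnet50_fcn(rng) -> tuple[Sequential, int]:
    layers = [
        Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, stride=2, pad=1),
    ]
    cin = 64
    for mid, n_blocks, stride in [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]:
        for b in range(n_blocks):
            layers.append(Bottleneck(cin, mid, stride if b == 0 else 1, rng))
            cin = mid * 4
    layers += [Conv2d(cin, 2, 1, pad=0, rng=rng), UpsampleBilinear(32)]
    return Sequential(*layers), 32


def build_model(
    backbone: str = "tiny", seed: int = 0, pretrained: str | None = None
) -> SegmentationModel:
    """Construct a segmentation model with seeded He initialization."""
    rng = np.random.default_rng(seed)
    builders = {"tiny": _tiny, "vgg16-fcn": _vgg16_fcn, "resnet50-fcn": _resnet50_fcn}
    if backbone not in builders:
        raise ValueError(f"unknown backbone {backbone!r}; expected one of {BACKBONES}")
    net, stride = builders[backbone](rng)
    model = SegmentationModel(net, backbone, stride, seed)
    if pretrained is not None:
        with np.load(pretrained) as data:
            model.load_state_arrays(dict(data))
    return model
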