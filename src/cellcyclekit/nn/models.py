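"""CellCycleNet-style encoder classifiers/regressors, in numpy.

The 3D network is the first four encoder blocks of a U-Net-style 3D CNN
retooled for binary staging: each block is two units of
[group norm -> 3x3x3 conv (no bias) -> ReLU] with widths
1->16->32, 32->32->64, 64->64->128, 128->128->256 and 2x2x2 max pooling
between blocks, followed by a head of [adaptive max pool to (1,1,1) ->
flatten -> dropout p=0.5 -> linear 256->1]. This instantiation carries
exactly 1,757,267 trainable parameters.

The 2D variant uses four single-unit blocks of
[group norm -> 3x3 conv (with bias) -> ReLU], widths 1->32->64->128->256,
2x2 pooling between blocks and the identical head: 388,547 parameters.

The same architecture serves classification (loss on logits, sigmoid for
probabilities) and regression (raw scalar output, target in degrees); the
two modes share every parameter shape.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import (Adam, ConvND, Dropout, GlobalMaxPool, GroupNorm, Linear,
                     MaxPool, ReLU, Sequential)

BLOCKS_3D = [(1, 16, 32), (32, 32, 64), (64, 64, 128), (128, 128, 256)]
CHANNELS_2D = [(1, 32), (32, 64), (64, 128), (128, 256)]
HEAD_FEATURES = 256

MODES = ("classification", "regression")


class Network(Sequential):
    """A built model plus its identity (architecture name, head mode, seed)."""

    def __init__(self, blocks, arch: str, mode: str, init_seed: int) -> None:
        super().__init__(blocks)
        self.arch = arch
        self.mode = mode
        self.init_seed = init_seed
        self.min_input = 16  # three 2x poolings must leave >= 2 per dim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        expected_ndim = 5 if self.arch == "3d" else 4
        if x.ndim != expected_ndim:
            raise ValueError(
                f"{self.arch} network expects {expected_ndim}D input (N, C, ...), got shape {x.shape}")
        if x.shape[1] != 1:
            raise ValueError(f"expected 1 input channel, got {x.shape[1]}")
        if min(x.shape[2:]) < self.min_input:
            raise ValueError(
                f"spatial dims must be >= {self.min_input}, got {x.shape[2:]}")
        return super().forward(x.astype(np.float32, copy=False), train=train)

    # -- dropout reseeding so repeated trainings are exactly reproducible --
    def reseed_dropout(self, seed: int) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.reseed(seed)

    # -- pretrained-encoder hook ------------------------------------------
    def load_encoder_weights(self, state: dict[str, np.ndarray]) -> int:
        """Load externally supplied encoder weights by parameter name.

        Names follow this package's convention (``block{i}.{j}.{Layer}.{param}``);
        head parameters absent from ``state`` are left at their initialisation.
        Returns the number of tensors loaded.
        """
        loaded = 0
        for name, layer, pname, p in self.named_parameters():
            if name in state:
                if state[name].shape != p.shape:
                    raise ValueError(f"shape mismatch for {name}")
                layer.params[pname] = state[name].astype(np.float32).copy()
                loaded += 1
        return loaded


def _unit(cin: int, cout: int, ndim: int, bias: bool, rng: np.random.Generator) -> list:
    return [GroupNorm(cin), ConvND(cin, cout, ndim=ndim, bias=bias, rng=rng), ReLU()]


def build_3d(mode: str = "classification", init_seed: int = 0) -> Network:
    """Build the 3D network (double-unit bias-free blocks; 1,757,267 params)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = np.random.default_rng(init_seed)
    blocks = []
    for i, (cin, mid, cout) in enumerate(BLOCKS_3D):
        layers = _unit(cin, mid, 3, False, rng) + _unit(mid, cout, 3, False, rng)
        if i < len(BLOCKS_3D) - 1:
            layers.append(MaxPool(ndim=3))
        blocks.append((f"block{i + 1}", layers))
    blocks.append(("head", [GlobalMaxPool(), Dropout(0.5, seed=init_seed),
                            Linear(HEAD_FEATURES, 1, rng)]))
    return Network(blocks, arch="3d", mode=mode, init_seed=init_seed)


def build_2d(mode: str = "classification", init_seed: int = 0) -> Network:
    """Build the 2D variant (single-unit biased blocks; 388,547 params)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = np.random.default_rng(init_seed)
    blocks = []
    for i, (cin, cout) in enumerate(CHANNELS_2D):
        layers = _unit(cin, cout, 2, True, rng)
        if i < len(CHANNELS_2D) - 1:
            layers.append(MaxPool(ndim=2))
        blocks.append((f"block{i + 1}", layers))
    blocks.append(("head", [GlobalMaxPool(), Dropout(0.5, seed=init_seed),
                            Linear(HEAD_FEATURES, 1, rng)]))
    return Network(blocks, arch="2d", mode=mode, init_seed=init_seed)


def build(arch: str, mode: str = "classification", init_seed: int = 0) -> Network:
    if arch == "3d":
        return build_3d(mode, init_seed)
    if arch == "2d":
        return build_2d(mode, init_seed)
    raise ValueError("arch must be '3d' or '2d'")


def count_parameters(model: Sequential) -> int:
    """Total size of all trainable tensors."""
    return model.n_parameters()


def parameter_breakdown(model: Sequential) -> dict[str, int]:
    """Per-block trainable parameter subtotals (block1..block4, head)."""
    return model.block_parameter_counts()


# -- checkpoint I/O -------------------------------------------------------

def save_checkpoint(path: str | Path, model: Network, meta: dict | None = None) -> None:
    """Write weights (npz) plus a JSON sidecar describing the run."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "arch": model.arch,
        "mode": model.mode,
        "init_seed": model.init_seed,
        "n_parameters": count_parameters(model),
    }
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Network, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build(meta["arch"], meta["mode"], meta.get("init_seed", 0))
    with np.load(path.with_suffix(".npz")) as z:
        model.load_state_dict(dict(z))
    return model, meta


__all__ = [
    "Network", "build", "build_3d", "build_2d", "count_parameters",
    "parameter_breakdown", "save_checkpoint", "load_checkpoint", "Adam",
]
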