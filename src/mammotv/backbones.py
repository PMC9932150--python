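"""Frozen CNN feature extraction: three backbone branches with fixed tap dims.

The classification pipeline taps three convolutional networks as frozen
feature extractors:

* ``inception_v3`` — Inception-style branch, 299x299 input, features taken at
  the global-average-pool layer: **2048** features per patch;
* ``resnet50`` — residual-bottleneck branch, 224x224 input, global-average-pool
  tap: **2048** features per patch;
* ``alexnet`` — AlexNet-style branch (five convolutions, three FC layers),
  227x227 input, features taken at the penultimate 4096-unit fully-connected
  layer ("fc7"): **4096** features per patch;

for a fused total of 8192 raw features.  The networks here are compact
numpy realisations of each architecture family: they preserve the family's
topology style (stem / bottleneck residual stages / parallel Inception
branches / conv+FC stack), the native input geometry and the tap layer type
and dimensionality, with frozen He-initialised random weights
(``weights="random_init"``).  Random frozen convolutional features act as a
nonlinear random projection of the patch, which is sufficient for every
dimensional, determinism and recovery contract in this package;
``weights="imagenet_pretrained"`` is reserved and raises, since no pretrained
weight set ships with the package.

Feature dimensionality depends only on the architecture — never on weights,
input content or batch size — and extraction is a pure function: repeated
runs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize

from . import _nn
from .errors import AlignmentError, ConfigurationError, ValidationError, WeightsUnavailableError
from .mias import Patch

__all__ = [
    "BackboneSpec",
    "FeatureMatrix",
    "BACKBONE_NAMES",
    "EXPECTED_DIMS",
    "default_specs",
    "preprocess_patch",
    "extract_features",
    "extract_all",
]

BACKBONE_NAMES = ("inception_v3", "resnet50", "alexnet")

EXPECTED_DIMS = {"inception_v3": 2048, "resnet50": 2048, "alexnet": 4096}
_INPUT_SIDES = {"inception_v3": 299, "resnet50": 224, "alexnet": 227}
_TAPS = {
    "inception_v3": "global_average_pool",
    "resnet50": "global_average_pool",
    "alexnet": "fc7",
}
_ARCH_ID = {"inception_v3": 1, "resnet50": 2, "alexnet": 3}


@dataclass(frozen=True)
class BackboneSpec:
    """Configuration of one frozen feature-extraction branch."""

    name: str
    input_side: int
    tap: str
    expected_dim: int
    weights: str = "random_init"
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BACKBONE_NAMES:
            raise ConfigurationError(f"unknown backbone {self.name!r}; known: {BACKBONE_NAMES}")
        if self.expected_dim != EXPECTED_DIMS[self.name]:
            raise ConfigurationError(
                f"{self.name}: expected_dim must be {EXPECTED_DIMS[self.name]}, got {self.expected_dim}"
            )
        if self.tap != _TAPS[self.name]:
            raise ConfigurationError(
                f"{self.name}: unknown tap layer {self.tap!r} (expected {_TAPS[self.name]!r})"
            )
        if self.weights not in ("imagenet_pretrained", "random_init"):
            raise ConfigurationError(f"unknown weight mode {self.weights!r}")

    @classmethod
    def for_name(cls, name: str, weights: str = "random_init", weight_seed: int = 0) -> "BackboneSpec":
        if name not in BACKBONE_NAMES:
            raise ConfigurationError(f"unknown backbone {name!r}; known: {BACKBONE_NAMES}")
        return cls(
            name=name,
            input_side=_INPUT_SIDES[name],
            tap=_TAPS[name],
            expected_dim=EXPECTED_DIMS[name],
            weights=weights,
            weight_seed=weight_seed,
        )


def default_specs(weights: str = "random_init", weight_seed: int = 0) -> tuple[BackboneSpec, ...]:
    """The three standard branches, in canonical order."""
    return tuple(BackboneSpec.for_name(n, weights, weight_seed) for n in BACKBONE_NAMES)


@dataclass
class FeatureMatrix:
    """N patches x M features with per-column provenance.

    ``column_provenance[j]`` is ``(backbone_name, original_column_index)`` so
    any selected column can be traced back to the branch and position it came
    from, through arbitrarily many selection/fusion steps.
    """

    values: np.ndarray  # (N, M) float32
    row_ids: list[str]
    column_provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be a 2-D array")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValidationError("row_ids length must equal the number of rows")
        if len(self.column_provenance) != self.values.shape[1]:
            raise ValidationError("column_provenance length must equal the number of columns")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            row_ids=list(self.row_ids),
            column_provenance=[self.column_provenance[j] for j in idx],
        )

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[idx, :],
            row_ids=[self.row_ids[i] for i in idx],
            column_provenance=list(self.column_provenance),
        )

    @staticmethod
    def hstack(blocks: Iterable["FeatureMatrix"]) -> "FeatureMatrix":
        blocks = list(blocks)
        if not blocks:
            raise ValidationError("cannot stack zero feature blocks")
        ids = blocks[0].row_ids
        for b in blocks[1:]:
            if b.row_ids != ids:
                raise AlignmentError("row_ids differ between feature blocks")
        return FeatureMatrix(
            values=np.hstack([b.values for b in blocks]),
            row_ids=list(ids),
            column_provenance=[p for b in blocks for p in b.column_provenance],
        )

    def save(self, prefix) -> None:
        """Persist as <prefix>.npy plus a JSON sidecar with ids/provenance."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.values)
        sidecar = {
            "row_ids": self.row_ids,
            "column_provenance": [[b, int(j)] for b, j in self.column_provenance],
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix) -> "FeatureMatrix":
        prefix = Path(prefix)
        values = np.load(prefix.with_suffix(".npy"))
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            values=values,
            row_ids=list(sidecar["row_ids"]),
            column_provenance=[(b, int(j)) for b, j in sidecar["column_provenance"]],
        )


# ---------------------------------------------------------------------------
# architecture builders (frozen random weights, deterministic per spec)
# ---------------------------------------------------------------------------

def _build_alexnet(rng: np.random.Generator) -> _nn.Sequential:
    # five convolutions + three FC layers; the tap is fc7 (4096 units)
    relu = _nn.ReLU()
    return _nn.Sequential([
        _nn.conv_init(rng, 48, 3, 11, stride=4), relu,          # 227 -> 55
        _nn.MaxPool2d(3, 2),                                    # -> 27
        _nn.conv_init(rng, 128, 48, 5, pad=2), relu,
        _nn.MaxPool2d(3, 2),                                    # -> 13
        _nn.conv_init(rng, 192, 128, 3, pad=1), relu,
        _nn.conv_init(rng, 192, 192, 3, pad=1), relu,
        _nn.conv_init(rng, 128, 192, 3, pad=1), relu,
        _nn.MaxPool2d(3, 2),                                    # -> 6
        _nn.Flatten(),                                          # 128*6*6 = 4608
        _nn.linear_init(rng, 4096, 4608), relu,                 # fc6
        _nn.linear_init(rng, 4096, 4096), relu,                 # fc7 (tap)
    ])


def _bottleneck(rng, in_ch: int, mid_ch: int, out_ch: int, stride: int) -> _nn.Residual:
    relu = _nn.ReLU()
    main = [
        _nn.conv_init(rng, mid_ch, in_ch, 1), relu,
        _nn.conv_init(rng, mid_ch, mid_ch, 3, stride=stride, pad=1), relu,
        _nn.conv_init(rng, out_ch, mid_ch, 1),
    ]
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = [_nn.conv_init(rng, out_ch, in_ch, 1, stride=stride)]
    return _nn.Residual(main, shortcut)


def _build_resnet(rng: np.random.Generator) -> _nn.Sequential:
    relu = _nn.ReLU()
    return _nn.Sequential([
        _nn.conv_init(rng, 32, 3, 7, stride=2, pad=3), relu,    # 224 -> 112
        _nn.MaxPool2d(3, 2, pad=1),                             # -> 56
        _bottleneck(rng, 32, 32, 128, stride=1),                # 56
        _bottleneck(rng, 128, 64, 256, stride=2),               # -> 28
        _bottleneck(rng, 256, 128, 512, stride=2),              # -> 14
        _bottleneck(rng, 512, 256, 2048, stride=2),             # -> 7, 2048 ch
        _nn.GlobalAvgPool(),                                    # tap: 2048
    ])


def _build_inception(rng: np.random.Generator) -> _nn.Sequential:
    relu = _nn.ReLU()
    module_a = _nn.Parallel([
        [_nn.conv_init(rng, 64, 96, 1), relu],
        [_nn.conv_init(rng, 48, 96, 1), relu, _nn.conv_init(rng, 64, 48, 5, pad=2), relu],
        [_nn.conv_init(rng, 64, 96, 1), relu,
         _nn.conv_init(rng, 96, 64, 3, pad=1), relu,
         _nn.conv_init(rng, 96, 96, 3, pad=1), relu],
        [_nn.AvgPool2d(3, 1, pad=1), _nn.conv_init(rng, 32, 96, 1), relu],
    ])  # 64+64+96+32 = 256
    module_b = _nn.Parallel([
        [_nn.conv_init(rng, 128, 256, 1), relu],
        [_nn.conv_init(rng, 96, 256, 1), relu, _nn.conv_init(rng, 128, 96, 3, pad=1), relu],
        [_nn.conv_init(rng, 96, 256, 1), relu,
         _nn.conv_init(rng, 128, 96, 3, pad=1), relu,
         _nn.conv_init(rng, 128, 128, 3, pad=1), relu],
        [_nn.AvgPool2d(3, 1, pad=1), _nn.conv_init(rng, 128, 256, 1), relu],
    ])  # 4 * 128 = 512
    module_c = _nn.Parallel([
        [_nn.conv_init(rng, 640, 512, 1), relu],
        [_nn.conv_init(rng, 256, 512, 1), relu, _nn.conv_init(rng, 640, 256, 3, pad=1), relu],
        [_nn.conv_init(rng, 128, 512, 1), relu, _nn.conv_init(rng, 384, 128, 5, pad=2), relu],
        [_nn.AvgPool2d(3, 1, pad=1), _nn.conv_init(rng, 384, 512, 1), relu],
    ])  # 640+640+384+384 = 2048
    return _nn.Sequential([
        _nn.conv_init(rng, 32, 3, 3, stride=2), relu,           # 299 -> 149
        _nn.conv_init(rng, 64, 32, 3, stride=2, pad=1), relu,   # -> 75
        _nn.MaxPool2d(3, 2),                                    # -> 37
        _nn.conv_init(rng, 96, 64, 3, stride=2, pad=1), relu,   # -> 19
        module_a,                                               # 256 ch
        _nn.MaxPool2d(3, 2, pad=1),                             # -> 10
        module_b,                                               # 512 ch
        _nn.MaxPool2d(3, 2, pad=1),                             # -> 5
        module_c,                                               # 2048 ch
        _nn.GlobalAvgPool(),                                    # tap: 2048
    ])


_BUILDERS = {
    "inception_v3": _build_inception,
    "resnet50": _build_resnet,
    "alexnet": _build_alexnet,
}

_MODEL_CACHE: dict[tuple[str, str, int], _nn.Sequential] = {}


def _get_model(spec: BackboneSpec) -> _nn.Sequential:
    if spec.weights == "imagenet_pretrained":
        raise WeightsUnavailableError(
            f"{spec.name}: no pretrained weight set ships with this package; "
            "use weights='random_init'"
        )
    key = (spec.name, spec.weights, spec.weight_seed)
    if key not in _MODEL_CACHE:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.weight_seed, _ARCH_ID[spec.name]])
        )
        _MODEL_CACHE[key] = _BUILDERS[spec.name](rng)
    return _MODEL_CACHE[key]


def preprocess_patch(patch: Patch, spec: BackboneSpec) -> np.ndarray:
    """Grayscale patch -> (3, input_side, input_side) float32 network input.

    Intensities are scaled to [0, 1], the single channel is replicated three
    times, and the image is bilinearly resized to the branch's native input
    side.  In ``random_init`` mode no further normalisation is applied
    (identity normalisation): random weights carry no training convention.
    """
    if patch.side < 32:
        raise ValidationError(f"patch side {patch.side} too small (minimum 32)")
    x = patch.pixels.astype(np.float32) / 255.0
    if patch.side != spec.input_side:
        x = resize(
            x, (spec.input_side, spec.input_side),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        ).astype(np.float32)
    return np.repeat(x[None, :, :], 3, axis=0)


def extract_features(
    patches: Sequence[Patch], spec: BackboneSpec, batch_size: int = 32
) -> FeatureMatrix:
    """Run every patch through the frozen branch; rows keep the input order.

    ``batch_size`` only groups the Python loop; each image is evaluated
    independently, so results are element-wise identical for any batch size.
    """
    if not patches:
        raise ValidationError("extract_features requires a non-empty patch list")
    if batch_size < 1:
        raise ValidationError(f"batch_size must be >= 1, got {batch_size}")
    model = _get_model(spec)
    rows = np.empty((len(patches), spec.expected_dim), dtype=np.float32)
    for i, patch in enumerate(patches):
        out = model(preprocess_patch(patch, spec))
        if out.shape != (spec.expected_dim,):
            raise ConfigurationError(
                f"{spec.name}: tap {spec.tap!r} produced shape {out.shape}, "
                f"expected ({spec.expected_dim},)"
            )
        rows[i] = out
    row_ids = [f"{i:04d}:{p.source_ref}" for i, p in enumerate(patches)]
    provenance = [(spec.name, j) for j in range(spec.expected_dim)]
    return FeatureMatrix(values=rows, row_ids=row_ids, column_provenance=provenance)


def extract_all(
    patches: Sequence[Patch], specs: Sequence[BackboneSpec], batch_size: int = 32
) -> dict[str, FeatureMatrix]:
    """Extract all three branches; blocks are row-aligned by construction."""
    if not specs:
        raise ConfigurationError("extract_all requires backbone specs")
    names = [s.name for s in specs]
    if sorted(names) != sorted(BACKBONE_NAMES):
        raise ConfigurationError(
            f"specs must cover {BACKBONE_NAMES} exactly once, got {names}"
        )
    blocks = {s.name: extract_features(patches, s, batch_size) for s in specs}
    ids = blocks[names[0]].row_ids
    for name in names[1:]:
        if blocks[name].row_ids != ids:
            raise AlignmentError("row order differs between backbone blocks")
    return blocks
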