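"""Deterministic MIAS-like synthetic fixtures.

Every downstream stage (feature extraction, term-variance selection, SVM
evaluation) is testable without the real mammography database: this module
generates grayscale patches in the three MIAS background-tissue regimes
(D dense-glandular, F fatty, G fatty-glandular) and three diagnostic classes
(normal / benign / malignant), with the canonical class distribution —
per tissue D/F/G: 100/100/100 normal, 23/23/20 benign, 17/17/16 malignant,
416 patches in total — and a single ``separability`` dial that scales the
class-discriminative lesion signal from 0 (classes statistically identical)
upward.

The texture model is band-limited Gaussian noise with a per-tissue spectral
slope; lesions are additive bright blobs — smooth and round for benign,
spiculated (angularly modulated radius) for malignant.  These are test
signals, not simulations of mammographic appearance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .mias import CLASS_ORDER, NORMAL_CODE, TISSUES, Patch, parse_info_file, write_pgm

__all__ = [
    "TextureParams",
    "LesionParams",
    "SyntheticSpec",
    "FixtureManifest",
    "generate_patches",
    "write_mias_fixture",
    "DEFAULT_COUNTS",
]

#: Canonical per-(tissue, class) patch counts (total 416: 300/66/50).
DEFAULT_COUNTS: dict[tuple[str, str], int] = {
    ("D", "normal"): 100, ("D", "benign"): 23, ("D", "malignant"): 17,
    ("F", "normal"): 100, ("F", "benign"): 23, ("F", "malignant"): 17,
    ("G", "normal"): 100, ("G", "benign"): 20, ("G", "malignant"): 16,
}


@dataclass(frozen=True)
class TextureParams:
    """Background-texture model for one tissue type.

    ``slope`` is the power-spectral exponent of the band-limited noise
    (larger = smoother, more blob-like texture); ``base`` the mean gray
    level; ``sigma`` the texture contrast in gray levels.
    """

    base: float
    slope: float
    sigma: float


@dataclass(frozen=True)
class LesionParams:
    """Additive-blob lesion model for one abnormal class.

    ``amplitude`` (gray levels) is multiplied by the spec's ``separability``;
    ``radius_range`` is in pixels at a 256-pixel patch side and scales with
    the patch side; ``edge_sharpness`` is the exponent of the radial profile
    ``exp(-(d/r)^s)``; ``n_spicules``/``spicule_depth`` modulate the blob
    radius angularly to mimic an irregular margin.
    """

    amplitude: float
    radius_range: tuple[float, float]
    edge_sharpness: float
    n_spicules: int = 0
    spicule_depth: float = 0.0


_DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "D": TextureParams(base=150.0, slope=3.0, sigma=18.0),
    "G": TextureParams(base=115.0, slope=2.4, sigma=18.0),
    "F": TextureParams(base=85.0, slope=1.8, sigma=18.0),
}

_DEFAULT_LESIONS: dict[str, LesionParams] = {
    "benign": LesionParams(amplitude=35.0, radius_range=(18.0, 30.0), edge_sharpness=2.0),
    "malignant": LesionParams(
        amplitude=55.0, radius_range=(14.0, 26.0), edge_sharpness=3.0,
        n_spicules=9, spicule_depth=0.45,
    ),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic fixture set; identical specs + seeds
    produce pixel-identical patches."""

    counts: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    patch_side: int = 256
    texture_params: Mapping[str, TextureParams] = field(
        default_factory=lambda: dict(_DEFAULT_TEXTURES)
    )
    lesion_params: Mapping[str, LesionParams] = field(
        default_factory=lambda: dict(_DEFAULT_LESIONS)
    )
    separability: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.patch_side < 32:
            raise ValidationError(f"patch_side must be >= 32, got {self.patch_side}")
        for key, n in self.counts.items():
            tissue, label = key
            if tissue not in TISSUES or label not in CLASS_ORDER:
                raise ValidationError(f"counts: unknown (tissue, class) cell {key!r}")
            if n < 0:
                raise ValidationError(f"counts[{key!r}] must be >= 0, got {n}")
        if self.separability < 0:
            raise ValidationError(f"separability must be >= 0, got {self.separability}")
        for (tissue, label), n in self.counts.items():
            if n > 0 and tissue not in self.texture_params:
                raise ValidationError(f"texture_params missing tissue {tissue!r}")
            if n > 0 and label != "normal" and label not in self.lesion_params:
                raise ValidationError(f"lesion_params missing class {label!r}")

    def scaled(self, factor: float) -> "SyntheticSpec":
        """A spec with every cell count scaled by ``factor`` (rounded, min 2)."""
        new_counts = {
            k: (max(2, round(v * factor)) if v > 0 else 0) for k, v in self.counts.items()
        }
        return replace(self, counts=new_counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class FixtureManifest:
    """Index of a written fixture: one entry per patch plus the seed used."""

    entries: list[dict]
    seed: int

    def validate(self) -> None:
        ids = [e["patch_id"] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("manifest patch ids are not unique")
        for e in self.entries:
            if not Path(e["path"]).exists():
                raise ValidationError(f"manifest path does not exist: {e['path']}")


def _textured_background(rng: np.random.Generator, side: int, tp: TextureParams) -> np.ndarray:
    """Band-limited Gaussian noise field with power-spectral slope ``tp.slope``."""
    white = rng.standard_normal((side, side))
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled separately
    amplitude = f ** (-tp.slope / 2.0)
    amplitude[0, 0] = 0.0  # zero-mean field; base gray added afterwards
    fieldv = np.fft.ifft2(np.fft.fft2(white) * amplitude).real
    std = fieldv.std()
    if std > 0:
        fieldv = fieldv / std
    return tp.base + tp.sigma * fieldv


def _lesion_profile(
    rng: np.random.Generator, side: int, lp: LesionParams, separability: float
) -> tuple[np.ndarray, dict]:
    """Additive bright blob; radius angularly modulated when spiculated."""
    scale = side / 256.0
    radius = float(rng.uniform(*lp.radius_range)) * scale
    jitter = side / 8.0
    cy = side / 2.0 + float(rng.uniform(-jitter, jitter))
    cx = side / 2.0 + float(rng.uniform(-jitter, jitter))
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    rows = np.arange(side)[:, None] - cy
    cols = np.arange(side)[None, :] - cx
    dist = np.hypot(rows, cols)
    if lp.n_spicules > 0:
        theta = np.arctan2(rows, cols)
        r_eff = radius * (1.0 + lp.spicule_depth * np.cos(lp.n_spicules * theta + phase))
        r_eff = np.maximum(r_eff, 1e-6)
    else:
        r_eff = radius
    profile = lp.amplitude * separability * np.exp(-((dist / r_eff) ** lp.edge_sharpness))
    meta = {"centre_row": int(round(cy)), "centre_col": int(round(cx)), "radius": int(round(radius))}
    return profile, meta


def generate_patches(spec: SyntheticSpec) -> list[Patch]:
    """Generate the requested number of patches per (tissue, class) cell.

    Deterministic: identical ``spec`` (including ``seed``) gives
    pixel-identical patches.  With ``separability == 0`` the lesion signal
    vanishes and the three classes are statistically indistinguishable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    patches: list[Patch] = []
    index = 0
    for tissue in ("D", "F", "G"):
        for label in CLASS_ORDER:
            n = int(spec.counts.get((tissue, label), 0))
            for _ in range(n):
                tp = spec.texture_params[tissue]
                img = _textured_background(rng, spec.patch_side, tp)
                meta: dict = {}
                if label != "normal":
                    profile, meta = _lesion_profile(
                        rng, spec.patch_side, spec.lesion_params[label], spec.separability
                    )
                    img = img + profile
                pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
                patches.append(
                    Patch(
                        pixels=pixels,
                        label=label,
                        tissue=tissue,
                        source_ref=f"syn{index:03d}",
                        origin=(0, 0),
                        meta=meta,
                    )
                )
                index += 1
    return patches


def write_mias_fixture(patches: list[Patch], directory) -> FixtureManifest:
    """Write patches as a MIAS-style directory: PGM files + Info metadata.

    Normal patches produce 3-field metadata lines; abnormal patches produce
    7-field lines (class code CIRC for benign, SPIC for malignant; centre in
    MIAS bottom-left-origin coordinates).  The written tree round-trips
    through :func:`mammotv.mias.parse_info_file` with identical labels and
    tissue types.  A ``manifest.csv`` indexes every file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [p.source_ref for p in patches]
    if len(set(ids)) != len(ids):
        raise ValidationError("patch source_refs must be unique to write a fixture")
    info_lines: list[str] = []
    entries: list[dict] = []
    for p in patches:
        path = directory / f"{p.source_ref}.pgm"
        write_pgm(p.pixels, path)
        side = p.side
        if p.label == "normal":
            info_lines.append(f"{p.source_ref} {p.tissue} {NORMAL_CODE}")
        else:
            code = "CIRC" if p.label == "benign" else "SPIC"
            sev = "B" if p.label == "benign" else "M"
            centre_row = int(p.meta.get("centre_row", side // 2))
            centre_col = int(p.meta.get("centre_col", side // 2))
            radius = int(p.meta.get("radius", side // 4))
            y_mias = side - 1 - centre_row  # bottom-left origin
            info_lines.append(
                f"{p.source_ref} {p.tissue} {code} {sev} {centre_col} {y_mias} {radius}"
            )
        entries.append(
            {
                "patch_id": p.source_ref,
                "path": str(path),
                "tissue": p.tissue,
                "label": p.label,
                "params": json.dumps(p.meta, sort_keys=True),
            }
        )
    (directory / "info.txt").write_text("\n".join(info_lines) + "\n")
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["patch_id", "path", "tissue", "label", "params"])
        writer.writeheader()
        writer.writerows(entries)
    manifest = FixtureManifest(entries=entries, seed=0)
    manifest.validate()
    # sanity: the metadata we just wrote must parse back
    parse_info_file((directory / "info.txt").read_text())
    return manifest
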