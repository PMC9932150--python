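"""MIAS-style data access: metadata parsing, PGM images, ROI patch extraction.

The MIAS (Mammographic Image Analysis Society) database distributes 322
digitised mammograms as PGM files plus one plain-text "Info" file.  Each data
line carries a reference number, a background-tissue letter (F fatty,
G fatty-glandular, D dense-glandular) and an abnormality class code; abnormal
entries additionally carry a severity letter (B benign / M malignant), the
abnormality centre ``x y`` and an approximate enclosing-circle radius, all in
pixels.  The ``y`` coordinate uses a bottom-left image origin — the classic
trap when cropping; :func:`extract_roi_patch` performs the axis conversion
explicitly.

Region-of-interest (ROI) patches are fixed-size square crops: centred on the
annotated abnormality for benign/malignant records, and randomly placed
(avoiding empty black border regions) for normal records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .errors import FormatError, ParseError, SamplingError, ValidationError

TISSUES = ("F", "G", "D")
CLASS_ORDER = ("normal", "benign", "malignant")

NORMAL_CODE = "NORM"
#: Abnormality class codes used by the MIAS metadata dialect.
ABNORMALITY_CODES = ("CALC", "CIRC", "SPIC", "MISC", "ARCH", "ASYM")

_SEVERITY_LABEL = {"B": "benign", "M": "malignant"}


@dataclass(frozen=True)
class MiasRecord:
    """One metadata line of the MIAS Info dialect.

    ``severity == "none"`` iff the record is normal iff centre/radius are
    absent; this invariant is enforced at construction.
    """

    refnum: str
    tissue: str
    class_code: str
    severity: str  # "benign" | "malignant" | "none"
    centre_x: Optional[int] = None
    centre_y: Optional[int] = None
    radius: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue type {self.tissue!r}")
        is_normal = self.class_code == NORMAL_CODE
        if is_normal != (self.severity == "none"):
            raise ValidationError(
                f"record {self.refnum}: class code {self.class_code!r} inconsistent "
                f"with severity {self.severity!r}"
            )
        has_geometry = self.centre_x is not None and self.centre_y is not None
        if is_normal and has_geometry:
            raise ValidationError(f"record {self.refnum}: normal record with centre coordinates")
        if not is_normal and not has_geometry:
            raise ValidationError(f"record {self.refnum}: abnormal record without centre coordinates")

    @property
    def label(self) -> str:
        """Patch class label: benign / malignant / normal (exhaustive, exclusive)."""
        return "normal" if self.severity == "none" else self.severity


@dataclass
class Patch:
    """A square grayscale ROI crop with its diagnostic label and provenance."""

    pixels: np.ndarray  # 2-D uint8
    label: str  # normal | benign | malignant
    tissue: str  # F | G | D
    source_ref: str
    origin: tuple[int, int] = (0, 0)  # (row, col) of the crop in the source image
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError("patch pixels must be a square 2-D array")
        if self.label not in CLASS_ORDER:
            raise ValidationError(f"unknown patch label {self.label!r}")
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue type {self.tissue!r}")

    @property
    def side(self) -> int:
        return int(self.pixels.shape[0])


def parse_info_file(text: str) -> list[MiasRecord]:
    """Parse MIAS Info-dialect metadata text into records.

    Blank lines and lines starting with ``#`` are skipped.  A data line is
    ``refnum tissue NORM`` (3 fields) for normals or
    ``refnum tissue CODE SEV x y radius`` (7 fields) for abnormal entries.
    Images with several abnormalities contribute several lines, hence several
    records (one eventual patch per abnormality).
    """
    if not text or not text.strip():
        raise ParseError("metadata text is empty")
    records: list[MiasRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError(f"line {lineno}: expected at least 3 fields, got {len(tokens)}")
        refnum, tissue, code = tokens[:3]
        if tissue not in TISSUES:
            raise ParseError(f"line {lineno}: unknown tissue code {tissue!r}")
        if code == NORMAL_CODE:
            if len(tokens) != 3:
                raise ParseError(f"line {lineno}: normal entry must have exactly 3 fields")
            records.append(MiasRecord(refnum, tissue, code, "none"))
        elif code in ABNORMALITY_CODES:
            if len(tokens) != 7:
                raise ParseError(
                    f"line {lineno}: abnormal entry must have 7 fields "
                    f"(refnum tissue class severity x y radius), got {len(tokens)}"
                )
            severity_code = tokens[3]
            if severity_code not in _SEVERITY_LABEL:
                raise ParseError(f"line {lineno}: unknown severity code {severity_code!r}")
            try:
                x, y, radius = (int(t) for t in tokens[4:7])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer geometry field ({exc})") from exc
            records.append(
                MiasRecord(refnum, tissue, code, _SEVERITY_LABEL[severity_code], x, y, radius)
            )
        else:
            raise ParseError(f"line {lineno}: unknown class code {code!r}")
    if not records:
        raise ParseError("metadata text contains no data lines")
    return records


def _pgm_header(data: bytes) -> tuple[bytes, int, int, int]:
    """Tokenise a PGM header (magic, width, height, maxval), honouring # comments."""
    tokens: list[bytes] = []
    i = 0
    while len(tokens) < 4 and i < len(data):
        c = data[i : i + 1]
        if c == b"#":
            while i < len(data) and data[i : i + 1] != b"\n":
                i += 1
        elif c.isspace():
            i += 1
        else:
            j = i
            while j < len(data) and not data[j : j + 1].isspace() and data[j : j + 1] != b"#":
                j += 1
            tokens.append(data[i:j])
            i = j
    if len(tokens) < 4:
        raise FormatError("truncated PGM header")
    try:
        width, height, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    except ValueError as exc:
        raise FormatError(f"non-numeric PGM header field: {exc}") from exc
    return tokens[0], width, height, maxval


def read_pgm(path) -> np.ndarray:
    """Read a P5 (binary) or P2 (plain ASCII) PGM file as a 2-D uint8 array.

    Only 8-bit images are supported; ``maxval > 255`` raises
    :class:`~mammotv.errors.FormatError`, as do bad magic numbers and
    truncated payloads.  Payload decoding is delegated to Pillow.
    """
    path = Path(path)
    data = path.read_bytes()
    if data[:2] not in (b"P2", b"P5"):
        raise FormatError(f"{path}: not a P2/P5 PGM file (magic {data[:2]!r})")
    _, _, _, maxval = _pgm_header(data)
    if maxval > 255:
        raise FormatError(f"{path}: maxval {maxval} exceeds the supported 8-bit depth")
    try:
        with Image.open(io.BytesIO(data)) as im:
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises various types on truncation
        raise FormatError(f"{path}: cannot decode PGM payload ({exc})") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image")
    return arr.astype(np.uint8)


def write_pgm(array: np.ndarray, path) -> None:
    """Write a 2-D uint8 array as a binary (P5) PGM file."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValidationError("write_pgm expects a 2-D array")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path), format="PPM")


def extract_roi_patch(image: np.ndarray, record: MiasRecord, patch_side: int) -> Patch:
    """Crop the square ROI centred on an annotated abnormality.

    The MIAS ``y`` coordinate counts from the bottom-left corner, so the row
    index is ``height - 1 - y``.  Crops that would overlap the image border
    are shifted inward so the full square stays inside the image (no padding
    pixels are ever introduced).
    """
    if record.centre_x is None or record.centre_y is None:
        raise ValidationError(f"record {record.refnum} has no centre coordinates (normal record?)")
    image = np.asarray(image)
    height, width = image.shape
    if patch_side > height or patch_side > width:
        raise ValidationError(
            f"patch_side {patch_side} exceeds image dimensions {height}x{width}"
        )
    centre_row = height - 1 - record.centre_y
    r0 = int(np.clip(centre_row - patch_side // 2, 0, height - patch_side))
    c0 = int(np.clip(record.centre_x - patch_side // 2, 0, width - patch_side))
    crop = image[r0 : r0 + patch_side, c0 : c0 + patch_side]
    return Patch(
        pixels=crop.astype(np.uint8),
        label=record.label,
        tissue=record.tissue,
        source_ref=record.refnum,
        origin=(r0, c0),
    )


def extract_random_normal_patch(
    image: np.ndarray,
    record: MiasRecord,
    patch_side: int,
    seed: int,
    background_threshold: float = 20.0,
    max_draws: int = 100,
) -> Patch:
    """Sample a uniformly random fully-inside crop from a normal mammogram.

    Candidate crops whose mean intensity falls below ``background_threshold``
    are rejected (they would be empty black border); after ``max_draws``
    rejections a :class:`~mammotv.errors.SamplingError` is raised.
    Deterministic given ``seed``.
    """
    if record.severity != "none":
        raise ValidationError(f"record {record.refnum} is not a normal record")
    image = np.asarray(image)
    height, width = image.shape
    if patch_side > height or patch_side > width:
        raise ValidationError(
            f"patch_side {patch_side} exceeds image dimensions {height}x{width}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        r0 = int(rng.integers(0, height - patch_side + 1))
        c0 = int(rng.integers(0, width - patch_side + 1))
        crop = image[r0 : r0 + patch_side, c0 : c0 + patch_side]
        if float(crop.mean()) >= background_threshold:
            return Patch(
                pixels=crop.astype(np.uint8),
                label="normal",
                tissue=record.tissue,
                source_ref=record.refnum,
                origin=(r0, c0),
            )
    raise SamplingError(
        f"record {record.refnum}: no crop passed the background filter "
        f"(threshold {background_threshold}) in {max_draws} draws"
    )


def load_patches(
    directory,
    patch_side: int = 256,
    seed: int = 0,
    normals_per_image: int = 1,
    background_threshold: float = 20.0,
    info_name: str = "info.txt",
) -> list[Patch]:
    """Load a MIAS-style directory (PGM files + Info metadata) into patches.

    Abnormal records yield one centred ROI crop each; each normal record
    yields ``normals_per_image`` random crops (the per-image count is a
    configuration knob because the canonical 300-normal-patch distribution
    implies more than one patch from some normal images).
    """
    directory = Path(directory)
    info_path = directory / info_name
    records = parse_info_file(info_path.read_text())
    patches: list[Patch] = []
    for k, record in enumerate(records):
        image = read_pgm(directory / f"{record.refnum}.pgm")
        if record.severity == "none":
            for j in range(normals_per_image):
                patches.append(
                    extract_random_normal_patch(
                        image,
                        record,
                        min(patch_side, image.shape[0], image.shape[1]),
                        seed=seed + 997 * k + j,
                        background_threshold=background_threshold,
                    )
                )
        else:
            patches.append(
                extract_roi_patch(
                    image, record, min(patch_side, image.shape[0], image.shape[1])
                )
            )
    return patches
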