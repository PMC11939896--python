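"""Image acquisition and preprocessing.

Reduces a flow-cell photograph to a single mean RGB triple through the
chain: decode -> resize to a common resolution -> optional gray-world white
balance -> crop a region of interest (ROI) -> spatial average.  Fixing the
resolution and averaging a 50x50 ROI makes the extracted intensities
comparable across phones with different sensors, and spatial averaging
suppresses per-pixel shot noise by ~1/sqrt(N).

Pixels are kept as float64 in [0, 255] throughout; quantization to 8 bits
only happens when an image is written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import (
    BoundsError,
    DegenerateImageError,
    FormatError,
    ParameterError,
)

#: Smallest image edge the pipeline accepts: the default ROI must fit.
MIN_EDGE = 50

#: Default long-edge resolution images are standardized to.
DEFAULT_TARGET_LONG_EDGE = 1000


class Role(str, Enum):
    """What a sample frame is, within a calibration/measurement session."""

    WATER = "water"
    BLANK = "blank"
    STANDARD = "standard"
    TEST = "test"


class Channel(str, Enum):
    """Color channel used for photometry; index matches array axis 2."""

    RED = "red"
    GREEN = "green"
    BLUE = "blue"

    @property
    def index(self) -> int:
        return ("red", "green", "blue").index(self.value)


@dataclass
class ImageSample:
    """A decoded flow-cell frame plus acquisition metadata.

    ``pixels`` is an H x W x 3 float64 array, channels ordered R, G, B,
    values in [0, 255].
    """

    pixels: np.ndarray
    role: Role = Role.TEST
    assay_id: str = ""
    device_label: str = ""
    lighting_label: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected H x W x 3 pixel array, got shape {px.shape}"
            )
        if px.min() < 0 or px.max() > 255:
            raise FormatError(
                "pixel intensities must lie in [0, 255]; "
                f"got range [{px.min():g}, {px.max():g}]"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ROIConfig:
    """Placement of the region of interest inside a standardized frame.

    The default is a centered 50x50 patch; an explicit 0-based origin
    (row-major, half-open extent) supports off-center flow cells.
    """

    height_px: int = 50
    width_px: int = 50
    anchor: str = "center"  # "center" | "explicit"
    origin_row: int = 0
    origin_col: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ParameterError("ROI dimensions must be >= 1 pixel")
        if self.anchor not in ("center", "explicit"):
            raise ParameterError(f"unknown ROI anchor {self.anchor!r}")


@dataclass(frozen=True)
class RawRGB:
    """Mean channel intensities of one frame, unitless in [0, 255]."""

    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=np.float64)

    def channel(self, ch: Channel) -> float:
        return float(self.as_array()[ch.index])


def load_image(
    path: str | Path,
    role: Role = Role.TEST,
    assay_id: str = "",
    device_label: str = "",
    lighting_label: str = "",
) -> ImageSample:
    """Decode a PNG/JPEG/TIFF file into an :class:`ImageSample`.

    An alpha channel, if present, is dropped.  Grayscale and palette
    images are rejected: the photometry stage needs three real channels.
    """
    p = Path(path)
    try:
        with Image.open(p) as im:
            mode = im.mode
            if mode in ("RGBA", "LA", "PA"):
                arr = np.asarray(im.convert("RGBA"), dtype=np.float64)[:, :, :3]
            elif mode == "RGB":
                arr = np.asarray(im, dtype=np.float64)
            else:
                bands = len(im.getbands())
                raise FormatError(
                    f"{p}: need a 3-channel color image, got mode "
                    f"{mode!r} ({bands} channel(s))"
                )
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {p}") from exc
    except UnidentifiedImageError as exc:
        raise IOError(f"not a decodable image file: {p}") from exc
    return ImageSample(
        pixels=arr,
        role=role,
        assay_id=assay_id,
        device_label=device_label,
        lighting_label=lighting_label,
        source_path=str(p),
    )


def save_image(img: ImageSample, path: str | Path) -> None:
    """Write an image to disk as 8-bit PNG (values rounded, then clipped)."""
    arr = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def resize_standard(
    img: ImageSample, target_long_edge: int = DEFAULT_TARGET_LONG_EDGE
) -> ImageSample:
    """Resize so the longer edge equals ``target_long_edge``.

    Aspect ratio is preserved to the nearest pixel; resampling is bilinear.
    An image already at the target is returned unchanged.
    """
    if target_long_edge < MIN_EDGE:
        raise ParameterError(
            f"target_long_edge must be >= {MIN_EDGE} so the ROI fits; "
            f"got {target_long_edge}"
        )
    h, w = img.shape
    long_edge = max(h, w)
    if long_edge == target_long_edge:
        return img
    scale = target_long_edge / long_edge
    if h >= w:
        new_h = target_long_edge
        new_w = max(1, round(w * scale))
    else:
        new_w = target_long_edge
        new_h = max(1, round(h * scale))
    # bilinear in float64: PIL's float path is only float32, which is too
    # coarse for downstream ratio cancellation
    px = ndimage.zoom(
        img.pixels, (new_h / h, new_w / w, 1.0), order=1, mode="nearest"
    )
    assert px.shape == (new_h, new_w, 3)
    px = np.clip(px, 0.0, 255.0)
    return replace(img, pixels=px)


def white_balance(img: ImageSample) -> ImageSample:
    """Gray-world white balance over the full frame.

    Each channel is scaled so its global mean equals the mean of the three
    channel means; the result is clipped to [0, 255].  Idempotent before
    clipping.  Appropriate only when the frame contains enough neutral
    content for the gray-world assumption to hold — a frame filled by a
    colored flow cell violates it, which is why the measurement pipeline
    leaves this off by default.
    """
    means = img.pixels.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        dead = [("red", "green", "blue")[i] for i in np.flatnonzero(means == 0)]
        raise DegenerateImageError(
            f"channel(s) {', '.join(dead)} have zero mean; cannot balance"
        )
    grand = means.mean()
    px = np.clip(img.pixels * (grand / means), 0.0, 255.0)
    return replace(img, pixels=px)


def extract_roi(img: ImageSample, roi: ROIConfig = ROIConfig()) -> np.ndarray:
    """Return the ROI sub-grid (h x w x 3 view copy).

    A center anchor places the ROI at ``floor((H-h)/2), floor((W-w)/2)``.
    """
    h, w = img.shape
    if roi.anchor == "center":
        r0 = (h - roi.height_px) // 2
        c0 = (w - roi.width_px) // 2
    else:
        r0, c0 = roi.origin_row, roi.origin_col
    r1, c1 = r0 + roi.height_px, c0 + roi.width_px
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise BoundsError(
            f"ROI rows [{r0}, {r1}) cols [{c0}, {c1}) does not fit inside "
            f"a {h} x {w} image"
        )
    return img.pixels[r0:r1, c0:c1, :].copy()


def spatial_average(patch: np.ndarray) -> RawRGB:
    """Per-channel arithmetic mean over all pixels of a patch.

    Fractional means are preserved; no rounding.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ParameterError("cannot average an empty patch")
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ParameterError(f"expected h x w x 3 patch, got {patch.shape}")
    m = patch.reshape(-1, 3).mean(axis=0)
    return RawRGB(float(m[0]), float(m[1]), float(m[2]))


def average_frames(frames: Sequence[RawRGB]) -> RawRGB:
    """Mean of several per-frame RGB triples (multi-shot noise reduction)."""
    if not frames:
        raise ParameterError("need at least one frame to average")
    arr = np.stack([f.as_array() for f in frames])
    m = arr.mean(axis=0)
    return RawRGB(float(m[0]), float(m[1]), float(m[2]))


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain (YAML keys ``preprocess.*``/``roi.*``)."""

    target_long_edge: int = DEFAULT_TARGET_LONG_EDGE
    white_balance: bool = False
    roi: ROIConfig = field(default_factory=ROIConfig)


def process_image(img: ImageSample, cfg: PreprocessConfig = PreprocessConfig()) -> RawRGB:
    """Run the full preprocessing chain on one frame and return its RawRGB."""
    out = resize_standard(img, cfg.target_long_edge)
    if cfg.white_balance:
        out = white_balance(out)
    patch = extract_roi(out, cfg.roi)
    return spatial_average(patch)
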