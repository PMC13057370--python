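"""Field-image containers and the preprocessing chain for confocal assay fields.

A field is a multi-channel 16-bit confocal acquisition (green = CFSE-labelled
T cells, red = endothelial monolayer).  Preprocessing follows the fixed order
used throughout the package: channel export -> background subtraction ->
8-bit conversion.  An unweighted RGB-average path is provided for legacy
colour exports only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.morphology import disk, erosion, dilation

__all__ = [
    "FieldImage",
    "GrayImage8",
    "split_channels",
    "subtract_background",
    "to_8bit",
    "rgb_to_gray",
    "read_field",
    "write_field",
]

U16_MAX = 65535


@dataclass
class FieldImage:
    """A named set of co-registered single-channel 16-bit images.

    Parameters
    ----------
    channels
        Mapping from role name (e.g. ``"green"``, ``"red"``) to a 2-D
        ``uint16`` array.  All channels must share one shape.
    pixel_size_um
        Physical pixel pitch in micrometres per pixel.
    source_path
        Provenance string (file the field was read from, or ``"synthetic"``).
    """

    channels: dict
    pixel_size_um: float = 1.0
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D arrays")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.min() < 0 or arr.max() > U16_MAX:
                raise ValueError(f"channel {name!r} outside [0, {U16_MAX}]")
            self.channels[name] = arr.astype(np.uint16)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


@dataclass
class GrayImage8:
    """An 8-bit grayscale image plus the intensity mapping that produced it."""

    pixels: np.ndarray
    mapping_record: tuple = (0.0, 255.0)  # (lo, hi) source intensities

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        lo, hi = self.mapping_record
        if not lo < hi:
            raise ValueError("mapping_record requires lo < hi")


def split_channels(fieldimg: FieldImage, names=None) -> dict:
    """Export individual channels, unmodified.

    ``names`` restricts the export; an unknown name raises with the
    available names listed.
    """
    if names is None:
        names = list(fieldimg.channels)
    out = {}
    for name in names:
        if name not in fieldimg.channels:
            raise KeyError(
                f"channel {name!r} not present; available: "
                f"{sorted(fieldimg.channels)}"
            )
        out[name] = fieldimg.channels[name].copy()
    return out


def subtract_background(img: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Remove gradual background by a rolling-ball-equivalent top-hat.

    The background estimate is a grayscale morphological opening with a disc
    structuring element of ``radius_px`` (ImageJ's "Subtract Background" tool
    family); the opening is subtracted so that intensity trends on scales of
    the disc or larger vanish while compact bright objects survive.  Output is
    non-negative and keeps the input dtype range.
    """
    img = np.asarray(img)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(img.shape):
        raise ValueError(
            f"radius {radius_px} px too large for image of shape {img.shape}"
        )
    # sequence decomposition keeps the disc opening tractable at radius ~50
    fp = disk(radius_px, decomposition="sequence")
    work = img.astype(np.int32)
    background = dilation(erosion(work, fp), fp)
    out = np.clip(work - background, 0, None)
    return out.astype(img.dtype)


def to_8bit(img: np.ndarray, lo_percentile: float = 0.0,
            hi_percentile: float = 99.9) -> GrayImage8:
    """Linearly map the [P_lo, P_hi] intensity window onto [0, 255].

    Values outside the window clip to 0/255.  Rounding is half-up so the
    mapping is bit-stable across platforms.  The window defaults leave only a
    small bright tail saturated, mirroring acquisition practice where a few
    saturated pixels anchor the dynamic range.
    """
    img = np.asarray(img)
    if not (0 <= lo_percentile < hi_percentile <= 100):
        raise ValueError("need 0 <= lo < hi <= 100")
    lo = float(np.percentile(img, lo_percentile))
    hi = float(np.percentile(img, hi_percentile))
    if lo == hi:
        raise ValueError(
            f"degenerate intensity window (P{lo_percentile} == P{hi_percentile}"
            f" == {lo}); cannot map to 8 bit"
        )
    scaled = (img.astype(np.float64) - lo) * (255.0 / (hi - lo))
    # half-up; the epsilon absorbs float error at exact .5 boundaries
    out = np.floor(scaled + 0.5 + 1e-9)
    out = np.clip(out, 0, 255).astype(np.uint8)
    return GrayImage8(out, mapping_record=(lo, hi))


def rgb_to_gray(rgb: np.ndarray) -> GrayImage8:
    """Average the three primary-colour planes into one gray plane.

    Legacy path for colour exports; each output pixel is the unweighted mean
    of R, G and B, rounded half-up.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    mean = rgb.astype(np.float64).mean(axis=2)
    out = np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)
    return GrayImage8(out, mapping_record=(0.0, 255.0))


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O

def write_field(fieldimg: FieldImage, tiff_path) -> Path:
    """Write a field as a multi-page TIFF (one page per channel) plus a JSON
    sidecar recording channel roles and pixel size."""
    tiff_path = Path(tiff_path)
    names = list(fieldimg.channels)
    stack = np.stack([fieldimg.channels[n] for n in names])
    try:
        tifffile.imwrite(tiff_path, stack)
    except OSError as exc:  # pragma: no cover - env dependent
        raise OSError(f"failed writing field TIFF at {tiff_path}: {exc}") from exc
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "channels": names,
        "pixel_size_um": fieldimg.pixel_size_um,
    }, indent=2))
    return tiff_path


def read_field(tiff_path) -> FieldImage:
    """Read a field written by :func:`write_field` (sidecar required)."""
    tiff_path = Path(tiff_path)
    sidecar = tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing channel sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(meta["channels"]):
        raise ValueError(
            f"{tiff_path}: {stack.shape[0]} pages but sidecar lists "
            f"{len(meta['channels'])} channels"
        )
    channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
    return FieldImage(channels, pixel_size_um=meta["pixel_size_um"],
                      source_path=str(tiff_path))
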