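"""Calibrated image-stack I/O and z-projection.

A *field* is one microscope frame of a retinal whole-mount: a z-stack of one
or two fluorescence channels (Iba-1 in red, optionally P2RY12 in green),
acquired at 20x so that each field covers 0.1502 mm^2, sampled every 2 um in
depth.  Quantification operates on a 2-D projection of the stack; the
default projection is maximum-intensity, which is standard for sparse
fluorescent structures such as microglia.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Area of one 20x field, mm^2.
FIELD_AREA_MM2 = 0.1502

#: Side of a square field with that area, in micrometres.
FIELD_SIDE_UM = float(np.sqrt(FIELD_AREA_MM2) * 1000.0)  # ~387.6 um

#: Default axial sampling of the z-scan, micrometres between planes.
DEFAULT_Z_STEP_UM = 2.0

#: Channel names the pipeline understands.
KNOWN_CHANNELS = ("iba1", "p2ry12")


@dataclass
class ImageStack:
    """A calibrated multi-plane, multi-channel image of one field.

    Parameters
    ----------
    channels
        Mapping from channel name (``"iba1"``, ``"p2ry12"``) to a 3-D
        ``(z, y, x)`` pixel array.  All channels must share one shape.
    pixel_size_um
        Lateral calibration, micrometres per pixel (isotropic in x and y).
    z_step_um
        Axial distance between consecutive planes, micrometres.
    bit_depth
        8 or 16; pixel values must lie within the corresponding range.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float = DEFAULT_Z_STEP_UM
    bit_depth: int = 8
    stack_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channel arrays must be (z, y, x); got {first}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        limit = 2**self.bit_depth - 1
        for ch, arr in self.channels.items():
            if arr.min() < 0 or arr.max() > limit:
                raise ValueError(
                    f"channel {ch!r} has values outside [0, {limit}] "
                    f"for bit depth {self.bit_depth}"
                )

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


@dataclass
class FieldImage:
    """A single-channel 2-D field image with calibration and provenance.

    ``flags`` carries non-fatal conditions discovered downstream (e.g. an
    all-zero field is flagged ``"empty_field"`` rather than raising).
    """

    pixels: np.ndarray
    pixel_size_um: float
    provenance: str = ""
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("FieldImage pixels must be non-negative")

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * self.pixel_size_um**2 / 1e6

    def with_flags(self, *flags: str) -> "FieldImage":
        return replace(self, flags=tuple(dict.fromkeys(self.flags + flags)))


def _dtype_for(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def read_stack(
    path,
    pixel_size_um: float | None = None,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    channel_order: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF as a calibrated :class:`ImageStack`.

    The TIFF must be ``(z, y, x)`` for one channel or ``(z, c, y, x)`` for
    several; ``channel_order`` names the channels in file order and
    defaults to ``("iba1",)`` / ``("iba1", "p2ry12")`` by channel count.
    Lateral calibration is taken from the TIFF resolution tags when
    present; an explicit ``pixel_size_um`` always wins, with a warning on
    conflict.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_tags(tf)

    if meta_px is not None:
        if pixel_size_um is None:
            pixel_size_um = meta_px
        elif not np.isclose(meta_px, pixel_size_um, rtol=1e-3):
            warnings.warn(
                f"TIFF metadata pixel size {meta_px:.4g} um differs from "
                f"configured {pixel_size_um:.4g} um; using configured value",
                stacklevel=2,
            )
    if pixel_size_um is None:
        raise ValueError("pixel_size_um not in TIFF metadata; pass it explicitly")

    if arr.ndim == 2:
        arr = arr[None]
    if channel_order is None:
        n_file = arr.shape[1] if arr.ndim == 4 else 1
        if n_file > len(KNOWN_CHANNELS):
            raise ValueError(f"file has {n_file} channels; name them explicitly")
        channel_order = KNOWN_CHANNELS[:n_file]
    if arr.ndim == 3:
        if len(channel_order) != 1:
            raise ValueError(
                f"file has 1 channel but channel_order names {len(channel_order)}"
            )
        per_channel = [arr]
    elif arr.ndim == 4:
        if arr.shape[1] != len(channel_order):
            raise ValueError(
                f"file has {arr.shape[1]} channels but channel_order names "
                f"{len(channel_order)}"
            )
        per_channel = [arr[:, i] for i in range(arr.shape[1])]
    else:
        raise ValueError(f"cannot interpret TIFF with shape {arr.shape}")

    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    channels = {
        name: plane.astype(_dtype_for(bit_depth))
        for name, plane in zip(channel_order, per_channel)
    }
    return ImageStack(
        channels=channels,
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um),
        bit_depth=bit_depth,
        stack_id=str(path),
    )


def write_stack(path, stack: ImageStack, channel_order: tuple[str, ...] | None = None) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF.

    Single channel -> ``(z, y, x)`` pages; several -> ``(z, c, y, x)``.
    Lateral calibration is stored in the TIFF resolution tags (pixels per
    centimetre) so :func:`read_stack` can recover it.
    """
    order = channel_order or tuple(stack.channels)
    dtype = _dtype_for(stack.bit_depth)
    if len(order) == 1:
        data = stack.channels[order[0]].astype(dtype)
    else:
        data = np.stack([stack.channels[ch] for ch in order], axis=1).astype(dtype)
    px_per_cm = 1e4 / stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def _pixel_size_from_tags(tf: tifffile.TiffFile) -> float | None:
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        px_per_unit = num / den
        unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 0), None)
        if unit_um is None:
            return None
        return unit_um / px_per_unit
    except Exception:  # malformed tags are not fatal; calibration comes from config
        return None


def project(stack: ImageStack, channel: str, method: str = "max") -> FieldImage:
    """Project one channel of a stack to 2-D (``"max"`` or ``"mean"``)."""
    if channel not in stack.channels:
        raise KeyError(
            f"channel {channel!r} not in stack (has {sorted(stack.channels)})"
        )
    planes = stack.channels[channel]
    if method == "max":
        pixels = planes.max(axis=0)
    elif method == "mean":
        pixels = planes.mean(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return FieldImage(
        pixels=pixels.astype(np.float64),
        pixel_size_um=stack.pixel_size_um,
        provenance=f"{method}_projection:{channel}:{stack.stack_id}",
    )


def max_project(stack: ImageStack, channel: str = "iba1") -> FieldImage:
    """Maximum-intensity projection along z of one channel."""
    return project(stack, channel, method="max")
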