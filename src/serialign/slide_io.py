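"""Reading and writing slide images.

Sources are flat or pyramidal TIFF / OME-TIFF and PNG.  A slide is held as
its stored pyramid levels (largest first) plus channel metadata and the
physical pixel size when the file records one.  Registration runs on a
downsampled copy; :func:`get_registration_image` picks the stored level
closest to the requested size and never upsamples.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.transform import resize

__all__ = ["SlideImage", "ScalarImage", "read_slide", "get_registration_image",
           "write_registered"]


class SlideFormatError(ValueError):
    """Raised when a file cannot be read as a supported slide format."""


@dataclass
class ScalarImage:
    """A single-channel working image at some scale relative to full resolution."""

    pixels: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not (0 < self.scale <= 1.0 + 1e-9):
            raise ValueError(f"scale must be in (0, 1], got {self.scale}")


@dataclass
class SlideImage:
    """A (possibly pyramidal) source image.

    ``levels`` are ordered largest first; ``full_shape`` is (width, height)
    of level 0.  ``pixel_size_um`` is micrometres per pixel at level 0, or
    None when the source file does not record it.
    """

    name: str
    levels: list[np.ndarray]
    channel_names: list[str] = field(default_factory=list)
    is_rgb: bool = True
    pixel_size_um: float | None = None

    def __post_init__(self):
        if not self.levels:
            raise ValueError("slide must have at least one level")
        for a, b in zip(self.levels, self.levels[1:]):
            if b.shape[0] >= a.shape[0] or b.shape[1] >= a.shape[1]:
                raise ValueError("pyramid levels must shrink in both dimensions")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channel_names:
            n = self.n_channels
            self.channel_names = (
                ["R", "G", "B"] if self.is_rgb and n == 3
                else [f"C{i}" for i in range(n)]
            )

    @property
    def full_shape(self) -> tuple[int, int]:
        h, w = self.levels[0].shape[:2]
        return (w, h)

    @property
    def n_channels(self) -> int:
        lvl = self.levels[0]
        return 1 if lvl.ndim == 2 else lvl.shape[2]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, int):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return channel
        lowered = [c.lower() for c in self.channel_names]
        if channel.lower() not in lowered:
            raise KeyError(
                f"channel {channel!r} not found; available: {self.channel_names}"
            )
        return lowered.index(channel.lower())


def _parse_ome_metadata(ome_xml: str):
    """Extract channel names and PhysicalSizeX (um) from OME-XML, best effort."""
    names, pixel_size = [], None
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return names, pixel_size
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is not None:
        psx = pixels.get("PhysicalSizeX")
        if psx is not None:
            try:
                pixel_size = float(psx)
                unit = pixels.get("PhysicalSizeXUnit", "µm")
                if unit in ("nm",):
                    pixel_size /= 1000.0
                elif unit in ("mm",):
                    pixel_size *= 1000.0
            except ValueError:
                pixel_size = None
        for ch in pixels.findall(f"{ns}Channel"):
            names.append(ch.get("Name") or f"C{len(names)}")
    return names, pixel_size


def _pixel_size_from_tags(page) -> float | None:
    """Physical pixel size from TIFF resolution tags (um/px), if meaningful."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if not num:
        return None
    px_per_unit = num / den
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        return 10_000.0 / px_per_unit
    if unit == 2:  # inch
        return 25_400.0 / px_per_unit
    return None


def read_slide(path: str | os.PathLike) -> SlideImage:
    """Read a TIFF/OME-TIFF/PNG file into a :class:`SlideImage`.

    RGB vs multichannel is inferred from photometric metadata; all stored
    pyramid levels are loaded.  Raises :class:`SlideFormatError` for
    unreadable or unsupported files.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise SlideFormatError(f"no such file: {path}")
    name = os.path.splitext(os.path.basename(path))[0]
    if name.lower().endswith(".ome"):
        name = name[:-4]
    ext = os.path.splitext(path)[1].lower()

    if ext == ".png":
        import imageio.v3 as iio

        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - imageio error text varies
            raise SlideFormatError(f"cannot read PNG {path}: {exc}") from exc
        if arr.size == 0:
            raise SlideFormatError(f"zero-size image: {path}")
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[..., :3]
        return SlideImage(name=name, levels=[arr], is_rgb=arr.ndim == 3)

    if ext not in (".tif", ".tiff"):
        raise SlideFormatError(f"unsupported format {ext!r} for {path}")

    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:
        raise SlideFormatError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        levels = []
        for level in getattr(series, "levels", [series]):
            arr = level.asarray()
            levels.append(arr)
        page = series.pages[0]
        photometric = getattr(page.photometric, "name", str(page.photometric)).lower()
        is_rgb = photometric == "rgb" or (
            levels[0].ndim == 3 and levels[0].shape[-1] == 3 and "minis" not in photometric
        )
        # channel-first multichannel stacks -> channel-last
        if not is_rgb:
            levels = [
                np.moveaxis(a, 0, -1)
                if a.ndim == 3 and a.shape[0] < min(a.shape[1:])
                else a
                for a in levels
            ]
        if levels[0].size == 0:
            raise SlideFormatError(f"zero-size image: {path}")
        channel_names, pixel_size = [], None
        if tf.ome_metadata:
            channel_names, pixel_size = _parse_ome_metadata(tf.ome_metadata)
        if pixel_size is None:
            pixel_size = _pixel_size_from_tags(page)
    return SlideImage(
        name=name,
        levels=levels,
        channel_names=channel_names,
        is_rgb=is_rgb,
        pixel_size_um=pixel_size,
    )


def get_registration_image(slide: SlideImage, max_dim: int = 850) -> ScalarImage:
    """Return the slide at registration scale (max dimension <= ``max_dim``).

    Picks the largest stored pyramid level whose maximum dimension fits;
    when none fits, the smallest stored level is area-averaged down to
    ``max_dim``.  Never upsamples.  ``scale`` is returned width over full
    width.  The pixel array keeps the source's channel layout.
    """
    if max_dim < 16:
        raise ValueError("max_dim must be >= 16")
    full_w = slide.full_shape[0]
    chosen = None
    for lvl in slide.levels:
        if max(lvl.shape[:2]) <= max_dim:
            chosen = lvl
            break
    if chosen is not None:
        return ScalarImage(pixels=chosen, scale=chosen.shape[1] / full_w)
    smallest = slide.levels[-1]
    h, w = smallest.shape[:2]
    factor = max_dim / max(h, w)
    new_w = max_dim if w >= h else int(round(w * factor))
    new_h = max_dim if h > w else int(round(h * factor))
    out_shape = (new_h, new_w) + smallest.shape[2:]
    resized = resize(
        smallest.astype(float), out_shape, anti_aliasing=True, preserve_range=True
    )
    if np.issubdtype(smallest.dtype, np.integer):
        info = np.iinfo(smallest.dtype)
        resized = np.clip(np.rint(resized), info.min, info.max).astype(smallest.dtype)
    return ScalarImage(pixels=resized, scale=new_w / full_w)


def _pyramid_levels(arr: np.ndarray, n: int) -> list[np.ndarray]:
    levels = [arr]
    for _ in range(1, n):
        prev = levels[-1]
        h, w = prev.shape[:2]
        if min(h, w) < 32:
            break
        out_shape = (h // 2, w // 2) + prev.shape[2:]
        ds = resize(prev.astype(float), out_shape, anti_aliasing=True,
                    preserve_range=True)
        if np.issubdtype(arr.dtype, np.integer):
            info = np.iinfo(arr.dtype)
            ds = np.clip(np.rint(ds), info.min, info.max).astype(arr.dtype)
        levels.append(ds)
    return levels


def write_registered(
    slide: SlideImage,
    out_path: str | os.PathLike,
    tile_size: int = 256,
    pyramid_levels: int = 3,
) -> None:
    """Write a slide as a tiled, pyramidal OME-TIFF.

    Level 0 is written losslessly (zlib), with channel names and physical
    pixel size carried in the OME metadata; sub-resolution levels are
    derived by area averaging.
    """
    arr = slide.levels[0]
    rgb = slide.is_rgb and arr.ndim == 3 and arr.shape[-1] == 3
    if arr.ndim == 2:
        planar = arr[np.newaxis]
    elif rgb:
        planar = arr
    else:
        planar = np.moveaxis(arr, -1, 0)
    levels = _pyramid_levels(planar, pyramid_levels)
    metadata = {"axes": "YXS" if rgb else ("YX" if planar.ndim == 2 else "CYX")}
    if not rgb:
        metadata["Channel"] = {"Name": list(slide.channel_names)}
    if slide.pixel_size_um is not None:
        metadata["PhysicalSizeX"] = slide.pixel_size_um
        metadata["PhysicalSizeY"] = slide.pixel_size_um
        metadata["PhysicalSizeXUnit"] = "µm"
        metadata["PhysicalSizeYUnit"] = "µm"
    tile = (tile_size, tile_size)
    try:
        with tifffile.TiffWriter(os.fspath(out_path), ome=True, bigtiff=False) as tw:
            tw.write(
                levels[0],
                tile=tile,
                compression="zlib",
                photometric="rgb" if rgb else "minisblack",
                subifds=len(levels) - 1,
                metadata=metadata,
            )
            for lvl in levels[1:]:
                tw.write(
                    lvl,
                    tile=tile,
                    compression="zlib",
                    photometric="rgb" if rgb else "minisblack",
                    subfiletype=1,
                )
    except OSError as exc:
        raise OSError(f"cannot write {out_path}: {exc}") from exc
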